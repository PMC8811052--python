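"""Ground-truthed synthetic inputs for the lung-window fate pipeline.

Three generators cover the pipeline's input space:

* :func:`simulate_cohort` — a longitudinal lung-window cohort: cells arrive
  in the field's microvasculature (Poisson per 8-h interval), then evolve by
  a discrete-time fate chain (disappear / extravasate while intravascular;
  die / grow once extravasated), observed only at interval boundaries exactly
  as the serial imaging sessions would see them.
* :func:`simulate_tissue` — a primary-tumor point pattern: Poisson nuclei,
  uniformly placed TMEM doorways and macrophages, and distance-dependent
  marker positivity ``p(d) = b * (1 + (E - 1) * exp(-d / tau))`` tied to the
  same dilated-doorway distance the downstream statistic measures.
* :func:`render_field` / :func:`simulate_timelapse` — image-space and
  migration-path fixtures.

Every generator is deterministic given its seed and returns the ground truth
alongside the observations, so recovery tests can score the pipeline against
the exact generative record.  :func:`markov_endpoints` computes the chain's
endpoint probabilities in closed form and is the calibration/oracle
counterpart of the stochastic cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .images import FieldImage
from .params import ConfigurationError, FateParams, FieldGeometry, TissueParams
from .spatial import DoorwayROIs, PointPattern, distance_to_tmem

OUTCOME_RETAINED = "retained-intravascular"
OUTCOME_DISAPPEARED = "disappeared"
OUTCOME_EXTRAV_SURVIVED = "extravasated-survived"
OUTCOME_EXTRAV_DIED = "extravasated-died"
OUTCOME_EXTRAV_GREW = "extravasated-grew"
OUTCOME_CENSORED = "censored"

MIN_CELL_SEPARATION_UM = 30.0


# ---------------------------------------------------------------------------
# Closed-form fate-chain endpoints (calibration oracle)
# ---------------------------------------------------------------------------

def markov_endpoints(params: FateParams) -> dict:
    """Exact endpoint probabilities of the fate chain, by forward recursion.

    States: intravascular (IV), extravasated single (EV), grown (GR,
    absorbing), disappeared (DI, absorbing), dead (DE, absorbing).  Returns
    per-cell marginals after the full follow-up of ``n_intervals`` intervals,
    the retention curve (probability the cell is still observable at each
    session), and the midpoint-convention extravasation-time moments.
    """
    params.ensure_valid()
    K = params.n_intervals
    pd_, pe = params.hazard("p_disappear"), params.hazard("p_extravasate")
    pm, pg = params.hazard("p_die"), params.hazard("p_grow")
    p_iv, p_ev, p_gr, p_di, p_de = 1.0, 0.0, 0.0, 0.0, 0.0
    q_extrav = np.zeros(K)          # P(extravasate during interval k)
    retention = [1.0]               # observable at session j since arrival
    for k in range(K):
        inflow = p_iv * pe[k]
        p_di += p_iv * pd_[k]
        p_iv *= 1.0 - pd_[k] - pe[k]
        p_de += p_ev * pm[k]
        p_gr += p_ev * pg[k]
        p_ev = p_ev * (1.0 - pm[k] - pg[k]) + inflow
        q_extrav[k] = inflow
        retention.append(1.0 - p_di - p_de)
    extrav_frac = float(q_extrav.sum())
    midpoints = (np.arange(K) + 0.5) * params.interval_h
    if extrav_frac > 0:
        w = q_extrav / extrav_frac
        mean_t = float(w @ midpoints)
        var_t = float(w @ (midpoints - mean_t) ** 2)
    else:
        mean_t, var_t = float("nan"), float("nan")
    out = {
        "retention_curve": np.asarray(retention),
        "retention_horizon": retention[-1],
        "extravasation_fraction": extrav_frac,
        "extravasation_interval_probs": q_extrav,
        "mean_extravasation_time_h": mean_t,
        "var_extravasation_time_h2": var_t,
        "p_states": {"iv": p_iv, "ev": p_ev, "grown": p_gr,
                     "disappeared": p_di, "dead": p_de},
    }
    if extrav_frac > 0:
        out["frac_died"] = p_de / extrav_frac
        out["frac_survived_single"] = p_ev / extrav_frac
        out["frac_grew"] = p_gr / extrav_frac
    else:
        out["frac_died"] = out["frac_survived_single"] = out["frac_grew"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Vessel layout
# ---------------------------------------------------------------------------

@dataclass
class Vessels:
    """Capillary-like vessel layout: centerline samples plus rasterized mask."""

    centerline_um: np.ndarray       # (n, 2) x_um, y_um
    mask: np.ndarray | None         # bool, image-space (row = y); None if not rasterized
    geometry: FieldGeometry
    _tree: cKDTree | None = None

    @property
    def centerline_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centerline_um)
        return self._tree


def make_vessels(
    geometry: FieldGeometry,
    seed: int | np.random.Generator,
    rasterize: bool = True,
) -> Vessels:
    """Dilated persistent-random-walk centerlines at the configured density.

    With ``rasterize=False`` only the centerline samples are generated (the
    coordinate-space cohort simulation never touches pixels); the walk and
    its random stream are identical either way, with the painted-area target
    replaced by the equivalent centerline length.
    """
    geometry.ensure_valid()
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    size = geometry.field_size_um
    px = geometry.pixel_size_um
    mask = np.zeros(shape, dtype=bool) if rasterize else None
    r_px = max(1, int(round(geometry.vessel_width_um / 2 / px)))
    centerline: list[tuple[float, float]] = []
    target_px = geometry.vessel_density * shape[0] * shape[1]
    # un-rasterized estimate: each 2-px step of a width-2r ribbon paints
    # about step * width new pixels (self-overlap ignored)
    px_per_step = 2.0 * (2 * r_px)
    painted = 0.0
    step = 2.0 * px
    max_walks = 200
    walk = 0
    while painted < target_px and walk < max_walks:
        walk += 1
        x, y = rng.uniform(0, size, size=2)
        heading = rng.uniform(0, 2 * math.pi)
        n_steps = int(1.5 * size / step)
        for _ in range(n_steps):
            heading += rng.normal(0, 0.25)
            x = float(np.clip(x + step * math.cos(heading), 0, size - 1e-6))
            y = float(np.clip(y + step * math.sin(heading), 0, size - 1e-6))
            centerline.append((x, y))
            if rasterize:
                rr, cc = draw_disk((y / px, x / px), r_px, shape=shape)
                patch = mask[rr, cc]
                painted += int(patch.size - patch.sum())
                mask[rr, cc] = True
            else:
                painted += px_per_step
            if painted >= target_px:
                break
    return Vessels(centerline_um=np.asarray(centerline), mask=mask, geometry=geometry)


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Observations plus the generative record of one simulated cohort."""

    detections: pd.DataFrame        # cell_id, session_h, x_um, y_um, area_um2, compartment, kind, pre_existing
    truth: pd.DataFrame             # one row per cell
    censoring: pd.DataFrame         # cell_id, censored_at_h (the imaging log)
    vessels: Vessels
    params: FateParams
    geometry: FieldGeometry
    session_times_h: np.ndarray

    def session_detections(self, session_h: float) -> pd.DataFrame:
        return self.detections[self.detections["session_h"] == session_h]


def _place_cells(
    n: int,
    centerline: np.ndarray,
    taken: list[np.ndarray],
    rng: np.random.Generator,
    min_sep: float = MIN_CELL_SEPARATION_UM,
) -> list[np.ndarray]:
    """Sample arrest positions on vessel centerlines, min_sep apart."""
    out = []
    taken_arr = (np.asarray(taken, dtype=float).reshape(-1, 2)
                 if taken else np.zeros((0, 2)))
    for _ in range(n):
        for _attempt in range(200):
            pos = centerline[rng.integers(len(centerline))].astype(float)
            if (len(taken_arr) == 0
                    or np.min(np.hypot(*(taken_arr - pos).T)) >= min_sep):
                break
        taken.append(pos)
        taken_arr = np.vstack([taken_arr, pos])
        out.append(pos)
    return out


def _extravasation_position(
    pos: np.ndarray,
    vessels: Vessels,
    taken: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Displace a cell off the vessel mask by at least one cell radius."""
    geom = vessels.geometry
    # just past the vessel wall: one cell radius clear of the lumen, but the
    # total move stays below the inter-session linking gate
    clearance = geom.vessel_width_um / 2 + geom.cell_radius_um + 1.0
    tree = vessels.centerline_tree
    size = geom.field_size_um
    for _attempt in range(100):
        theta = rng.uniform(0, 2 * math.pi)
        dist = clearance + rng.uniform(0, 2.0)
        cand = pos + dist * np.array([math.cos(theta), math.sin(theta)])
        if not (0 <= cand[0] < size and 0 <= cand[1] < size):
            continue
        d_vessel, _ = tree.query(cand)
        if d_vessel < clearance:
            continue
        taken_arr = np.asarray(taken, dtype=float).reshape(-1, 2)
        if (len(taken_arr) == 0
                or np.min(np.hypot(*(taken_arr - cand).T))
                >= MIN_CELL_SEPARATION_UM / 2):
            taken.append(cand)
            return cand
    taken.append(pos)       # crowded field: stay put rather than fail
    return pos


def simulate_cohort(
    params: FateParams,
    geometry: FieldGeometry,
    seed: int | np.random.Generator,
    vessels: Vessels | None = None,
) -> CohortResult:
    """Simulate a longitudinal lung-window cohort.

    Cells arrive per interval (Poisson with mean ``arrival_rate``) on vessel
    centerlines, evolve by the fate chain with hazards indexed by intervals
    since arrival, and are reported exactly at the 8-h session boundaries.
    Each cell is followed for ``horizon_h`` after its own arrival.  Cells
    present at the "Pre" session are flagged pre-existing (excluded by the
    tracker).  Censored cells stop being observed after their censoring
    session and are listed in the returned censoring log.
    """
    params.ensure_valid()
    geometry.ensure_valid()
    rng = np.random.default_rng(seed)
    if vessels is None:
        vessels = make_vessels(geometry, rng)
    dt = params.interval_h
    K = params.n_intervals
    pd_, pe = params.hazard("p_disappear"), params.hazard("p_extravasate")
    pm, pg = params.hazard("p_die"), params.hazard("p_grow")

    pre_time = -dt
    last_session = (params.n_arrival_intervals - 1) * dt + params.horizon_h
    session_times = np.arange(pre_time, last_session + dt / 2, dt)

    taken: list[np.ndarray] = []
    det_rows: list[dict] = []
    truth_rows: list[dict] = []
    censor_rows: list[dict] = []
    base_area = geometry.single_cell_area_um2
    next_id = 0

    # pre-existing cells: present from the Pre session onward, persist
    pre_positions = _place_cells(params.n_preexisting, vessels.centerline_um, taken, rng)
    for pos in pre_positions:
        cid = next_id
        next_id += 1
        for t in session_times:
            jitter = rng.normal(0, geometry.jitter_sd_um, size=2)
            det_rows.append(dict(
                cell_id=cid, session_h=float(t),
                x_um=float(pos[0] + jitter[0]), y_um=float(pos[1] + jitter[1]),
                area_um2=float(base_area * (1 + rng.normal(0, 0.05))),
                compartment="intravascular", kind="cell", pre_existing=True,
            ))
        truth_rows.append(dict(
            cell_id=cid, pre_existing=True, arrival_session_h=float(pre_time),
            extravasation_interval=np.nan, disappearance_interval=np.nan,
            death_interval=np.nan, growth_interval=np.nan,
            censor_interval=np.nan, outcome=OUTCOME_RETAINED,
            x0_um=float(pos[0]), y0_um=float(pos[1]),
        ))

    arrivals = rng.poisson(params.arrival_rate, size=params.n_arrival_intervals)
    for a, n_new in enumerate(arrivals):
        t_arrival = a * dt
        positions = _place_cells(int(n_new), vessels.centerline_um, taken, rng)
        for pos in positions:
            cid = next_id
            next_id += 1
            censor_k = None
            if params.censor_prob > 0 and rng.random() < params.censor_prob:
                censor_k = int(rng.integers(1, K)) if K > 1 else 1
            state = "iv"
            cur_pos = np.asarray(pos, dtype=float)
            area_factor = 1.0
            extrav_k = disap_k = death_k = growth_k = None
            obs: list[dict] = []

            def record(t_h: float, compartment: str) -> None:
                jitter = rng.normal(0, geometry.jitter_sd_um, size=2)
                obs.append(dict(
                    cell_id=cid, session_h=float(t_h),
                    x_um=float(np.clip(cur_pos[0] + jitter[0], 0,
                                       geometry.field_size_um - 1e-6)),
                    y_um=float(np.clip(cur_pos[1] + jitter[1], 0,
                                       geometry.field_size_um - 1e-6)),
                    area_um2=float(base_area * area_factor * (1 + rng.normal(0, 0.05))),
                    compartment=compartment, kind="cell", pre_existing=False,
                ))

            record(t_arrival, "intravascular")
            for k in range(K):
                if censor_k is not None and k >= censor_k:
                    break
                # per-cell randomness drawn every interval regardless of branch
                u = rng.random()
                v = rng.random()
                t_next = t_arrival + (k + 1) * dt
                if state == "iv":
                    if u < pd_[k]:
                        disap_k = k
                        break
                    if u < pd_[k] + pe[k]:
                        state = "ev"
                        extrav_k = k
                        cur_pos = _extravasation_position(cur_pos, vessels, taken, rng)
                elif state == "ev":
                    if v < pm[k]:
                        death_k = k
                        n_debris = int(rng.integers(2, 4))
                        for j in range(n_debris):
                            offs = rng.normal(0, geometry.cell_radius_um, size=2)
                            det_rows.append(dict(
                                cell_id=cid, session_h=float(t_next),
                                x_um=float(np.clip(cur_pos[0] + offs[0], 0,
                                                   geometry.field_size_um - 1e-6)),
                                y_um=float(np.clip(cur_pos[1] + offs[1], 0,
                                                   geometry.field_size_um - 1e-6)),
                                area_um2=float(np.pi * geometry.debris_radius_um**2
                                               * (1 + rng.normal(0, 0.1))),
                                compartment="extravascular", kind="debris",
                                pre_existing=False,
                            ))
                        break
                    if v < pm[k] + pg[k]:
                        state = "grown"
                        growth_k = k
                        area_factor = geometry.growth_area_factor
                record(t_next, "intravascular" if state == "iv" else "extravascular")

            censored_before_event = (
                censor_k is not None
                and disap_k is None and death_k is None
                and censor_k < K
            )
            if disap_k is not None:
                outcome = OUTCOME_DISAPPEARED
            elif death_k is not None:
                outcome = OUTCOME_EXTRAV_DIED
            elif censored_before_event:
                outcome = OUTCOME_CENSORED
            elif growth_k is not None:
                outcome = OUTCOME_EXTRAV_GREW
            elif extrav_k is not None:
                outcome = OUTCOME_EXTRAV_SURVIVED
            else:
                outcome = OUTCOME_RETAINED
            det_rows.extend(obs)
            truth_rows.append(dict(
                cell_id=cid, pre_existing=False, arrival_session_h=float(t_arrival),
                extravasation_interval=np.nan if extrav_k is None else extrav_k,
                disappearance_interval=np.nan if disap_k is None else disap_k,
                death_interval=np.nan if death_k is None else death_k,
                growth_interval=np.nan if growth_k is None else growth_k,
                censor_interval=np.nan if not censored_before_event else censor_k,
                outcome=outcome, x0_um=float(pos[0]), y0_um=float(pos[1]),
            ))
            if censored_before_event:
                censor_rows.append(dict(
                    cell_id=cid, censored_at_h=float(t_arrival + censor_k * dt)
                ))

    detections = pd.DataFrame(
        det_rows,
        columns=["cell_id", "session_h", "x_um", "y_um", "area_um2",
                 "compartment", "kind", "pre_existing"],
    ).sort_values(["session_h", "y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    censoring = pd.DataFrame(censor_rows, columns=["cell_id", "censored_at_h"])
    return CohortResult(
        detections=detections, truth=truth, censoring=censoring,
        vessels=vessels, params=params, geometry=geometry,
        session_times_h=session_times,
    )


# ---------------------------------------------------------------------------
# Tissue point patterns
# ---------------------------------------------------------------------------

def simulate_tissue(
    params: TissueParams,
    bounds_um: tuple[float, float] = (1000.0, 1000.0),
    seed: int | np.random.Generator = 0,
) -> tuple[PointPattern, pd.DataFrame]:
    """Simulate a primary-tumor tissue field.

    Nuclei are homogeneous Poisson; TMEM doorways and macrophages are uniform
    (with one macrophage at each doorway, since a doorway contains one); each
    nucleus is marker-positive with probability ``p(d)`` of its
    dilated-doorway distance.  Returns the pattern and a per-nucleus ground
    truth table (distance, positive probability, label).
    """
    params.ensure_valid()
    rng = np.random.default_rng(seed)
    w, h = bounds_um
    area_mm2 = w * h / 1e6
    n_nuc = int(rng.poisson(params.nuclei_density * area_mm2))
    nuclei = rng.uniform([0, 0], [w, h], size=(n_nuc, 2))
    doorway_centers = rng.uniform([0, 0], [w, h], size=(params.tmem_count, 2))
    doorways = DoorwayROIs(centers=doorway_centers,
                           radius_um=params.macrophage_roi_radius_um)
    n_mac = int(rng.poisson(params.macrophage_density * area_mm2))
    free_macs = rng.uniform([0, 0], [w, h], size=(n_mac, 2))
    macrophages = np.vstack([free_macs, doorway_centers]) if len(doorways) else free_macs

    d = distance_to_tmem(nuclei, doorways, params.dilation_um)
    p = params.positive_prob(d)
    if np.any(p > 1 + 1e-12):
        raise ConfigurationError("positive probability exceeds 1 at small distances")
    positive = rng.random(n_nuc) < p
    pattern = PointPattern(
        nuclei=nuclei,
        marker_pos_idx=np.nonzero(positive)[0],
        macrophages=macrophages,
        doorways=doorways,
        bounds_um=(w, h),
    )
    truth = pd.DataFrame({
        "x_um": nuclei[:, 0], "y_um": nuclei[:, 1],
        "distance_to_tmem_um": d, "p_positive": p, "marker_positive": positive,
    })
    return pattern, truth


def solve_enrichment_amp(
    d_reference: np.ndarray,
    target_ratio: float,
    params: TissueParams,
    near: tuple[float, float] = (0.0, 80.0),
    far: tuple[float, float] = (160.0, 200.0),
) -> float:
    """Solve the enrichment amplitude E giving a requested true near/far ratio.

    The true combined-window positivity ratio over realized nuclei distances
    is ``R(E) = (1 + (E-1) m_near) / (1 + (E-1) m_far)`` with
    ``m_w = mean(exp(-d/tau) | d in w)``; linear in ``E - 1``, so closed form.
    """
    d = np.asarray(d_reference, dtype=float)
    w = np.exp(-d / params.decay_len_um)
    in_near = (d >= near[0]) & (d < near[1])
    in_far = (d >= far[0]) & (d < far[1])
    if not in_near.any() or not in_far.any():
        raise ConfigurationError("no nuclei in the near or far window")
    m_near, m_far = float(w[in_near].mean()), float(w[in_far].mean())
    denom = m_near - target_ratio * m_far
    if denom <= 0:
        raise ConfigurationError(
            f"target ratio {target_ratio} unreachable with decay_len_um="
            f"{params.decay_len_um} (near weight {m_near:.3f} <= "
            f"ratio * far weight {target_ratio * m_far:.3f})"
        )
    e = 1.0 + (target_ratio - 1.0) / denom
    if params.baseline_pos_frac * e > 1:
        raise ConfigurationError(
            f"solved E={e:.2f} pushes p(0) above 1 at baseline "
            f"{params.baseline_pos_frac}"
        )
    return e


def simulate_tissue_with_true_ratio(
    target_ratio: float,
    params: TissueParams,
    bounds_um: tuple[float, float] = (1000.0, 1000.0),
    seed: int | np.random.Generator = 0,
    near: tuple[float, float] = (0.0, 80.0),
    far: tuple[float, float] = (160.0, 200.0),
) -> tuple[PointPattern, pd.DataFrame, float]:
    """Tissue whose *true* near/far positivity ratio equals ``target_ratio``.

    Draws the geometry first, then solves E against the realized nuclei
    distances, so the generative truth matches the target exactly for this
    tissue.  Returns (pattern, truth table, solved E).
    """
    rng = np.random.default_rng(seed)
    # geometry pass with E = 1 (labels discarded), then relabel with solved E
    flat = params.replace(enrichment_amp=1.0)
    pattern, truth = simulate_tissue(flat, bounds_um, rng)
    d = truth["distance_to_tmem_um"].to_numpy()
    e = solve_enrichment_amp(d, target_ratio, params, near, far)
    calibrated = params.replace(enrichment_amp=e)
    p = calibrated.positive_prob(d)
    positive = rng.random(len(d)) < p
    pattern = PointPattern(
        nuclei=pattern.nuclei,
        marker_pos_idx=np.nonzero(positive)[0],
        macrophages=pattern.macrophages,
        doorways=pattern.doorways,
        bounds_um=pattern.bounds_um,
        section_id=pattern.section_id,
    )
    truth = truth.assign(p_positive=p, marker_positive=positive)
    return pattern, truth, e


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def _add_blob(img: np.ndarray, x_px: float, y_px: float, sigma_px: float,
              amplitude: float) -> None:
    half = int(math.ceil(4 * sigma_px))
    cy, cx = int(round(y_px)), int(round(x_px))
    y0, y1 = max(0, cy - half), min(img.shape[0], cy + half + 1)
    x0, x1 = max(0, cx - half), min(img.shape[1], cx + half + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y_px) ** 2 + (xx - x_px) ** 2) / (2 * sigma_px**2)
    )


def render_field(
    detections: pd.DataFrame,
    vessels: Vessels,
    geometry: FieldGeometry,
    seed: int | np.random.Generator = 0,
    session_time_h: float = 0.0,
    field_id: str = "field-0",
    negative_control: bool = False,
) -> FieldImage:
    """Render one session's detections into a two-channel fluorescence field.

    Cells become Gaussian blobs on the tumor channel (blob scale follows the
    detection's area, so grown cells render larger and debris smaller);
    vessels fill the vasculature channel; both get additive Gaussian noise.
    With ``negative_control=True`` the signal is omitted and only the noise
    model remains — the thresholding calibration input.
    """
    geometry.ensure_valid()
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    tumor = np.zeros(shape, dtype=float)
    px = geometry.pixel_size_um
    if not negative_control:
        size = geometry.field_size_um
        for row in detections.itertuples():
            if not (0 <= row.x_um < size and 0 <= row.y_um < size):
                raise ValueError(
                    f"detection at ({row.x_um:.1f}, {row.y_um:.1f}) um outside field"
                )
            radius_um = math.sqrt(row.area_um2 / math.pi)
            sigma_px = max(0.8, radius_um / 2 / px)
            amp = (geometry.debris_intensity
                   if getattr(row, "kind", "cell") == "debris"
                   else geometry.cell_intensity)
            _add_blob(tumor, row.x_um / px, row.y_um / px, sigma_px, amp)
    vasc = np.zeros(shape, dtype=float)
    if not negative_control:
        vasc = vessels.mask.astype(float) * geometry.vessel_intensity
        if geometry.psf_sigma_um > 0:
            vasc = gaussian_filter(vasc, geometry.psf_sigma_um / px)
            tumor = gaussian_filter(tumor, geometry.psf_sigma_um / px)
    if geometry.noise_sd > 0:
        tumor = tumor + rng.normal(0, geometry.noise_sd, shape)
        vasc = vasc + rng.normal(0, geometry.noise_sd, shape)
    return FieldImage(
        channels={"tumor": tumor, "vasculature": vasc},
        pixel_size_um=px, session_time_h=session_time_h, field_id=field_id,
    )


# ---------------------------------------------------------------------------
# Migration time-lapse
# ---------------------------------------------------------------------------

def simulate_timelapse(
    n_cells: int,
    speed_um_per_h: float | np.ndarray,
    frame_interval_h: float,
    duration_h: float,
    seed: int | np.random.Generator = 0,
    mode: str = "random_walk",
    bounds_um: tuple[float, float] = (512.0, 512.0),
) -> pd.DataFrame:
    """Per-frame coordinates of migrating cells.

    Each cell moves one step of length ``speed * frame_interval`` per frame;
    headings are uniform i.i.d. (``random_walk``) or fixed per cell
    (``ballistic``).  Speeds may be a scalar or per-cell array; negative
    speeds are rejected.
    """
    if duration_h < frame_interval_h:
        raise ValueError("duration must be at least one frame interval")
    speeds = np.broadcast_to(np.asarray(speed_um_per_h, dtype=float), (n_cells,)).copy()
    if np.any(speeds < 0):
        raise ValueError("speeds must be non-negative")
    if mode not in ("random_walk", "ballistic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_frames = int(math.floor(duration_h / frame_interval_h)) + 1
    w, h = bounds_um
    start = rng.uniform([0.25 * w, 0.25 * h], [0.75 * w, 0.75 * h], size=(n_cells, 2))
    fixed_heading = rng.uniform(0, 2 * math.pi, size=n_cells)
    rows = []
    pos = start.copy()
    for f in range(n_frames):
        for i in range(n_cells):
            rows.append(dict(
                cell_id=i, frame=f, t_h=f * frame_interval_h,
                x_um=float(pos[i, 0]), y_um=float(pos[i, 1]),
            ))
        headings = (fixed_heading if mode == "ballistic"
                    else rng.uniform(0, 2 * math.pi, size=n_cells))
        step = speeds * frame_interval_h
        pos = pos + np.column_stack([step * np.cos(headings), step * np.sin(headings)])
    return pd.DataFrame(rows)
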