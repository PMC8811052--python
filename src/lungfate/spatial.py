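"""Nearest-structure distance enrichment for marker-positive cells.

Implements the normalized distance statistic used to ask whether
marker-positive tumor cells (e.g. NR2F1+, or NR2F1+/MenaINV+ double
positives) cluster around TMEM doorways, TMEM-free blood vessels, or
macrophages in primary-tumor sections.

The statistic: for every query cell and every reference nucleus, compute the
distance to the nearest structure; bin both sets of distances on a fixed
40-um grid over [0, 200] um; divide the query relative frequency by the
reference relative frequency per bin.  Under no association the ratio is ~1
in every bin.  The headline scalar is the fold enrichment between a near
window (default [0, 80) um) and a far window (default [160, 200) um),
computed on combined windows so empty sub-bins cannot destabilize it.

Doorway distances follow the dilated-ROI convention: the doorway macrophage
ROI is dilated by 60 um and any cell inside or touching the dilated ROI is at
distance 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .registration import Transform2D

DEFAULT_BIN_EDGES_UM = (0.0, 40.0, 80.0, 120.0, 160.0, 200.0)
DEFAULT_DILATION_UM = 60.0
NEAR_WINDOW_UM = (0.0, 80.0)
FAR_WINDOW_UM = (160.0, 200.0)


class DegeneratePatternError(ValueError):
    """A point pattern cannot support the requested distance statistic."""


@dataclass
class DoorwayROIs:
    """TMEM doorway macrophage ROIs as discs (centers in um, common radius)."""

    centers: np.ndarray            # (k, 2) x_um, y_um
    radius_um: float = 5.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)

    def __len__(self) -> int:
        return self.centers.shape[0]


@dataclass
class StructureMask:
    """Binary structure mask (e.g. thresholded vessel channel)."""

    mask: np.ndarray
    pixel_size_um: float = 1.0
    kind: str = "vessel"           # "vessel" | "vessel_no_tmem" | "tmem_roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PointPattern:
    """Labeled 2D point pattern for one tissue field.

    ``nuclei`` holds every reference nucleus; ``marker_pos_idx`` indexes the
    marker-positive subset (positives are nuclei, so their coordinates are a
    subset of the nucleus coordinates by construction).
    """

    nuclei: np.ndarray                      # (n, 2) x_um, y_um
    marker_pos_idx: np.ndarray              # indices into nuclei
    macrophages: np.ndarray                 # (m, 2)
    doorways: DoorwayROIs
    bounds_um: tuple[float, float]          # (width, height)
    section_id: str = "section-0"

    def __post_init__(self) -> None:
        self.nuclei = np.atleast_2d(np.asarray(self.nuclei, dtype=float))
        self.macrophages = np.atleast_2d(np.asarray(self.macrophages, dtype=float))
        if self.macrophages.size == 0:
            self.macrophages = self.macrophages.reshape(0, 2)
        self.marker_pos_idx = np.asarray(self.marker_pos_idx, dtype=int)

    @property
    def marker_pos(self) -> np.ndarray:
        return self.nuclei[self.marker_pos_idx]

    def to_frame(self):
        """Long-format table (x_um, y_um, label, section_id) for CSV export."""
        import pandas as pd

        rows = []
        for (x, y) in self.nuclei:
            rows.append((x, y, "nucleus"))
        for (x, y) in self.marker_pos:
            rows.append((x, y, "marker_pos"))
        for (x, y) in self.macrophages:
            rows.append((x, y, "macrophage"))
        for (x, y) in self.doorways.centers:
            rows.append((x, y, "tmem_doorway"))
        df = pd.DataFrame(rows, columns=["x_um", "y_um", "label"])
        df["section_id"] = self.section_id
        return df


@dataclass
class DistanceHistogram:
    """Binned nearest-structure distances with reference normalization."""

    bin_edges_um: np.ndarray
    counts_query: np.ndarray
    counts_reference: np.ndarray
    n_query: int                   # in-range query points (distance < last edge)
    n_reference: int
    n_query_total: int
    n_reference_total: int

    @property
    def rel_freq_query(self) -> np.ndarray:
        if self.n_query == 0:
            return np.full_like(self.counts_query, np.nan, dtype=float)
        return self.counts_query / self.n_query

    @property
    def rel_freq_reference(self) -> np.ndarray:
        if self.n_reference == 0:
            return np.full_like(self.counts_reference, np.nan, dtype=float)
        return self.counts_reference / self.n_reference

    @property
    def normalized_ratio(self) -> np.ndarray:
        """Per-bin query/reference relative-frequency ratio; NaN where the
        reference bin is empty (undefined, flagged rather than inf)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = self.rel_freq_query / self.rel_freq_reference
        ratio[self.counts_reference == 0] = np.nan
        return ratio

    def window_counts(self, window: tuple[float, float]) -> tuple[int, int]:
        lo, hi = window
        edges = self.bin_edges_um
        sel = (edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"window {window} does not align with bin edges {edges}")
        return int(self.counts_query[sel].sum()), int(self.counts_reference[sel].sum())


def align_serial_sections(
    landmarks_fixed: np.ndarray, landmarks_moving: np.ndarray
) -> Transform2D:
    """Least-squares affine aligning moving-section landmarks onto the fixed section.

    Serial 4-um sections are nearly rigid but may be rotated, shifted and
    slightly scaled on the slide; an affine fit over >= 3 non-collinear
    landmark pairs absorbs all of that.  Returns the 2x3 matrix mapping
    moving (x, y) to fixed coordinates and the RMS landmark residual in um.
    """
    fixed = np.atleast_2d(np.asarray(landmarks_fixed, dtype=float))
    moving = np.atleast_2d(np.asarray(landmarks_moving, dtype=float))
    if fixed.shape != moving.shape or fixed.shape[0] < 3:
        raise ValueError("need >= 3 landmark pairs of matching shape")
    design = np.hstack([moving, np.ones((moving.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear: affine fit is underdetermined")
    coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    matrix = coef.T                                   # 2x3
    residuals = design @ coef - fixed
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return Transform2D(kind="affine", matrix=matrix, rms_residual_um=rms, score=1.0)


def distance_to_tmem(
    points: np.ndarray,
    doorways: DoorwayROIs,
    dilation_um: float = DEFAULT_DILATION_UM,
) -> np.ndarray:
    """Distance from each point to the nearest dilated TMEM doorway ROI.

    ``d = max(0, euclidean distance to nearest macrophage ROI - dilation_um)``;
    points inside or touching the dilated ROI are at exactly 0 um.
    """
    if len(doorways) == 0:
        raise DegeneratePatternError("no TMEM doorways in the field")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d_center, _ = cKDTree(doorways.centers).query(pts)
    d = d_center - doorways.radius_um - dilation_um
    return np.maximum(d, 0.0)


def distance_to_points(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Plain nearest-neighbour distance from each point to the target set."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise DegeneratePatternError("no target points for distance query")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d, _ = cKDTree(targets).query(pts)
    return d


def exclude_tmem_vessels(mask: StructureMask, doorways: DoorwayROIs) -> StructureMask:
    """Delete vessel connected components that intersect any doorway ROI."""
    labels = cc_label(mask.mask, connectivity=2)
    if labels.max() == 0:
        raise DegeneratePatternError("structure mask is empty")
    drop: set[int] = set()
    yy, xx = np.nonzero(mask.mask)
    px_xy_um = np.column_stack([xx, yy]).astype(float) * mask.pixel_size_um
    if len(doorways) > 0:
        d, _ = cKDTree(doorways.centers).query(px_xy_um)
        hit = d <= doorways.radius_um
        drop = set(np.unique(labels[yy[hit], xx[hit]]).tolist())
    keep = mask.mask & ~np.isin(labels, sorted(drop))
    if not keep.any():
        raise DegeneratePatternError(
            "every vessel component intersects a TMEM doorway; nothing left "
            "to measure distances to"
        )
    return StructureMask(mask=keep, pixel_size_um=mask.pixel_size_um, kind="vessel_no_tmem")


def distance_to_structure(
    points: np.ndarray,
    mask: StructureMask,
    exclude_doorways: DoorwayROIs | None = None,
) -> np.ndarray:
    """Distance (um) from each point to the nearest structure pixel.

    If ``exclude_doorways`` is given, vessel components carrying a doorway are
    removed first (distance to TMEM-free vessels).  Points on the structure
    are at 0.  Exact point-to-pixel-center distances via a KD-tree over the
    structure pixels.
    """
    m = mask
    if exclude_doorways is not None:
        m = exclude_tmem_vessels(mask, exclude_doorways)
    yy, xx = np.nonzero(m.mask)
    if yy.size == 0:
        raise DegeneratePatternError("structure mask is empty")
    px_xy_um = np.column_stack([xx, yy]).astype(float) * m.pixel_size_um
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d, _ = cKDTree(px_xy_um).query(pts)
    return d


def enrichment_histogram(
    query_points: np.ndarray,
    reference_points: np.ndarray,
    distance_fn: Callable[[np.ndarray], np.ndarray],
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
) -> DistanceHistogram:
    """Reference-normalized nearest-structure distance histogram.

    ``distance_fn`` maps (n, 2) coordinates to nearest-structure distances
    (e.g. a closure over :func:`distance_to_tmem`).  Bins are half-open
    [lo, hi); points at or beyond the last edge fall in an overflow bin that
    is excluded from the relative frequencies and ratios.
    """
    query_points = np.atleast_2d(np.asarray(query_points, dtype=float))
    reference_points = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if query_points.shape[0] < 1:
        raise DegeneratePatternError("no query points")
    if reference_points.shape[0] < query_points.shape[0]:
        raise DegeneratePatternError(
            "reference population smaller than query population"
        )
    d_query = distance_fn(query_points)
    d_reference = distance_fn(reference_points)
    return histogram_from_distances(d_query, d_reference, bin_edges_um)


def histogram_from_distances(
    d_query: np.ndarray,
    d_reference: np.ndarray,
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
) -> DistanceHistogram:
    edges = np.asarray(bin_edges_um, dtype=float)
    d_query = np.asarray(d_query, dtype=float)
    d_reference = np.asarray(d_reference, dtype=float)
    cq, _ = np.histogram(d_query, bins=edges)
    cr, _ = np.histogram(d_reference, bins=edges)
    # np.histogram closes the last bin; enforce half-open [160, 200)
    cq[-1] -= int(np.sum(d_query == edges[-1]))
    cr[-1] -= int(np.sum(d_reference == edges[-1]))
    return DistanceHistogram(
        bin_edges_um=edges,
        counts_query=cq,
        counts_reference=cr,
        n_query=int(cq.sum()),
        n_reference=int(cr.sum()),
        n_query_total=int(d_query.size),
        n_reference_total=int(d_reference.size),
    )


def fold_enrichment(
    hist: DistanceHistogram,
    near: tuple[float, float] = NEAR_WINDOW_UM,
    far: tuple[float, float] = FAR_WINDOW_UM,
) -> float:
    """Near/far fold enrichment of the reference-normalized query frequency.

    ``[fq(near)/fr(near)] / [fq(far)/fr(far)]`` on combined windows.  Returns
    NaN (with a warning) when the far query window is empty and raises
    :class:`DegeneratePatternError` when a reference window is empty — the
    statistic is then not computable, never silently 0 or inf.
    """
    q_near, r_near = hist.window_counts(near)
    q_far, r_far = hist.window_counts(far)
    if r_near == 0 or r_far == 0:
        raise DegeneratePatternError(
            f"empty reference window (near n={r_near}, far n={r_far}); "
            "fold enrichment undefined"
        )
    if q_far == 0:
        warnings.warn(
            "no query cells in the far window; fold enrichment undefined (NaN)",
            stacklevel=2,
        )
        return float("nan")
    return (q_near / r_near) / (q_far / r_far)


def combined_fold_enrichment(
    hists: list[DistanceHistogram],
    near: tuple[float, float] = NEAR_WINDOW_UM,
    far: tuple[float, float] = FAR_WINDOW_UM,
) -> float:
    """Group-level fold enrichment over replicate tissues.

    The per-tissue normalized window frequencies are averaged across tissues
    *before* taking the near/far ratio — the way replicate ROI curves are
    averaged and then read off.  This avoids dividing by the handful of
    far-window query cells any single tissue contains, which makes the
    single-tissue ratio noticeably biased upward at realistic counts.
    """
    if not hists:
        raise DegeneratePatternError("no histograms to combine")
    ratios_near, ratios_far = [], []
    for h in hists:
        q_near, r_near = h.window_counts(near)
        q_far, r_far = h.window_counts(far)
        if h.n_query == 0 or r_near == 0 or r_far == 0:
            continue
        ratios_near.append((q_near / h.n_query) / (r_near / h.n_reference))
        ratios_far.append((q_far / h.n_query) / (r_far / h.n_reference))
    if not ratios_far or np.mean(ratios_far) == 0:
        raise DegeneratePatternError(
            "no usable far-window signal across the replicate tissues"
        )
    return float(np.mean(ratios_near) / np.mean(ratios_far))


def macrophage_proximity(
    query_points: np.ndarray,
    reference_points: np.ndarray,
    macrophages: np.ndarray,
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
) -> DistanceHistogram:
    """Distance histogram to the nearest macrophage (no ROI dilation).

    Same normalization machinery as the doorway statistic; the near window
    for macrophage proximity is conventionally [0, 40) um.
    """
    return enrichment_histogram(
        query_points,
        reference_points,
        lambda pts: distance_to_points(pts, macrophages),
        bin_edges_um,
    )


def permutation_null(
    pattern: PointPattern,
    n_perm: int,
    seed: int | np.random.Generator,
    distance_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    near: tuple[float, float] = NEAR_WINDOW_UM,
    far: tuple[float, float] = FAR_WINDOW_UM,
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
) -> dict:
    """Permutation null for the fold-enrichment statistic.

    Marker labels are permuted over nuclei: each permutation redraws the
    marker-positive set as a uniform subset of the nuclei of the observed
    size, and the fold enrichment is recomputed.  Returns the observed fold,
    the null sample, selected null quantiles, and the one-sided empirical
    p-value ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    n_pos = len(pattern.marker_pos_idx)
    n_nuc = pattern.nuclei.shape[0]
    if n_pos == 0 or n_nuc <= n_pos:
        raise DegeneratePatternError(
            "permutation null needs 0 < n_marker_pos < n_nuclei"
        )
    if distance_fn is None:
        distance_fn = lambda pts: distance_to_tmem(pts, pattern.doorways)
    rng = np.random.default_rng(seed)
    d_ref = distance_fn(pattern.nuclei)

    edges = np.asarray(bin_edges_um, dtype=float)
    obs_hist = histogram_from_distances(d_ref[pattern.marker_pos_idx], d_ref, edges)
    observed = fold_enrichment(obs_hist, near, far)

    in_near = (d_ref >= near[0]) & (d_ref < near[1])
    in_far = (d_ref >= far[0]) & (d_ref < far[1])
    r_near, r_far = int(in_near.sum()), int(in_far.sum())
    if r_near == 0 or r_far == 0:
        raise DegeneratePatternError("empty reference window in permutation null")
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_nuc, size=n_pos, replace=False)
        q_near = int(in_near[idx].sum())
        q_far = int(in_far[idx].sum())
        null[i] = np.nan if q_far == 0 else (q_near / r_near) / (q_far / r_far)
    finite_null = null[np.isfinite(null)]
    if np.isnan(observed):
        p_value = float("nan")
    else:
        p_value = (1 + int(np.sum(finite_null >= observed))) / (1 + finite_null.size)
    return {
        "observed_fold": observed,
        "null": null,
        "null_quantiles": {
            q: float(np.nanquantile(null, q)) for q in (0.025, 0.5, 0.975)
        },
        "p_value": p_value,
        "n_perm": n_perm,
    }
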