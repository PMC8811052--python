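"""Recovery evaluation: run the full tracking pipeline on synthetic cohorts
and score its estimates against the generative truth.

These helpers drive the package's own validation studies: simulate a cohort
with known hazards, push the emitted detections through linking, fate
classification and the cohort statistics, and compare each estimate to the
closed-form chain endpoint within its sampling interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fatestats import extravasation_stats, km_retention, survival_outcomes
from .params import FateParams, FieldGeometry
from .synthetic import (
    CohortResult,
    make_vessels,
    markov_endpoints,
    simulate_cohort,
)
from .tracking import CellTrack, classify_tracks, link_detections


def analyze_cohort(
    res: CohortResult,
    gate_um: float = 20.0,
    debris_max_area_um2: float = 50.0,
) -> list[CellTrack]:
    """Detections -> classified tracks for one simulated cohort."""
    dets = res.detections
    pre = dets[dets.session_h < 0]
    sessions = [float(t) for t in res.session_times_h if t >= 0]
    tables = [dets[dets.session_h == t] for t in sessions]
    censor_log = res.censoring
    if len(censor_log):
        last = (dets[dets.kind == "cell"]
                .sort_values("session_h").groupby("cell_id").last())
        censor_log = censor_log.join(last[["x_um", "y_um"]], on="cell_id")
    tracks = link_detections(
        tables, sessions, gate_um=gate_um, pre_detections=pre,
        debris_max_area_um2=debris_max_area_um2,
    )
    return classify_tracks(
        tracks, tables, sessions,
        interval_h=res.params.interval_h, horizon_h=res.params.horizon_h,
        single_cell_area_um2=res.geometry.single_cell_area_um2,
        debris_max_area_um2=debris_max_area_um2, gate_um=gate_um,
        censoring_log=censor_log if len(censor_log) else None,
    )


def estimate_endpoints(
    params: FateParams,
    geometry: FieldGeometry,
    seed: int | np.random.Generator,
) -> dict:
    """Pipeline estimates of the cohort endpoints for one simulated cohort."""
    rng = np.random.default_rng(seed)
    vessels = make_vessels(geometry, rng, rasterize=False)
    res = simulate_cohort(params, geometry, rng, vessels=vessels)
    tracks = analyze_cohort(res)
    name = "cohort"
    km = km_retention({name: tracks}, params.interval_h, params.horizon_h)
    ex = extravasation_stats(tracks, params.interval_h, params.horizon_h)
    out = survival_outcomes(tracks)
    return {
        "n_tracks": len(tracks),
        "n_extravasated": out["n_extravasated"],
        "retention_horizon": float(km["curves"][name]["survival"].iloc[-1]),
        "extravasation_fraction": ex["pct_extravasated"] / 100.0,
        "mean_extravasation_time_h": ex["mean_extravasation_time_h"],
        "frac_died": out["died"],
        "frac_survived_single": out["survived_single"],
        "frac_grew": out["grew"],
        "tracks": tracks,
        "cohort": res,
    }


def random_fate_params(
    rng: np.random.Generator,
    n_cells: int = 500,
    n_arrival_intervals: int = 8,
) -> FateParams:
    """A random constant-hazard configuration for recovery studies."""
    return FateParams(
        arrival_rate=n_cells / n_arrival_intervals,
        n_arrival_intervals=n_arrival_intervals,
        p_disappear=float(rng.uniform(0.02, 0.25)),
        p_extravasate=float(rng.uniform(0.05, 0.40)),
        p_die=float(rng.uniform(0.02, 0.30)),
        p_grow=float(rng.uniform(0.0, 0.15)),
    ).ensure_valid()


def _binomial_inside(count: int, n: int, p_truth: float, alpha: float) -> bool:
    """Is an observed count inside the central (1 - alpha) binomial band?"""
    if n == 0:
        return True
    lo = stats.binom.ppf(alpha / 2, n, p_truth)
    hi = stats.binom.ppf(1 - alpha / 2, n, p_truth)
    return lo <= count <= hi


def score_recovery(estimates: dict, truth: dict, joint_alpha: float = 0.01) -> dict:
    """Check every endpoint estimate against its truth sampling interval.

    The per-configuration check is a joint (1 - ``joint_alpha``) region:
    Sidak-split across the individual quantities, exact binomial bands for
    the proportions and a normal band for the mean extravasation time.
    """
    n = estimates["n_tracks"]
    n_ex = estimates["n_extravasated"]
    m = 6
    alpha_q = 1 - (1 - joint_alpha) ** (1 / m)
    checks = {
        "retention_horizon": _binomial_inside(
            int(round(estimates["retention_horizon"] * n)), n,
            truth["retention_horizon"], alpha_q,
        ),
        "extravasation_fraction": _binomial_inside(
            n_ex, n, truth["extravasation_fraction"], alpha_q,
        ),
    }
    for key in ("frac_died", "frac_survived_single", "frac_grew"):
        est = estimates[key]
        count = 0 if not np.isfinite(est) else int(round(est * n_ex))
        checks[key] = _binomial_inside(count, n_ex, truth[key], alpha_q)
    if n_ex > 1 and np.isfinite(truth["mean_extravasation_time_h"]):
        se = np.sqrt(truth["var_extravasation_time_h2"] / n_ex)
        z = stats.norm.ppf(1 - alpha_q / 2)
        checks["mean_extravasation_time_h"] = (
            abs(estimates["mean_extravasation_time_h"]
                - truth["mean_extravasation_time_h"]) <= z * se
        )
    else:
        checks["mean_extravasation_time_h"] = True
    return {"checks": checks, "passed": all(checks.values())}


def recovery_benchmark(
    n_configs: int = 20,
    n_cells: int = 500,
    seed: int = 0,
    field_size_um: float = 2048.0,
    joint_alpha: float = 0.01,
) -> pd.DataFrame:
    """Fate-parameter recovery study over random hazard configurations.

    For each seeded configuration, simulate ~``n_cells`` cells, run the full
    detection->track->summarize pipeline, and record whether every endpoint
    estimate (64-h retention, extravasation fraction, midpoint-convention
    mean extravasation time, and post-extravasation outcome fractions) lies
    inside the joint 99% sampling region of the closed-form truth.
    """
    geometry = FieldGeometry(field_size_um=field_size_um)
    rows = []
    seqs = np.random.SeedSequence(seed).spawn(n_configs)
    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        params = random_fate_params(rng, n_cells=n_cells)
        truth = markov_endpoints(params)
        est = estimate_endpoints(params, geometry, rng)
        result = score_recovery(est, truth, joint_alpha)
        rows.append({
            "config": i,
            "n_tracks": est["n_tracks"],
            "passed": result["passed"],
            **{f"check_{k}": v for k, v in result["checks"].items()},
            "retention_est": est["retention_horizon"],
            "retention_truth": truth["retention_horizon"],
            "extrav_est": est["extravasation_fraction"],
            "extrav_truth": truth["extravasation_fraction"],
            "mean_t_est": est["mean_extravasation_time_h"],
            "mean_t_truth": truth["mean_extravasation_time_h"],
        })
    return pd.DataFrame(rows)
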