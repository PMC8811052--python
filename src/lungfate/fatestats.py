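"""Cohort-level fate statistics: retention curves, extravasation kinetics,
post-extravasation outcomes, motility projections, and group comparisons.

Retention is summarized with the Kaplan–Meier product-limit estimator on the
8-h session grid; the event is the cell's disappearance (or death), and
cells still observed at the end of their follow-up are censored.  Times are
measured from each cell's own arrival.  Extravasation times are interval
censored by the imaging scheme, so an event in interval ``k`` is assigned
the interval midpoint ``(k + 0.5) * interval_h``.

Percentages are aggregated per animal first and then averaged across animals
(mean +/- SEM), matching how replicated intravital cohorts are reported and
avoiding pseudo-replication over cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .tracking import CellTrack


@dataclass
class FateSummary:
    """Per-group fate summary: retention curve, extravasation kinetics,
    and post-extravasation outcome fractions."""

    group: str
    km_curve: pd.DataFrame                  # time_h, survival, n_at_risk, n_events
    n_tracks: int
    pct_extravasated: float
    extravasation_histogram: pd.DataFrame   # interval, midpoint_h, n_cells
    mean_extravasation_time_h: float
    sem_extravasation_time_h: float
    outcome_fractions: dict                 # died / survived_single / grew
    per_animal: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_tracks": self.n_tracks,
            "km_curve": self.km_curve.to_dict(orient="list"),
            "pct_extravasated": self.pct_extravasated,
            "extravasation_histogram":
                self.extravasation_histogram.to_dict(orient="list"),
            "mean_extravasation_time_h": self.mean_extravasation_time_h,
            "sem_extravasation_time_h": self.sem_extravasation_time_h,
            "outcome_fractions": self.outcome_fractions,
            "per_animal": (None if self.per_animal is None
                           else self.per_animal.to_dict(orient="list")),
        }


def _retention_times(
    tracks: list[CellTrack], interval_h: float, horizon_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """(duration from arrival, event flag) per track for the KM estimator.

    Event = disappearance or death, timed at the first session the cell was
    absent; censoring at the censoring time or the follow-up horizon.
    """
    durations, events = [], []
    for t in tracks:
        ev_interval = t.disappearance_interval
        if ev_interval is None:
            ev_interval = t.death_interval
        if ev_interval is not None:
            durations.append((ev_interval + 1) * interval_h)
            events.append(1)
        elif t.censored_at_h is not None:
            durations.append(max(t.censored_at_h - t.arrival_session_h, 0.0))
            events.append(0)
        else:
            durations.append(horizon_h)
            events.append(0)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=int)


def km_retention(
    tracks_by_group: dict[str, list[CellTrack]],
    interval_h: float = 8.0,
    horizon_h: float = 64.0,
) -> dict:
    """Product-limit retention curves per group, plus a log-rank comparison.

    Returns ``{"curves": {group: DataFrame}, "logrank": {...} or None}``;
    the log-rank (Mantel–Cox) test is computed when exactly two groups are
    given.  Empty groups are an error.
    """
    for name, tracks in tracks_by_group.items():
        if not tracks:
            raise ValueError(f"group {name!r} has no tracks")
    grid = np.arange(0, horizon_h + interval_h / 2, interval_h)
    curves: dict[str, pd.DataFrame] = {}
    fits = {}
    for name, tracks in tracks_by_group.items():
        durations, events = _retention_times(tracks, interval_h, horizon_h)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, events, timeline=grid, label=name)
        surv = kmf.survival_function_[name].to_numpy()
        ev_table = kmf.event_table
        n_at_risk = [int(ev_table.loc[:t_, "at_risk"].iloc[-1])
                     if (ev_table.index <= t_).any() else len(tracks)
                     for t_ in grid]
        n_events = [int(ev_table.loc[ev_table.index == t_, "observed"].sum())
                    for t_ in grid]
        curves[name] = pd.DataFrame({
            "time_h": grid, "survival": surv,
            "n_at_risk": n_at_risk, "n_events": n_events,
        })
        fits[name] = (durations, events)
    logrank = None
    if len(tracks_by_group) == 2:
        (da, ea), (db, eb) = fits.values()
        res = logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        logrank = {
            "test": "log-rank (Mantel-Cox)",
            "statistic": float(res.test_statistic),
            "p_value": float(res.p_value),
        }
    return {"curves": curves, "logrank": logrank}


def extravasation_stats(
    tracks: list[CellTrack],
    interval_h: float = 8.0,
    horizon_h: float = 64.0,
) -> dict:
    """Extravasation kinetics of one cohort.

    Histogram of extravasation intervals (8-h bins at interval midpoints),
    percentage of analyzable cells that extravasated within the horizon, and
    the mean +/- SEM of the midpoint-convention extravasation times.
    """
    n_intervals = int(round(horizon_h / interval_h))
    analyzable = [t for t in tracks if t.outcome != "censored" or t.extravasated]
    times = []
    counts = np.zeros(n_intervals, dtype=int)
    for t in analyzable:
        k = t.extravasation_interval
        if k is not None and k < n_intervals:
            counts[k] += 1
            times.append((k + 0.5) * interval_h)
    times = np.asarray(times, dtype=float)
    hist = pd.DataFrame({
        "interval": np.arange(n_intervals),
        "midpoint_h": (np.arange(n_intervals) + 0.5) * interval_h,
        "n_cells": counts,
    })
    n = len(analyzable)
    pct = 100.0 * len(times) / n if n else float("nan")
    mean_t = float(times.mean()) if len(times) else float("nan")
    sem_t = (float(times.std(ddof=1) / np.sqrt(len(times)))
             if len(times) > 1 else 0.0 if len(times) == 1 else float("nan"))
    return {
        "n_analyzable": n,
        "n_extravasated": int(len(times)),
        "pct_extravasated": pct,
        "histogram": hist,
        "mean_extravasation_time_h": mean_t,
        "sem_extravasation_time_h": sem_t,
    }


def survival_outcomes(tracks: list[CellTrack]) -> dict:
    """Fractions of extravasated cells that died / survived single / grew."""
    extrav = [t for t in tracks
              if t.extravasated and t.outcome != "censored"]
    n = len(extrav)
    if n == 0:
        warnings.warn("no extravasated tracks; outcome fractions undefined",
                      stacklevel=2)
        return {"n_extravasated": 0, "died": float("nan"),
                "survived_single": float("nan"), "grew": float("nan")}
    died = sum(t.outcome == "extrav_died" for t in extrav)
    grew = sum(t.outcome == "extrav_grew" for t in extrav)
    survived = sum(t.outcome in ("extrav_survived_single", "retained")
                   for t in extrav)
    return {
        "n_extravasated": n,
        "died": died / n,
        "survived_single": survived / n,
        "grew": grew / n,
    }


def per_animal_summary(
    tracks: list[CellTrack],
    interval_h: float = 8.0,
    horizon_h: float = 64.0,
) -> pd.DataFrame:
    """Per-animal percentages (one row per animal_id)."""
    rows = []
    by_animal: dict[str, list[CellTrack]] = {}
    for t in tracks:
        by_animal.setdefault(t.animal_id or "animal-0", []).append(t)
    for animal, ts in sorted(by_animal.items()):
        ex = extravasation_stats(ts, interval_h, horizon_h)
        out = survival_outcomes(ts) if any(t.extravasated for t in ts) else None
        rows.append(dict(
            animal_id=animal, n_tracks=len(ts),
            pct_extravasated=ex["pct_extravasated"],
            mean_extravasation_time_h=ex["mean_extravasation_time_h"],
            pct_died=100 * out["died"] if out else np.nan,
            pct_survived_single=100 * out["survived_single"] if out else np.nan,
            pct_grew=100 * out["grew"] if out else np.nan,
        ))
    return pd.DataFrame(rows)


def summarize_group(
    tracks: list[CellTrack],
    group: str,
    interval_h: float = 8.0,
    horizon_h: float = 64.0,
) -> FateSummary:
    """Full FateSummary for one group (pooled cells + per-animal table)."""
    km = km_retention({group: tracks}, interval_h, horizon_h)
    ex = extravasation_stats(tracks, interval_h, horizon_h)
    out = survival_outcomes(tracks)
    return FateSummary(
        group=group,
        km_curve=km["curves"][group],
        n_tracks=len(tracks),
        pct_extravasated=ex["pct_extravasated"],
        extravasation_histogram=ex["histogram"],
        mean_extravasation_time_h=ex["mean_extravasation_time_h"],
        sem_extravasation_time_h=ex["sem_extravasation_time_h"],
        outcome_fractions={k: out[k] for k in ("died", "survived_single", "grew")},
        per_animal=per_animal_summary(tracks, interval_h, horizon_h),
    )


def motility_analysis(
    timelapse: pd.DataFrame,
    center_to_boundary_um: float = 256.0,
) -> dict:
    """Speeds and projected minimum field-exit time from time-lapse tracks.

    Per-cell mean speed = path length / elapsed time; the projected minimum
    exit time is how long the *fastest* cell would need to travel from the
    field center to its boundary, infinite when nothing moves.  Single-frame
    tracks are excluded.
    """
    speeds = {}
    for cid, g in timelapse.sort_values("frame").groupby("cell_id"):
        if len(g) < 2:
            continue
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        path = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        elapsed = float(g["t_h"].iloc[-1] - g["t_h"].iloc[0])
        if elapsed > 0:
            speeds[cid] = path / elapsed
    if not speeds:
        raise ValueError("no track with >= 2 frames")
    arr = np.array(list(speeds.values()))
    max_speed = float(arr.max())
    exit_time = (float("inf") if max_speed == 0
                 else center_to_boundary_um / max_speed)
    return {
        "mean_speed_um_per_h": float(arr.mean()),
        "max_speed_um_per_h": max_speed,
        "projected_min_exit_time_h": exit_time,
        "per_cell_speeds": speeds,
    }


# ---------------------------------------------------------------------------
# Group comparisons (normality-screened test selection)
# ---------------------------------------------------------------------------

def _dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal–Wallis,
    Bonferroni-adjusted, with the tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (n_total - 1))
    offsets = np.cumsum([0] + [len(groups[n]) for n in names])
    mean_ranks = {
        n: float(ranks[offsets[i]:offsets[i + 1]].mean())
        for i, n in enumerate(names)
    }
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term) * (1 / na + 1 / nb)
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append(dict(group_a=a, group_b=b, statistic=float(z),
                             p_value=float(min(1.0, p * m))))
    return pd.DataFrame(rows)


def _sidak_pairwise_t(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            t, p = stats.ttest_ind(groups[a], groups[b])
            rows.append(dict(group_a=a, group_b=b, statistic=float(t),
                             p_value=float(1 - (1 - p) ** m)))
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Compare per-animal values across groups, choosing the test by a
    Shapiro–Wilk normality screen at ``alpha``.

    Two groups: t-test when both pass the screen, else two-tailed
    Mann–Whitney.  More than two: one-way ANOVA with Sidak-adjusted pairwise
    t-tests, else Kruskal–Wallis with Dunn's pairwise comparisons.  Groups
    smaller than 3 skip the screen and fall back to the nonparametric branch
    (with a warning).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = [k for k, v in arrays.items() if len(v) < 3]
    if small:
        warnings.warn(
            f"groups {small} have < 3 values; normality screen skipped, "
            "nonparametric test used", stacklevel=2,
        )
        normal = False
    else:
        normal = all(
            np.ptp(v) > 0 and stats.shapiro(v).pvalue > alpha
            for v in arrays.values()
        )
    vals = list(arrays.values())
    if len(arrays) == 2:
        if normal:
            res = stats.ttest_ind(*vals)
            name = "two-tailed unpaired t-test"
        else:
            res = stats.mannwhitneyu(*vals, alternative="two-sided")
            name = "two-tailed Mann-Whitney test"
        return {"test": name, "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "normality_screen_passed": normal}
    if normal:
        res = stats.f_oneway(*vals)
        pairwise = _sidak_pairwise_t(arrays)
        name = "one-way ANOVA with Sidak's multiple comparisons"
    else:
        res = stats.kruskal(*vals)
        pairwise = _dunn_test(arrays)
        name = "Kruskal-Wallis test with Dunn's multiple comparisons"
    return {"test": name, "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "normality_screen_passed": normal,
            "pairwise": pairwise}
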