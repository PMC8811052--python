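"""Linking detections across sessions and classifying each cell's fate.

Tracks are built by greedy mutual-nearest-neighbour matching between
consecutive sessions within a spatial gate (cells are essentially immobile
between 8-h sessions, so the gate is far below a cell diameter of
inter-session travel).  Fate rules:

* a cell absent at the next session while intravascular *disappeared*
  (re-entered circulation or was cleared);
* an absent extravascular cell surrounded by >= 2 sub-cellular debris
  objects *died* (apoptotic bodies);
* an absent extravascular cell with no debris cannot recirculate — the track
  is flagged anomalous and censored;
* an extravasated cell whose area exceeds twice the single-cell area *grew*
  into a micrometastasis.

Tracks seeded within the gate of a detection from the "Pre" session are
pre-existing cells of unknown arrival time and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_GATE_UM = 20.0
DEFAULT_DEBRIS_MAX_AREA_UM2 = 50.0
GROWTH_AREA_FACTOR = 2.0

INTRAVASCULAR = "intravascular"
EXTRAVASCULAR = "extravascular"
UNCERTAIN = "uncertain"


@dataclass
class CellTrack:
    """One linked cell across sessions, with derived fate events.

    Event intervals are counted in observation intervals since the track's
    arrival session (interval ``k`` spans sessions ``k`` to ``k+1``).
    """

    track_id: int
    arrival_session_h: float
    observations: pd.DataFrame      # session_h, x_um, y_um, area_um2, compartment
    extravasation_interval: int | None = None
    disappearance_interval: int | None = None
    death_interval: int | None = None
    growth_interval: int | None = None
    censored_at_h: float | None = None
    outcome: str = "unclassified"
    anomalous: bool = False
    animal_id: str | None = None

    @property
    def last_session_h(self) -> float:
        return float(self.observations["session_h"].iloc[-1])

    @property
    def last_position(self) -> np.ndarray:
        row = self.observations.iloc[-1]
        return np.array([row["x_um"], row["y_um"]])

    @property
    def extravasated(self) -> bool:
        return self.extravasation_interval is not None


def _greedy_mutual_match(
    prev_xy: np.ndarray, next_xy: np.ndarray, gate_um: float
) -> list[tuple[int, int]]:
    """Greedy nearest-pair matching within the gate (ascending distance).

    Equivalent to repeatedly pairing the globally closest unmatched
    (previous, next) detections; ties broken by detection order.
    """
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    dist = cdist(prev_xy, next_xy)
    order = np.argsort(dist, axis=None, kind="stable")
    used_prev: set[int] = set()
    used_next: set[int] = set()
    matches = []
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > gate_um:
            break
        if i in used_prev or j in used_next:
            continue
        matches.append((int(i), int(j)))
        used_prev.add(int(i))
        used_next.add(int(j))
    return matches


def split_cells_debris(
    detections: pd.DataFrame, debris_max_area_um2: float = DEFAULT_DEBRIS_MAX_AREA_UM2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a detection table into cell-sized and debris-sized objects."""
    is_debris = detections["area_um2"] < debris_max_area_um2
    return detections[~is_debris], detections[is_debris]


def link_detections(
    session_detections: list[pd.DataFrame],
    session_times_h: list[float],
    gate_um: float = DEFAULT_GATE_UM,
    pre_detections: pd.DataFrame | None = None,
    debris_max_area_um2: float = DEFAULT_DEBRIS_MAX_AREA_UM2,
) -> list[CellTrack]:
    """Link per-session detection tables into tracks.

    ``session_detections`` must be time-ordered and co-registered; each table
    needs columns x_um, y_um, area_um2 and (if available) compartment.
    Unmatched new detections open tracks with arrival at that session;
    unmatched prior detections close their track (candidate disappearance or
    death, resolved later by :func:`classify_tracks`).  Debris-sized objects
    never seed or extend tracks.  Tracks seeded within the gate of a Pre
    detection are dropped (pre-existing cells, arrival time unknown).
    """
    if len(session_detections) != len(session_times_h):
        raise ValueError("session_detections and session_times_h differ in length")
    pre_xy = None
    if pre_detections is not None and len(pre_detections):
        pre_cells, _ = split_cells_debris(pre_detections, debris_max_area_um2)
        pre_xy = pre_cells[["x_um", "y_um"]].to_numpy(dtype=float)

    tracks: list[CellTrack] = []
    open_tracks: list[CellTrack] = []        # heads eligible for matching
    next_id = 0
    for t_h, table in zip(session_times_h, session_detections):
        cells, _ = split_cells_debris(table, debris_max_area_um2)
        cells = cells.sort_values(["y_um", "x_um"], kind="mergesort").reset_index(drop=True)
        next_xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        prev_xy = (np.array([t.last_position for t in open_tracks])
                   if open_tracks else np.zeros((0, 2)))
        matches = _greedy_mutual_match(prev_xy, next_xy, gate_um)
        matched_next = {j for _, j in matches}
        still_open: list[CellTrack] = []
        matched_prev = {i for i, _ in matches}
        for i, j in matches:
            track = open_tracks[i]
            row = cells.iloc[[j]].assign(session_h=t_h)
            track.observations = pd.concat(
                [track.observations, _obs_row(row)], ignore_index=True
            )
            still_open.append(track)
        for i, track in enumerate(open_tracks):
            if i not in matched_prev:
                tracks.append(track)             # closed: absent this session
        for j in range(len(cells)):
            if j in matched_next:
                continue
            seed = cells.iloc[[j]].assign(session_h=t_h)
            xy = next_xy[j]
            if pre_xy is not None and len(pre_xy):
                if np.min(np.hypot(*(pre_xy - xy).T)) <= gate_um:
                    continue                     # pre-existing cell
            track = CellTrack(
                track_id=next_id, arrival_session_h=float(t_h),
                observations=_obs_row(seed),
            )
            next_id += 1
            still_open.append(track)
        open_tracks = still_open
    tracks.extend(open_tracks)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def _obs_row(row: pd.DataFrame) -> pd.DataFrame:
    cols = ["session_h", "x_um", "y_um", "area_um2"]
    out = row[cols + (["compartment"] if "compartment" in row else [])].copy()
    if "compartment" not in out:
        out["compartment"] = UNCERTAIN
    return out.reset_index(drop=True)


def classify_compartment(
    cell_mask: np.ndarray,
    vessel_mask: np.ndarray,
    overlap_threshold: float = 0.5,
) -> str:
    """Intravascular / extravascular call from cell-vessel pixel overlap.

    Overlap fraction >= threshold: intravascular; exactly 0: extravasated;
    in between: uncertain (the localization cannot be resolved; such cells
    are excluded from extravasation statistics).
    """
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    overlap = float(np.logical_and(cell, vessel_mask).sum() / cell.sum())
    if overlap >= overlap_threshold:
        return INTRAVASCULAR
    if overlap == 0:
        return EXTRAVASCULAR
    return UNCERTAIN


def disk_mask(
    shape: tuple[int, int], x_um: float, y_um: float, radius_um: float,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Disc footprint of a detection, for overlap classification."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float) * pixel_size_um
    return (yy - y_um) ** 2 + (xx - x_um) ** 2 <= radius_um**2


def detect_death(
    track: CellTrack,
    session_objects: pd.DataFrame,
    debris_max_area_um2: float = DEFAULT_DEBRIS_MAX_AREA_UM2,
    gate_um: float = DEFAULT_GATE_UM,
) -> bool:
    """Death call for a track absent at the current session.

    True when >= 2 objects, each below the debris area ceiling, lie within
    the gate of the cell's last position (apoptotic bodies where the cell
    was).
    """
    if len(track.observations) == 0:
        raise ValueError("track has no prior observation")
    if session_objects is None or len(session_objects) == 0:
        return False
    small = session_objects[session_objects["area_um2"] < debris_max_area_um2]
    if len(small) == 0:
        return False
    xy = small[["x_um", "y_um"]].to_numpy(dtype=float)
    d = np.hypot(*(xy - track.last_position).T)
    return int(np.sum(d <= gate_um)) >= 2


def detect_growth(
    track: CellTrack,
    single_cell_area_um2: float,
    growth_factor: float = GROWTH_AREA_FACTOR,
    cluster_size: int = 1,
) -> int | None:
    """First interval at which an extravasated cell shows growth, or None.

    Growth = observed area above ``growth_factor`` times the single-cell
    area (default 2x, safely above transient ~10% area fluctuations), or the
    track's cluster containing >= 2 cells.
    """
    if not track.extravasated:
        return None
    if cluster_size >= 2:
        return track.extravasation_interval
    areas = track.observations["area_um2"].to_numpy(dtype=float)
    over = np.nonzero(areas > growth_factor * single_cell_area_um2)[0]
    if len(over) == 0:
        return None
    return max(0, int(over[0]) - 1)


def classify_tracks(
    tracks: list[CellTrack],
    session_detections: list[pd.DataFrame],
    session_times_h: list[float],
    interval_h: float = 8.0,
    horizon_h: float = 64.0,
    single_cell_area_um2: float = 200.0,
    debris_max_area_um2: float = DEFAULT_DEBRIS_MAX_AREA_UM2,
    gate_um: float = DEFAULT_GATE_UM,
    censoring_log: pd.DataFrame | None = None,
) -> list[CellTrack]:
    """Apply the fate rules to linked tracks (in place; returns the list).

    ``censoring_log`` is the imaging log of known losses to follow-up
    (columns censored_at_h, x_um, y_um): a track whose end matches a log
    entry in time and position is censored, not an event.  Each track is
    evaluated over ``horizon_h`` after its own arrival; tracks complete at
    the horizon are retained / survived / grew according to their state.
    """
    time_index = {round(t, 6): i for i, t in enumerate(session_times_h)}
    for track in tracks:
        obs = track.observations
        t0 = track.arrival_session_h
        follow_end = t0 + horizon_h
        comp = obs["compartment"].to_numpy()
        sessions = obs["session_h"].to_numpy(dtype=float)
        extrav_sessions = np.nonzero(comp == EXTRAVASCULAR)[0]
        if len(extrav_sessions):
            first = int(extrav_sessions[0])
            k = int(round((sessions[first] - t0) / interval_h))
            track.extravasation_interval = max(0, k - 1)
        track.growth_interval = detect_growth(track, single_cell_area_um2)

        t_last = track.last_session_h
        censored_by_log = False
        if censoring_log is not None and len(censoring_log):
            dt_match = np.isclose(censoring_log["censored_at_h"], t_last)
            if {"x_um", "y_um"}.issubset(censoring_log.columns):
                xy = censoring_log[["x_um", "y_um"]].to_numpy(dtype=float)
                d = np.hypot(*(xy - track.last_position).T)
                dt_match &= d <= gate_um
            censored_by_log = bool(dt_match.any())

        ended_early = t_last + interval_h / 2 < min(follow_end, session_times_h[-1])
        if censored_by_log:
            track.censored_at_h = t_last
        elif ended_early:
            k_absent = int(round((t_last - t0) / interval_h))  # absent in interval k_absent
            next_idx = time_index.get(round(t_last + interval_h, 6))
            next_objects = (session_detections[next_idx]
                            if next_idx is not None else None)
            died = detect_death(track, next_objects, debris_max_area_um2, gate_um)
            last_comp = comp[-1]
            if died and last_comp == EXTRAVASCULAR:
                track.death_interval = k_absent
            elif last_comp == INTRAVASCULAR:
                track.disappearance_interval = k_absent
            else:
                # extravascular cell vanished without debris: cannot
                # recirculate, so the observation is anomalous -> censor
                track.anomalous = True
                track.censored_at_h = t_last
        elif t_last + interval_h / 2 < follow_end:
            # experiment ended before this cell's horizon: administrative censoring
            track.censored_at_h = t_last

        if track.disappearance_interval is not None:
            track.outcome = "disappeared"
        elif track.death_interval is not None:
            track.outcome = "extrav_died"
        elif track.censored_at_h is not None:
            track.outcome = "censored"
        elif track.growth_interval is not None:
            track.outcome = "extrav_grew"
        elif track.extravasated:
            track.outcome = "extrav_survived_single"
        else:
            track.outcome = "retained"
    return tracks


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    """Flat per-track summary table (one row per track) for CSV export."""
    rows = []
    for t in tracks:
        rows.append(dict(
            track_id=t.track_id, animal_id=t.animal_id,
            arrival_session_h=t.arrival_session_h,
            n_observations=len(t.observations),
            last_session_h=t.last_session_h,
            extravasation_interval=t.extravasation_interval,
            disappearance_interval=t.disappearance_interval,
            death_interval=t.death_interval,
            growth_interval=t.growth_interval,
            censored_at_h=t.censored_at_h,
            outcome=t.outcome, anomalous=t.anomalous,
        ))
    return pd.DataFrame(rows)


def track_identity_agreement(
    tracks: list[CellTrack], truth_detections: pd.DataFrame
) -> float:
    """Fraction of tracks whose observations all map to one true cell.

    Evaluation helper: each observation is matched to the nearest
    ground-truth detection in its session; a track is pure when every
    observation maps to the same true cell_id and that cell maps to no other
    track... (purity here: single dominant id across all its observations).
    """
    if not tracks:
        return float("nan")
    by_session = {
        t: g for t, g in truth_detections.groupby("session_h")
    }
    pure = 0
    for track in tracks:
        ids = []
        for row in track.observations.itertuples():
            g = by_session.get(row.session_h)
            if g is None or len(g) == 0:
                ids.append(-1)
                continue
            xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
            d = np.hypot(xy[:, 0] - row.x_um, xy[:, 1] - row.y_um)
            ids.append(int(g["cell_id"].to_numpy()[np.argmin(d)]))
        if len(set(ids)) == 1 and ids[0] != -1:
            pure += 1
    return pure / len(tracks)
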