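"""Config-driven orchestration: simulate -> track -> summarize -> spatial.

A run is described by a nested config dict (usually loaded from YAML),
validated and normalized by :func:`validate_config`, and executed by
:func:`run_pipeline`, which writes all intermediate tables (detections,
tracks, KM curves, enrichment histograms) plus a machine-readable
``report.json``.  All randomness flows from the single run seed through
``numpy.random.SeedSequence`` spawns, so rerunning the same config
reproduces every number exactly.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fatestats import compare_groups, km_retention, summarize_group
from .params import FateParams, FieldGeometry, TissueParams
from .profiles import PROFILES, default_geometry, default_tissue_params
from .spatial import (
    combined_fold_enrichment,
    fold_enrichment,
    histogram_from_distances,
    permutation_null,
)
from .synthetic import (
    CohortResult,
    markov_endpoints,
    simulate_cohort,
    simulate_tissue_with_true_ratio,
)
from .tracking import classify_tracks, link_detections, tracks_to_frame

log = logging.getLogger("lungfate")

DEFAULT_CONFIG: dict = {
    "mode": "simulate_and_analyze",
    "seed": 0,
    "outdir": "lungfate-run",
    "groups": {
        "SM": {"profile": "SM", "n_animals": 4},
        "EM": {"profile": "EM", "n_animals": 4},
    },
    "geometry": {},
    "tissue": {
        "enabled": True,
        "params": {},
        "bounds_um": [1700.0, 1700.0],
        "n_tissues": 8,
        "target_ratio": 2.2,
        "n_perm": 199,
    },
    "tracking": {"gate_um": 20.0, "debris_max_area_um2": 50.0},
    "inputs": {},          # analyze_existing: group -> detections CSV path
}


@dataclass
class RunConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.raw["outdir"])

    def geometry(self) -> FieldGeometry:
        return default_geometry(**self.raw.get("geometry", {}))

    def fate_params(self, group: str) -> FateParams:
        spec = self.raw["groups"][group]
        profile = spec.get("profile")
        overrides = spec.get("fate_params", {})
        if profile is not None:
            return PROFILES[profile](**overrides)
        return FateParams(**overrides).ensure_valid()

    def tissue_params(self) -> TissueParams:
        return default_tissue_params(**self.raw["tissue"].get("params", {}))

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> tuple[RunConfig | None, list[str]]:
    """Fill defaults and enumerate every constraint violation.

    Returns ``(RunConfig, [])`` on success or ``(None, errors)`` with the
    full error list (not just the first)."""
    raw = _merge(DEFAULT_CONFIG, config or {})
    if config and config.get("groups"):
        # an explicit group list replaces the default roster; per-group
        # defaults (profiles) still merge in for names shared with it
        raw["groups"] = {k: raw["groups"][k] for k in config["groups"]}
    errors: list[str] = []
    if raw["mode"] not in ("simulate_and_analyze", "analyze_existing"):
        errors.append(f"mode: unknown mode {raw['mode']!r}")
    if raw["mode"] == "simulate_and_analyze" and raw.get("seed") is None:
        errors.append("seed: mandatory in simulate_and_analyze mode")
    if not raw.get("groups"):
        errors.append("groups: at least one group required")
    for name, spec in (raw.get("groups") or {}).items():
        profile = spec.get("profile")
        if profile is not None and profile not in PROFILES:
            errors.append(
                f"groups.{name}.profile: unknown profile {profile!r} "
                f"(have {sorted(PROFILES)})"
            )
            continue
        try:
            params = (PROFILES[profile](**spec.get("fate_params", {}))
                      if profile is not None
                      else FateParams(**spec.get("fate_params", {})))
        except TypeError as exc:
            errors.append(f"groups.{name}.fate_params: {exc}")
            continue
        errors.extend(f"groups.{name}.{e}" for e in params.validate())
        if spec.get("n_animals", 1) < 1:
            errors.append(f"groups.{name}.n_animals: must be >= 1")
    try:
        geom = FieldGeometry(**raw.get("geometry", {}))
        errors.extend(f"geometry.{e}" for e in geom.validate())
    except TypeError as exc:
        errors.append(f"geometry: {exc}")
    if raw["tissue"].get("enabled", True):
        try:
            tp = TissueParams(**raw["tissue"].get("params", {}))
            errors.extend(f"tissue.{e}" for e in tp.validate())
        except TypeError as exc:
            errors.append(f"tissue.params: {exc}")
        if raw["tissue"].get("n_perm", 199) < 100:
            errors.append("tissue.n_perm: must be >= 100")
    if raw["mode"] == "analyze_existing":
        for name in (raw.get("groups") or {}):
            path = (raw.get("inputs") or {}).get(name)
            if path is None:
                errors.append(f"inputs.{name}: detections path required in "
                              "analyze_existing mode")
            elif not Path(path).exists():
                errors.append(f"inputs.{name}: path {path} does not exist")
    if errors:
        return None, errors
    return RunConfig(raw), []


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    return yaml.safe_load(Path(path).read_text()) or {}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _analyze_cohort(res: CohortResult, cfg: RunConfig, animal_id: str):
    """Link and fate-classify one animal's detections."""
    dets = res.detections
    dt = res.params.interval_h
    pre = dets[dets.session_h < 0]
    sessions = [float(t) for t in res.session_times_h if t >= 0]
    tables = [dets[dets.session_h == t] for t in sessions]
    censor_log = res.censoring
    if len(censor_log):
        # attach last observed positions so the tracker can match log entries
        last = (dets[dets.kind == "cell"]
                .sort_values("session_h").groupby("cell_id").last())
        censor_log = censor_log.join(last[["x_um", "y_um"]], on="cell_id")
    tracks = link_detections(
        tables, sessions,
        gate_um=cfg.raw["tracking"]["gate_um"],
        pre_detections=pre,
        debris_max_area_um2=cfg.raw["tracking"]["debris_max_area_um2"],
    )
    classify_tracks(
        tracks, tables, sessions,
        interval_h=dt, horizon_h=res.params.horizon_h,
        single_cell_area_um2=res.geometry.single_cell_area_um2,
        debris_max_area_um2=cfg.raw["tracking"]["debris_max_area_um2"],
        gate_um=cfg.raw["tracking"]["gate_um"],
        censoring_log=censor_log if len(censor_log) else None,
    )
    for t in tracks:
        t.animal_id = animal_id
    return tracks


def _analyze_existing_group(path: str, cfg: RunConfig) -> list:
    dets = pd.read_csv(path)
    pre = dets[dets.session_h < 0]
    sessions = sorted(t for t in dets["session_h"].unique() if t >= 0)
    tables = [dets[dets.session_h == t] for t in sessions]
    tracks = link_detections(
        tables, [float(t) for t in sessions],
        gate_um=cfg.raw["tracking"]["gate_um"],
        pre_detections=pre if len(pre) else None,
        debris_max_area_um2=cfg.raw["tracking"]["debris_max_area_um2"],
    )
    dt = float(np.diff(sessions).min()) if len(sessions) > 1 else 8.0
    horizon = float(cfg.raw.get("horizon_h", 64.0))
    classify_tracks(
        tracks, tables, [float(t) for t in sessions],
        interval_h=dt, horizon_h=horizon,
        single_cell_area_um2=cfg.geometry().single_cell_area_um2,
    )
    animal = dets["animal_id"].iloc[0] if "animal_id" in dets else "animal-0"
    for t in tracks:
        t.animal_id = str(animal)
    return tracks


def _spatial_stage(cfg: RunConfig, seed_seq: np.random.SeedSequence, outdir: Path) -> dict:
    tcfg = cfg.raw["tissue"]
    params = cfg.tissue_params()
    bounds = tuple(tcfg["bounds_um"])
    n_tissues = int(tcfg["n_tissues"])
    target = float(tcfg["target_ratio"])
    folds, tables, hists = [], [], []
    child = seed_seq.spawn(n_tissues + 1)
    for i in range(n_tissues):
        pattern, truth, e_amp = simulate_tissue_with_true_ratio(
            target, params, bounds, np.random.default_rng(child[i])
        )
        d = truth["distance_to_tmem_um"].to_numpy()
        hist = histogram_from_distances(d[pattern.marker_pos_idx], d)
        hists.append(hist)
        folds.append(fold_enrichment(hist))
        tables.append(pd.DataFrame({
            "tissue": i,
            "bin_lo_um": hist.bin_edges_um[:-1],
            "bin_hi_um": hist.bin_edges_um[1:],
            "counts_query": hist.counts_query,
            "counts_reference": hist.counts_reference,
            "normalized_ratio": hist.normalized_ratio,
        }))
        if i == 0:
            perm = permutation_null(
                pattern, int(tcfg["n_perm"]), np.random.default_rng(child[-1])
            )
    pd.concat(tables, ignore_index=True).to_csv(
        outdir / "enrichment_histograms.csv", index=False
    )
    folds = np.asarray(folds)
    return {
        "target_ratio": target,
        "n_tissues": n_tissues,
        "fold_enrichment_per_tissue": [float(f) for f in folds],
        "mean_fold_enrichment": float(np.nanmean(folds)),
        "combined_fold_enrichment": combined_fold_enrichment(hists),
        "sem_fold_enrichment": float(np.nanstd(folds, ddof=1) / np.sqrt(len(folds))),
        "permutation_p_first_tissue": perm["p_value"],
    }


def run_pipeline(config: dict | RunConfig) -> dict:
    """Execute the enabled stages and write the run report.

    Returns the report dict; raises :class:`StageError` on a stage failure
    (partial outputs remain in the output directory next to a
    ``FAILED.<stage>`` marker)."""
    if isinstance(config, RunConfig):
        cfg = config
    else:
        cfg, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "lungfate", "version": __version__},
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.raw,
        "groups": {},
    }
    root_seq = np.random.SeedSequence(cfg.seed)
    group_names = list(cfg.raw["groups"])
    group_seqs = root_seq.spawn(len(group_names) + 1)
    stage = "setup"
    try:
        tracks_by_group: dict[str, list] = {}
        for gi, name in enumerate(group_names):
            stage = f"cohort:{name}"
            t0 = time.perf_counter()
            spec = cfg.raw["groups"][name]
            if cfg.raw["mode"] == "analyze_existing":
                tracks = _analyze_existing_group(cfg.raw["inputs"][name], cfg)
            else:
                params = cfg.fate_params(name)
                n_animals = int(spec.get("n_animals", 1))
                animal_seqs = group_seqs[gi].spawn(n_animals)
                tracks = []
                all_dets = []
                for a in range(n_animals):
                    res = simulate_cohort(
                        params, cfg.geometry(),
                        np.random.default_rng(animal_seqs[a]),
                    )
                    animal = f"{name}-animal-{a}"
                    dets = res.detections.assign(animal_id=animal)
                    all_dets.append(dets)
                    tracks.extend(_analyze_cohort(res, cfg, animal))
                pd.concat(all_dets, ignore_index=True).to_csv(
                    outdir / f"detections_{name}.csv", index=False
                )
                report["groups"].setdefault(name, {})["true_endpoints"] = {
                    k: (float(v) if np.isscalar(v) else None)
                    for k, v in markov_endpoints(params).items()
                    if np.isscalar(v)
                }
            tracks_by_group[name] = tracks
            tracks_to_frame(tracks).to_csv(outdir / f"tracks_{name}.csv", index=False)
            stage = f"summary:{name}"
            params_for_grid = (cfg.fate_params(name)
                               if cfg.raw["mode"] != "analyze_existing" else None)
            dt = params_for_grid.interval_h if params_for_grid else 8.0
            horizon = params_for_grid.horizon_h if params_for_grid else 64.0
            summary = summarize_group(tracks, name, dt, horizon)
            summary.km_curve.to_csv(outdir / f"km_{name}.csv", index=False)
            report["groups"].setdefault(name, {})["summary"] = summary.to_dict()
            log.info("group %s done in %.2fs", name, time.perf_counter() - t0)

        if len(tracks_by_group) == 2:
            stage = "km_comparison"
            km = km_retention(tracks_by_group)
            report["logrank"] = km["logrank"]
            stage = "group_comparison"
            per_animal = {
                name: np.asarray([
                    v for v in report["groups"][name]["summary"]["per_animal"]
                    ["pct_extravasated"] if np.isfinite(v)
                ])
                for name in group_names
            }
            if all(len(v) >= 2 for v in per_animal.values()):
                report["extravasation_comparison"] = {
                    k: (v if not isinstance(v, pd.DataFrame)
                        else v.to_dict(orient="list"))
                    for k, v in compare_groups(per_animal).items()
                }

        if cfg.raw["tissue"].get("enabled", True):
            stage = "spatial"
            t0 = time.perf_counter()
            report["spatial"] = _spatial_stage(cfg, group_seqs[-1], outdir)
            log.info("spatial stage done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        (outdir / f"FAILED.{stage.replace(':', '_')}").write_text(str(exc))
        raise StageError(stage, exc) from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(obj)}")
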