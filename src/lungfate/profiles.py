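"""Shipped calibration profiles for the synthetic cohort generator.

The intravital literature reports endpoint percentages, not per-interval
hazards, so the hazards here were calibrated once against the closed-form
chain endpoints (:func:`lungfate.synthetic.markov_endpoints`) to reproduce
the published endpoint pattern of each model, and then frozen.  They are
calibration inputs for synthetic scenarios, not measured quantities.

``SM`` (spontaneous metastasis, cells disseminating from a primary tumor):
high retention (~70% at 64 h), efficient fast extravasation (64% by 64 h,
mean ~11.6 h, about half within the first 8-h interval) and high
post-extravasation survival (84% single / 13% died / 3% grew).

``EM`` (experimental metastasis, tail-vein injected): rapid clearance (~5%
retained at 64 h), inefficient late extravasation (16%, mean ~28 h, none in
the first interval) and poor survival (10% single / 72% died / 18% grew).
"""

from __future__ import annotations

from .params import FateParams, FieldGeometry, TissueParams

# Extravasation hazard ramps by intervals since arrival (logistic-in-k shape
# from the calibration fit; see module docstring).
_EM_P_EXTRAVASATE = (0.0107, 0.0294, 0.0720, 0.1411, 0.2089, 0.2494, 0.2669, 0.2734)
_SM_P_EXTRAVASATE = (0.3342, 0.2578, 0.1867, 0.1280, 0.0841, 0.0535, 0.0334, 0.0205)


def em_fate_params(**overrides) -> FateParams:
    """EM-model calibration: one bolus arrival interval, rapid clearance."""
    base = dict(
        interval_h=8.0,
        horizon_h=64.0,
        arrival_rate=60.0,
        n_arrival_intervals=1,
        n_preexisting=0,
        p_disappear=0.3157,
        p_extravasate=_EM_P_EXTRAVASATE,
        p_die=0.4372,
        p_grow=0.1093,
        censor_prob=0.0,
    )
    base.update(overrides)
    return FateParams(**base).ensure_valid()


def sm_fate_params(**overrides) -> FateParams:
    """SM-model calibration: ongoing arrivals, high retention and survival."""
    base = dict(
        interval_h=8.0,
        horizon_h=64.0,
        arrival_rate=8.0,
        n_arrival_intervals=8,
        n_preexisting=4,
        p_disappear=0.0708,
        p_extravasate=_SM_P_EXTRAVASATE,
        p_die=0.0232,
        p_grow=0.0054,
        censor_prob=0.0,
    )
    base.update(overrides)
    return FateParams(**base).ensure_valid()


def default_geometry(**overrides) -> FieldGeometry:
    base = dict(field_size_um=512.0, pixel_size_um=1.0)
    base.update(overrides)
    return FieldGeometry(**base).ensure_valid()


def default_tissue_params(**overrides) -> TissueParams:
    """Primary-tumor tissue defaults: ~2000 nuclei/mm^2 in 1-3 mm^2 ROIs,
    ~3.5 TMEM doorways per mm^2, 10% baseline marker positivity."""
    base = dict(
        nuclei_density=2000.0,
        tmem_count=10,
        macrophage_density=40.0,
        baseline_pos_frac=0.10,
        enrichment_amp=2.0,
        decay_len_um=40.0,
    )
    base.update(overrides)
    return TissueParams(**base).ensure_valid()


PROFILES = {"EM": em_fate_params, "SM": sm_fate_params}
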