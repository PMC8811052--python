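"""Parameter containers for the synthetic cohort, field geometry, and tissue models.

All lengths are micrometers, all times hours, all densities per mm**2 unless a
field name says otherwise.  Containers are plain dataclasses; ``validate()``
returns the full list of constraint violations (so a config checker can report
them all at once) and ``ensure_valid()`` raises :class:`ConfigurationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "FateParams",
    "FieldGeometry",
    "TissueParams",
]


class ConfigurationError(ValueError):
    """A parameter set violates one of its documented invariants."""


def _as_hazard(value: float | Sequence[float], n_intervals: int) -> np.ndarray:
    """Broadcast a scalar or per-interval hazard to a length-``n_intervals`` array."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n_intervals, float(arr[0]))
    if arr.size < n_intervals:
        # pad with the last value: a short profile extends at its final hazard
        return np.concatenate([arr, np.full(n_intervals - arr.size, arr[-1])])
    return arr[:n_intervals].copy()


@dataclass
class FateParams:
    """Discrete-time hazards driving a simulated lung-window cohort.

    The fate chain is first-order Markov over observation intervals of
    ``interval_h`` hours.  Hazards are indexed by intervals since the cell's
    arrival; scalars are broadcast to every interval.

    ``p_disappear[k]``  P(intravascular cell absent at next session)
    ``p_extravasate[k]`` P(intravascular cell crosses into parenchyma)
    ``p_die[k]``        P(extravasated single cell dies, leaving debris)
    ``p_grow[k]``       P(surviving extravasated cell begins growth)
    """

    interval_h: float = 8.0
    horizon_h: float = 64.0
    arrival_rate: float = 5.0
    p_disappear: float | Sequence[float] = 0.05
    p_extravasate: float | Sequence[float] = 0.1
    p_die: float | Sequence[float] = 0.05
    p_grow: float | Sequence[float] = 0.02
    censor_prob: float = 0.0
    n_arrival_intervals: int = 8
    n_preexisting: int = 0

    @property
    def n_intervals(self) -> int:
        return int(round(self.horizon_h / self.interval_h))

    def hazard(self, name: str) -> np.ndarray:
        return _as_hazard(getattr(self, name), self.n_intervals)

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.interval_h <= 0:
            errors.append("interval_h must be positive")
            return errors
        ratio = self.horizon_h / self.interval_h
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            errors.append(
                f"horizon_h ({self.horizon_h}) must be a positive integer "
                f"multiple of interval_h ({self.interval_h})"
            )
            return errors
        k = self.n_intervals
        pd_, pe = self.hazard("p_disappear"), self.hazard("p_extravasate")
        pm, pg = self.hazard("p_die"), self.hazard("p_grow")
        for name, arr in [
            ("p_disappear", pd_), ("p_extravasate", pe), ("p_die", pm), ("p_grow", pg),
        ]:
            if np.any(arr < 0) or np.any(arr > 1):
                errors.append(f"{name} must lie in [0, 1]")
        if np.any(pd_ + pe > 1 + 1e-12):
            errors.append(
                "p_disappear + p_extravasate exceeds 1 in at least one interval "
                f"(max {float((pd_ + pe).max()):.3f}); fields p_disappear, p_extravasate"
            )
        if np.any(pm + pg > 1 + 1e-12):
            errors.append(
                "p_die + p_grow exceeds 1 in at least one interval "
                f"(max {float((pm + pg).max()):.3f}); fields p_die, p_grow"
            )
        if self.arrival_rate < 0:
            errors.append("arrival_rate must be non-negative")
        if not 0 <= self.censor_prob <= 1:
            errors.append("censor_prob must lie in [0, 1]")
        if self.n_arrival_intervals < 1:
            errors.append("n_arrival_intervals must be >= 1")
        if self.n_preexisting < 0:
            errors.append("n_preexisting must be >= 0")
        return errors

    def ensure_valid(self) -> "FateParams":
        errors = self.validate()
        if errors:
            raise ConfigurationError("; ".join(errors))
        return self

    def replace(self, **kwargs) -> "FateParams":
        return replace(self, **kwargs)


@dataclass
class FieldGeometry:
    """Geometry of one imaging field and of the objects rendered into it."""

    field_size_um: float = 512.0
    pixel_size_um: float = 1.0
    vessel_width_um: float = 10.0
    vessel_density: float = 0.15
    cell_radius_um: float = 8.0
    debris_radius_um: float = 2.5
    noise_sd: float = 4.0
    psf_sigma_um: float = 1.0
    cell_intensity: float = 200.0
    vessel_intensity: float = 150.0
    debris_intensity: float = 150.0
    growth_area_factor: float = 2.5
    jitter_sd_um: float = 1.0

    @property
    def center_to_boundary_um(self) -> float:
        # distance from the field center to its boundary
        return self.field_size_um / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        n = int(round(self.field_size_um / self.pixel_size_um))
        return (n, n)

    @property
    def single_cell_area_um2(self) -> float:
        return float(np.pi * self.cell_radius_um**2)

    def validate(self) -> list[str]:
        errors = []
        for name in ("field_size_um", "pixel_size_um", "vessel_width_um",
                     "cell_radius_um", "debris_radius_um"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not 0 < self.vessel_density < 1:
            errors.append("vessel_density must lie in (0, 1)")
        if self.noise_sd < 0:
            errors.append("noise_sd must be non-negative")
        return errors

    def ensure_valid(self) -> "FieldGeometry":
        errors = self.validate()
        if errors:
            raise ConfigurationError("; ".join(errors))
        return self


@dataclass
class TissueParams:
    """Primary-tumor tissue point-pattern model.

    Nuclei form a homogeneous Poisson pattern; each nucleus is marker-positive
    with probability ``p(d) = baseline_pos_frac * (1 + (E - 1) * exp(-d / tau))``
    where ``d`` is its distance to the nearest TMEM doorway (after the 60 um
    ROI dilation used by the distance statistic, so ``d = 0`` inside the
    dilated doorway ROI).
    """

    nuclei_density: float = 2000.0      # nuclei per mm^2
    tmem_count: int = 10
    macrophage_density: float = 40.0    # macrophages per mm^2, doorway Mphi extra
    vessel_density: float = 0.05
    baseline_pos_frac: float = 0.10
    enrichment_amp: float = 2.0         # E: multiplicative excess at d = 0
    decay_len_um: float = 40.0          # tau
    macrophage_roi_radius_um: float = 5.0
    dilation_um: float = 60.0

    def positive_prob(self, d: np.ndarray | float) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p = self.baseline_pos_frac * (
            1.0 + (self.enrichment_amp - 1.0) * np.exp(-d / self.decay_len_um)
        )
        return p

    def validate(self) -> list[str]:
        errors = []
        if not 0 < self.baseline_pos_frac <= 1:
            errors.append("baseline_pos_frac must lie in (0, 1]")
        if self.enrichment_amp < 1:
            errors.append("enrichment_amp must be >= 1")
        if self.decay_len_um <= 0:
            errors.append("decay_len_um must be positive")
        if self.baseline_pos_frac * self.enrichment_amp > 1 + 1e-12:
            errors.append(
                "positive probability exceeds 1 at distance 0 "
                "(baseline_pos_frac * enrichment_amp > 1)"
            )
        if self.nuclei_density <= 0:
            errors.append("nuclei_density must be positive")
        if self.tmem_count < 0:
            errors.append("tmem_count must be >= 0")
        if self.macrophage_density < 0:
            errors.append("macrophage_density must be >= 0")
        return errors

    def ensure_valid(self) -> "TissueParams":
        errors = self.validate()
        if errors:
            raise ConfigurationError("; ".join(errors))
        return self

    def replace(self, **kwargs) -> "TissueParams":
        return replace(self, **kwargs)
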