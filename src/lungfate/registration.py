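"""Field relocation and drift removal by translation registration.

The lung-window fixturing constrains inter-session motion to an x-y shift, so
both relocating a field across 8-h sessions and removing residual drift within
a time-lapse stack are modelled as integer-pixel translations estimated by
phase correlation.  A normalized cross-correlation score in [0, 1] quantifies
match quality; relocation picks the candidate with the best score on the
vasculature channel and fails when no candidate scores above ``min_score``
(the downstream pipeline then censors tracks at that session).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .images import FieldImage

DEFAULT_MIN_SCORE = 0.5


class DegenerateImageError(ValueError):
    """An image carries no registration information (zero variance)."""


class RelocationError(RuntimeError):
    """No candidate field matched the reference above the score floor."""


@dataclass
class Transform2D:
    """A 2D alignment: integer-pixel translation or 2x3 affine matrix."""

    kind: str = "translation"            # "translation" | "affine"
    dy_px: int = 0
    dx_px: int = 0
    matrix: np.ndarray | None = None     # 2x3, maps moving (x, y) -> fixed
    score: float = 1.0                   # match quality in [0, 1]
    rms_residual_um: float = 0.0

    def apply_to_image(self, image: np.ndarray) -> np.ndarray:
        if self.kind != "translation":
            raise NotImplementedError("image warping implemented for translations only")
        return np.roll(np.roll(image, self.dy_px, axis=0), self.dx_px, axis=1)

    def apply_to_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        if self.kind == "translation":
            return xy + np.array([self.dx_px, self.dy_px], dtype=float)
        ones = np.ones((xy.shape[0], 1))
        return np.hstack([xy, ones]) @ self.matrix.T


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape images, clipped to [0, 1]."""
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(np.clip((a @ b) / denom, 0.0, 1.0))


def estimate_translation(
    reference: FieldImage, moving: FieldImage, channel_role: str = "vasculature"
) -> Transform2D:
    """Integer-pixel translation aligning ``moving`` onto ``reference``.

    Phase correlation on the stated channel; the returned score is the
    normalized cross-correlation after applying the shift.  Raises
    :class:`DegenerateImageError` for a flat (zero-variance) channel.
    """
    ref = np.asarray(reference.channel(channel_role), dtype=float)
    mov = np.asarray(moving.channel(channel_role), dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if reference.pixel_size_um != moving.pixel_size_um:
        raise ValueError("pixel sizes differ between reference and moving image")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise DegenerateImageError("flat image: translation is unidentifiable")
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    t = Transform2D(kind="translation", dy_px=dy, dx_px=dx, score=0.0)
    t.score = _ncc(ref, t.apply_to_image(mov))
    return t


def relocate_field(
    reference: FieldImage,
    candidates: list[FieldImage],
    min_score: float = DEFAULT_MIN_SCORE,
    channel_role: str = "vasculature",
) -> tuple[int, Transform2D]:
    """Pick the candidate field that best matches the reference vasculature.

    Returns ``(index, transform)`` of the best-scoring candidate, or raises
    :class:`RelocationError` if the best score falls below ``min_score`` —
    the field could not be re-found this session.
    """
    if not candidates:
        raise ValueError("relocate_field requires at least one candidate")
    best_idx, best_t = -1, None
    for i, cand in enumerate(candidates):
        try:
            t = estimate_translation(reference, cand, channel_role)
        except DegenerateImageError:
            continue
        if best_t is None or t.score > best_t.score:
            best_idx, best_t = i, t
    if best_t is None or best_t.score < min_score:
        score = 0.0 if best_t is None else best_t.score
        raise RelocationError(
            f"no candidate matched the reference field (best score {score:.3f} "
            f"< min_score {min_score})"
        )
    return best_idx, best_t


def register_timelapse(
    frames: list[FieldImage], channel_role: str = "vasculature"
) -> list[Transform2D]:
    """Per-frame translations aligning a time-lapse stack to its first frame."""
    if len(frames) < 2:
        raise ValueError("register_timelapse requires at least 2 frames")
    transforms = [Transform2D(kind="translation", dy_px=0, dx_px=0, score=1.0)]
    for frame in frames[1:]:
        transforms.append(estimate_translation(frames[0], frame, channel_role))
    return transforms


def blood_average(frames: list[FieldImage], channel_role: str = "vasculature") -> FieldImage:
    """Per-pixel temporal median of one channel over registered frames.

    Suppresses the frame-to-frame serum-signal variation created by flowing
    erythrocytes; requires at least 3 frames for the median to reject a
    corrupted frame.
    """
    if len(frames) < 3:
        raise ValueError("blood_average requires at least 3 registered frames")
    stack = np.stack([np.asarray(f.channel(channel_role), dtype=float) for f in frames])
    med = np.median(stack, axis=0)
    return FieldImage(
        channels={channel_role: med},
        pixel_size_um=frames[0].pixel_size_um,
        session_time_h=frames[0].session_time_h,
        field_id=frames[0].field_id,
    )


def transforms_to_frame(transforms: list[Transform2D]):
    """Serialize a transform list to a DataFrame (frame, dy_px, dx_px, score)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": np.arange(len(transforms)),
            "dy_px": [t.dy_px for t in transforms],
            "dx_px": [t.dx_px for t in transforms],
            "score": [t.score for t in transforms],
        }
    )
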