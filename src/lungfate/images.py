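"""Multi-channel field images and their TIFF serialization.

A :class:`FieldImage` is one imaging session of one lung-window field: a map
of channel role (``tumor``, ``vasculature``, ``structural``) to a 2D intensity
array, plus the pixel size and session timestamp.  Images round-trip through
multi-page TIFF (one page per channel) with the channel roles and metadata in
the ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_ROLES = ("tumor", "vasculature", "structural")


@dataclass
class FieldImage:
    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    session_time_h: float = 0.0
    field_id: str = "field-0"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel role {role!r} not present; have {sorted(self.channels)}"
            ) from None

    def write_tiff(self, path: str | Path) -> None:
        roles = list(self.channels)
        stack = np.stack([np.asarray(self.channels[r], dtype=np.float32) for r in roles])
        meta = {
            "channel_roles": roles,
            "pixel_size_um": self.pixel_size_um,
            "session_time_h": self.session_time_h,
            "field_id": self.field_id,
        }
        tifffile.imwrite(path, stack, description=json.dumps(meta))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "FieldImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if stack.ndim == 2:
            stack = stack[None]
        channels = {role: stack[i] for i, role in enumerate(meta["channel_roles"])}
        return cls(
            channels=channels,
            pixel_size_um=float(meta["pixel_size_um"]),
            session_time_h=float(meta["session_time_h"]),
            field_id=str(meta["field_id"]),
        )
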