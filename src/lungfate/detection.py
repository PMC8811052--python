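"""Cell segmentation, marker thresholding, and object counting.

Detection tables are pandas DataFrames with the column contract
``cell_id, session_h (optional), x_um, y_um, area_um2, mean_intensity``
plus marker-call columns.  Thresholds are :class:`ThresholdSpec` records
carrying their provenance so the same cutoff can be re-applied unchanged to
other tissues (the high-marker calibration is derived once on a reference
population and then frozen).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .images import FieldImage

MACROPHAGE_MIN_AREA_UM2 = 19.0
FOCI_MIN_CELLS = 6           # "> 5 tumor cells"
FOCI_LINK_DISTANCE_UM = 30.0


@dataclass
class ThresholdSpec:
    """An intensity cutoff with its derivation recorded.

    methods: ``negative_control`` (quantile of control pixels),
    ``top_fraction_calibration`` (reference-population order statistic),
    ``manual``.
    """

    marker: str
    method: str
    value: float
    calibration_fraction: float | None = None
    quantile: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")
        if self.calibration_fraction is not None and not (
            0 < self.calibration_fraction < 1
        ):
            raise ValueError("calibration_fraction must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSpec":
        return cls(**json.loads(Path(path).read_text()))


def _watershed_split(binary: np.ndarray, min_peak_separation_px: int = 4) -> np.ndarray:
    """Split touching objects by watershed on the distance transform.

    The distance map is lightly smoothed before peak finding so plateaus in
    near-symmetric objects do not spawn spurious seeds."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        ndi.gaussian_filter(distance, 1.0),
        min_distance=min_peak_separation_px, labels=binary,
        exclude_border=False,
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(binary)
        return labels
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-distance, markers=markers, mask=binary)


def segment_cells(
    image: FieldImage,
    channel_role: str = "tumor",
    min_area_um2: float = 50.0,
    threshold: float = 0.0,
    split_touching: bool = True,
) -> pd.DataFrame:
    """Segment suprathreshold objects on one channel into a detection table.

    Connected components above ``threshold`` are watershed-split, filtered by
    ``min_area_um2``, and reported with centroids and areas in um using the
    image pixel size.  Rows are ordered deterministically by (y, x).  An
    empty image yields an empty table, not an error.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    img = np.asarray(image.channel(channel_role), dtype=float)
    px = image.pixel_size_um
    binary = img > threshold
    labels = _watershed_split(binary) if split_touching else ndi.label(binary)[0]
    rows = []
    for prop in regionprops(labels, intensity_image=img):
        area_um2 = prop.area * px**2
        if area_um2 < min_area_um2:
            continue
        cy, cx = prop.centroid
        rows.append(dict(
            x_um=cx * px, y_um=cy * px, area_um2=area_um2,
            mean_intensity=float(prop.intensity_mean),
            label=int(prop.label),
        ))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2",
                                     "mean_intensity", "label"])
    df = df.sort_values(["y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "cell_id", np.arange(len(df)))
    df["session_h"] = image.session_time_h
    return df


def derive_threshold_negative_control(
    control_image: FieldImage | np.ndarray,
    marker: str = "marker",
    quantile: float = 0.999,
    channel_role: str = "tumor",
) -> ThresholdSpec:
    """Positivity cutoff "just above background" from a negative control.

    The cutoff is the stated quantile (default 99.9%) of the control-image
    pixel intensities: deterministic and robust to isolated hot pixels.
    """
    if isinstance(control_image, FieldImage):
        pixels = np.asarray(control_image.channel(channel_role), dtype=float)
    else:
        pixels = np.asarray(control_image, dtype=float)
    if pixels.size == 0:
        raise ValueError("empty negative control")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    value = float(np.quantile(pixels, quantile))
    return ThresholdSpec(
        marker=marker, method="negative_control", value=value, quantile=quantile,
        provenance=f"{quantile:.4g} quantile of {pixels.size} negative-control pixels",
    )


def calibrate_high_threshold(
    reference_intensities: np.ndarray,
    marker: str = "marker",
    fraction: float = 0.05,
) -> ThresholdSpec:
    """Cutoff such that ~``fraction`` of the reference cells call "high".

    The cutoff is the (1 - fraction) quantile of the reference per-cell mean
    intensities; positivity is *strictly greater than* the cutoff, so ties
    default to negative.  The returned spec is meant to be reused unchanged
    on other tissues.
    """
    x = np.asarray(reference_intensities, dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 reference cells to calibrate a high threshold")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    value = float(np.quantile(x, 1 - fraction))
    n_high = int(np.sum(x > value))
    if n_high == 0 and np.ptp(x) == 0:
        warnings.warn(
            "all reference intensities equal; 0% of cells call high", stacklevel=2
        )
    return ThresholdSpec(
        marker=marker, method="top_fraction_calibration", value=value,
        calibration_fraction=fraction,
        provenance=f"(1 - {fraction}) quantile of {x.size} reference cells "
                   f"({n_high} call high)",
    )


def call_marker(intensities: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Vector of marker calls ('positive'/'high' vs 'negative') per cell."""
    x = np.asarray(intensities, dtype=float)
    label = "high" if spec.method == "top_fraction_calibration" else "positive"
    return np.where(x > spec.value, label, "negative")


def count_macrophages(
    image: FieldImage,
    channel_role: str = "structural",
    threshold: float | ThresholdSpec = 0.0,
    min_area_um2: float = MACROPHAGE_MIN_AREA_UM2,
) -> tuple[int, pd.DataFrame]:
    """Count macrophages on a stained channel.

    Threshold, watershed-split touching cells, then count objects with area
    strictly greater than ``min_area_um2`` (default 19 um**2).  Returns the
    count and the object table (all objects, with a ``counted`` flag).
    """
    thr = threshold.value if isinstance(threshold, ThresholdSpec) else float(threshold)
    objects = segment_cells(image, channel_role, min_area_um2=0.0, threshold=thr)
    counted = objects["area_um2"] > min_area_um2
    table = objects.assign(counted=counted)
    return int(counted.sum()), table


def nuclear_intensity_profile(
    marker_image: FieldImage | np.ndarray,
    nuclei_mask: np.ndarray,
    channel_role: str = "tumor",
) -> pd.DataFrame:
    """Per-nucleus mean marker intensity over a labeled nuclei mask.

    One row per positive integer label, ordered by label index; nuclei
    clipped by the image border are averaged over their in-bounds pixels.
    """
    if isinstance(marker_image, FieldImage):
        img = np.asarray(marker_image.channel(channel_role), dtype=float)
    else:
        img = np.asarray(marker_image, dtype=float)
    mask = np.asarray(nuclei_mask)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["nucleus_label", "mean_intensity", "area_px"])
    means = ndi.mean(img, labels=mask, index=labels)
    areas = ndi.sum_labels(np.ones_like(img), labels=mask, index=labels)
    return pd.DataFrame({
        "nucleus_label": labels.astype(int),
        "mean_intensity": means,
        "area_px": areas.astype(int),
    })


def cluster_detections(
    detections: pd.DataFrame, link_distance_um: float = FOCI_LINK_DISTANCE_UM
) -> np.ndarray:
    """Single-linkage clustering of detections at a contact distance.

    Two cells belong to the same focus when a chain of pairwise distances
    <= ``link_distance_um`` connects them.  Returns a cluster label per row.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree
    from scipy.sparse import coo_matrix

    xy = detections[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(xy)
    if n == 0:
        return np.zeros(0, dtype=int)
    pairs = cKDTree(xy).query_pairs(link_distance_um, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def count_met_foci(
    detections: pd.DataFrame,
    tissue_area_mm2: float,
    min_cells: int = FOCI_MIN_CELLS,
    link_distance_um: float = FOCI_LINK_DISTANCE_UM,
) -> tuple[float, pd.DataFrame]:
    """Metastatic foci (clusters of > 5 tumor cells) per mm**2 of tissue.

    Detections are grouped by single-linkage contact clustering; clusters
    with at least ``min_cells`` members count as foci; the result is
    normalized to the tissue area.  Returns (foci per mm**2, cluster table).
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue_area_mm2 must be positive")
    labels = cluster_detections(detections, link_distance_um)
    if len(labels) == 0:
        return 0.0, pd.DataFrame(columns=["cluster", "n_cells", "is_focus"])
    sizes = pd.Series(labels).value_counts().sort_index()
    table = pd.DataFrame({
        "cluster": sizes.index, "n_cells": sizes.to_numpy(),
    })
    table["is_focus"] = table["n_cells"] >= min_cells
    return float(table["is_focus"].sum() / tissue_area_mm2), table
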