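"""Fixed-cell and endpoint analyses: shape metrics, object filtering,
perinuclear quantification, hotspot ratios, and adhesion-area change.

Shape metrics follow the standard region-properties definitions: eccentricity
is the interfocal distance over the major axis of the second-central-moment
ellipse, solidity is object area over convex-hull area. Object filtering keeps
cells above a pixel-area threshold containing exactly one nucleus.
Perinuclear quantification dilates each nucleus by a disk and reports the mean
marker intensity per cell, resolving overlaps by nearest nucleus. The hotspot
ratio thresholds a marker at 8× over background (median outside the cell) and
reports in-hotspot means normalized to the whole-cell mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .movie import Calibration


@dataclass
class ShapeRecord:
    """Shape and intensity descriptors of one segmented object."""

    object_id: int
    area_px: int
    area_um2: float
    eccentricity: float
    solidity: float
    major_axis_um: float
    minor_axis_um: float
    perimeter_um: float
    orientation_rad: float
    centroid: tuple[float, float]
    nucleus_count: int = -1          # -1 = not evaluated
    mean_intensities: dict | None = None

    def as_row(self) -> dict:
        row = {
            "object_id": self.object_id,
            "area_px": self.area_px,
            "area_um2": self.area_um2,
            "eccentricity": self.eccentricity,
            "solidity": self.solidity,
            "major_axis_um": self.major_axis_um,
            "minor_axis_um": self.minor_axis_um,
            "perimeter_um": self.perimeter_um,
            "orientation_rad": self.orientation_rad,
            "centroid_y": self.centroid[0],
            "centroid_x": self.centroid[1],
            "nucleus_count": self.nucleus_count,
        }
        if self.mean_intensities:
            for k, v in self.mean_intensities.items():
                row[f"mean_{k}"] = v
        return row


def shape_metrics(
    mask: np.ndarray,
    calibration: Calibration,
    object_id: int = 0,
    intensity_images: dict[str, np.ndarray] | None = None,
) -> ShapeRecord:
    """Region properties of a single connected mask, in calibrated units."""
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must be a single connected component, got {n}")
    props = regionprops(lab.astype(int))[0]
    um = calibration.um_per_px
    means = None
    if intensity_images:
        means = {
            name: float(np.asarray(img, dtype=float)[mask].mean())
            for name, img in intensity_images.items()
        }
    return ShapeRecord(
        object_id=object_id,
        area_px=int(props.area),
        area_um2=float(props.area) * um**2,
        eccentricity=float(props.eccentricity),
        solidity=float(props.solidity),
        major_axis_um=float(props.axis_major_length) * um,
        minor_axis_um=float(props.axis_minor_length) * um,
        perimeter_um=float(props.perimeter) * um,
        orientation_rad=float(props.orientation),
        centroid=(float(props.centroid[0]), float(props.centroid[1])),
        mean_intensities=means,
    )


def detect_nuclei(
    nuclear_image: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area_px: int = 50,
) -> np.ndarray:
    """Label nuclei: Gaussian smoothing, Otsu, watershed split on the EDT."""
    img = gaussian(np.asarray(nuclear_image, dtype=float), sigma=smooth_sigma)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    binary = img > threshold_otsu(img)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(binary)
    smoothed = gaussian(dist, sigma=smooth_sigma)
    peaks = label(
        smoothed == ndimage.maximum_filter(smoothed, size=7), connectivity=2
    ) * binary
    labels = watershed(-dist, markers=peaks, mask=binary)
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 0
    for region in regionprops(labels):
        if region.area >= min_area_px:
            next_id += 1
            out[labels == region.label] = next_id
    return out


def filter_objects(
    object_masks: list[np.ndarray],
    nuclei_labels: np.ndarray,
    calibration: Calibration,
    min_area_px: int = 3000,
    intensity_images: dict[str, np.ndarray] | None = None,
) -> list[ShapeRecord]:
    """Keep objects with area > ``min_area_px`` and exactly one nucleus.

    ``nuclei_labels`` is a labeled nucleus image aligned with the object
    masks. The retained records carry the nucleus count actually found.
    """
    records: list[ShapeRecord] = []
    for i, mask in enumerate(object_masks):
        mask = np.asarray(mask, dtype=bool)
        area = int(mask.sum())
        if area <= min_area_px:
            continue
        inside = np.unique(nuclei_labels[mask])
        n_nuclei = int((inside > 0).sum())
        if n_nuclei != 1:
            continue
        rec = shape_metrics(mask, calibration, object_id=i,
                            intensity_images=intensity_images)
        rec.nucleus_count = n_nuclei
        records.append(rec)
    return records


def perinuclear_quantification(
    nuclei_labels: np.ndarray,
    marker_image: np.ndarray,
    dilation_px: int = 7,
) -> dict[int, float]:
    """Mean marker intensity in disk-dilated nuclear regions, per cell.

    Pixels reached by the dilation of more than one nucleus are assigned to
    the nearest nucleus (by Euclidean distance to nucleus pixels).
    """
    nuclei_labels = np.asarray(nuclei_labels)
    marker = np.asarray(marker_image, dtype=float)
    if nuclei_labels.shape != marker.shape:
        raise ValueError("nuclei mask and marker image must share a shape")
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}
    # nearest-nucleus assignment everywhere, then crop to the dilation radius
    dist, (iy, ix) = ndimage.distance_transform_edt(
        nuclei_labels == 0, return_indices=True
    )
    owner = nuclei_labels[iy, ix]
    footprint = disk(dilation_px).astype(bool)
    dilated = ndimage.binary_dilation(nuclei_labels > 0, structure=footprint)
    region = dilated & (owner > 0)
    out: dict[int, float] = {}
    for i in ids:
        sel = region & (owner == i)
        out[int(i)] = float(marker[sel].mean()) if sel.any() else float("nan")
    return out


@dataclass
class HotspotResult:
    normalized_ratio: float      # mean ratio in hotspots / whole-cell mean
    normalized_marker: float     # mean marker in hotspots / whole-cell mean
    hotspot_fraction: float      # hotspot pixels / cell pixels
    background: float


def hotspot_ratio(
    cell_mask: np.ndarray,
    marker_image: np.ndarray,
    ratio_image: np.ndarray,
    threshold_factor: float = 8.0,
) -> HotspotResult:
    """In-hotspot ratio/marker means normalized to the whole-cell means.

    Hotspots are cell pixels whose marker intensity exceeds
    ``threshold_factor`` × background, where background is the median marker
    intensity outside the cell mask. Raises if no pixel qualifies.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    marker = np.asarray(marker_image, dtype=float)
    ratio = np.asarray(ratio_image, dtype=float)
    if not cell.any() or cell.all():
        raise ValueError("cell mask must be non-empty and leave background")
    background = float(np.median(marker[~cell]))
    hot = cell & (marker > threshold_factor * background)
    if not hot.any():
        raise ValueError("no hotspot pixels above threshold")
    whole_ratio = float(ratio[cell].mean())
    whole_marker = float(marker[cell].mean())
    if whole_ratio == 0 or whole_marker == 0:
        raise ValueError("whole-cell mean is zero")
    return HotspotResult(
        normalized_ratio=float(ratio[hot].mean()) / whole_ratio,
        normalized_marker=float(marker[hot].mean()) / whole_marker,
        hotspot_fraction=float(hot.sum()) / float(cell.sum()),
        background=background,
    )


def adhesion_area_change(mask_t0: np.ndarray, mask_t1: np.ndarray) -> float:
    """Percent change of adhesion (mask) area between two time points."""
    a0 = int(np.asarray(mask_t0, dtype=bool).sum())
    a1 = int(np.asarray(mask_t1, dtype=bool).sum())
    if a0 == 0:
        raise ValueError("initial area is zero")
    return 100.0 * (a1 - a0) / a0


def records_to_frame(records: list[ShapeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def condition_summary(records: list[ShapeRecord]) -> pd.DataFrame:
    """Mean ± SD of area, eccentricity and solidity across objects."""
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame()
    stats = df[["area_um2", "eccentricity", "solidity"]].agg(["mean", "std"])
    return stats
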