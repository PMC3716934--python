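"""Echogram fish-detection pipeline.

Stages, with their reference parameter values:

1. 3x3 median filter (reflect padding) — removes speckle and single-pixel
   artifacts.
2. Background removal with a 40x40 flat structuring element.  Implemented as
   the white top-hat (image minus its morphological opening): the opening
   estimates the slowly varying background brightness, and subtracting it
   keeps every object smaller than the element — a literal opening alone
   would erase the fish blobs it is meant to isolate.
3. Binarization at 20% of the mean brightness of the background-removed
   image (strictly-greater comparison).
4. Water-column masking: rows at or above the surface band and at or below
   the per-ping bottom line (each widened by a safety margin) are cleared.
5. 8-connected component labeling with a minimum-area filter; the unweighted
   pixel centroid of each component locates the fish.  Closely adjacent fish
   merge into one component — a documented limitation of the approach.
6. Depth from the row coordinate (``depth = row * range / rows``) and
   position by linear interpolation of the sparse GPS fixes in ping index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .echogen import Echogram
from .errors import InputError
from .survey import BeamGeometry  # noqa: F401  (re-export convenience)

log = logging.getLogger(__name__)

__all__ = [
    "DetectParams",
    "FishDetection",
    "DetectionTable",
    "preprocess",
    "binarize",
    "mask_water_column",
    "label_and_measure",
    "assign_depth",
    "assign_position",
    "detect_fish",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class DetectParams:
    """All pipeline parameters, with the reference sonar-module defaults."""

    median_size: int = 3
    opening_size: int = 40
    threshold_factor: float = 0.20
    min_area_px: int = 4
    margin_px: int = 5


@dataclass(frozen=True)
class FishDetection:
    """One labeled blob with its size, location and georeference."""

    id: int
    area_px: int
    centroid_row: float
    centroid_ping: float
    depth_m: float
    lat: float | None = None
    lon: float | None = None
    gps_valid: bool = False
    # approximate physical cross-section (m^2): area_px * (range/rows)^2,
    # assuming square pixels at the depth scale; no exact conversion exists
    volume_approx_m2: float | None = None


@dataclass
class DetectionTable:
    """Ordered detections (ids consecutive from 1) plus provenance."""

    detections: list[FishDetection] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


def _median_and_tophat(image: np.ndarray, params: DetectParams) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < params.median_size:
        raise InputError(
            f"image must be 2D and at least {params.median_size}x{params.median_size}"
        )
    med = ndimage.median_filter(image, size=params.median_size, mode="reflect")
    opened = ndimage.grey_opening(
        med, size=(params.opening_size, params.opening_size), mode="reflect"
    )
    return med, np.clip(med - opened, 0.0, None)


def preprocess(image: np.ndarray, params: DetectParams = DetectParams()) -> np.ndarray:
    """Median filter then white top-hat background removal; clipped at 0."""
    return _median_and_tophat(image, params)[1]


def binarize(
    image: np.ndarray,
    threshold_factor: float = 0.20,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold at ``threshold_factor`` times the total average brightness.

    The average is taken over ``reference`` when given, else over ``image``
    itself; the comparison is strictly greater.  The full pipeline passes the
    median-filtered input as the reference: the average of the
    background-removed residual alone is dominated by the noise floor, so a
    fraction of it can never separate noise from targets, whereas the input
    image's average retains the bright surface and bottom returns and yields
    a threshold well above the residual noise.
    """
    image = np.asarray(image, dtype=float)
    ref = image if reference is None else np.asarray(reference, dtype=float)
    return image > threshold_factor * ref.mean()


def mask_water_column(
    mask: np.ndarray,
    surface_row: int,
    bottom_profile: np.ndarray,
    margin_px: int = 5,
) -> np.ndarray:
    """Clear everything at/above the surface band and at/below the bottom line.

    Rows ``<= surface_row + margin`` and rows ``>= bottom_profile[ping] -
    margin`` are zeroed.  Raises on inverted geometry; a margin that leaves
    no water column yields an empty mask with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    bottom_profile = np.asarray(bottom_profile, dtype=int)
    if bottom_profile.shape != (mask.shape[1],):
        raise InputError("bottom_profile length must equal the ping count")
    if surface_row >= int(bottom_profile.min()):
        raise InputError("inverted geometry: surface row at or below the bottom line")
    rows = np.arange(mask.shape[0])[:, None]
    keep = (rows > surface_row + margin_px) & (rows < bottom_profile[None, :] - margin_px)
    out = mask & keep
    if not keep.any():
        log.warning("water column empty after applying margin %d px", margin_px)
    return out


def label_and_measure(
    mask: np.ndarray, min_area_px: int = 4
) -> list[tuple[int, int, tuple[float, float]]]:
    """8-connected components of at least ``min_area_px`` pixels.

    Returns ``(label, area_px, (centroid_row, centroid_ping))`` with labels
    renumbered 1..n in row-major discovery order; centroids are unweighted
    means of member pixel coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labeled, index=index).astype(int)
    centroids = ndimage.center_of_mass(mask, labeled, index=index)
    out = []
    new_id = 0
    for lab, area, com in zip(index, areas, centroids):
        if area < min_area_px:
            continue
        new_id += 1
        out.append((new_id, int(area), (float(com[0]), float(com[1]))))
    return out


def assign_depth(row: float, rows_K: int, range_m: float) -> float:
    """Depth in meters of an image row: ``row * range_m / rows_K``.

    With 1970 rows spanning a 10 m range, one meter is 197 pixels.
    """
    if range_m <= 0:
        raise InputError("range_m must be positive")
    if not 0 <= row < rows_K:
        raise InputError(f"row {row} outside [0, {rows_K})")
    return row * range_m / rows_K


def assign_position(
    ping: float, fixes: list[tuple[int, float, float]]
) -> tuple[float | None, float | None, bool]:
    """Georeference a ping by linear interpolation between bracketing GPS fixes.

    Outside the fix range the nearest fix is used; with no fixes at all the
    coordinates are absent and ``gps_valid`` is False (the echogram is still
    usable for counting, just not for mapping).
    """
    if not fixes:
        return None, None, False
    pings = np.array([f[0] for f in fixes], dtype=float)
    lats = np.array([f[1] for f in fixes], dtype=float)
    lons = np.array([f[2] for f in fixes], dtype=float)
    return float(np.interp(ping, pings, lats)), float(np.interp(ping, pings, lons)), True


def detect_fish(echogram: Echogram, params: DetectParams = DetectParams()) -> DetectionTable:
    """Run the full pipeline on one echogram and return the detection table."""
    filtered, tophat = _median_and_tophat(echogram.intensity, params)
    mask = binarize(tophat, params.threshold_factor, reference=filtered)
    n_above = int(mask.sum())
    mask = mask_water_column(mask, echogram.surface_row, echogram.bottom_profile,
                             params.margin_px)
    components = label_and_measure(mask, params.min_area_px)
    log.debug("pixels above threshold: %d; components kept: %d", n_above, len(components))
    rows_K = echogram.intensity.shape[0]
    detections = []
    for label, area, (crow, cping) in components:
        lat, lon, valid = assign_position(cping, echogram.gps_fixes)
        detections.append(FishDetection(
            id=label, area_px=area, centroid_row=crow, centroid_ping=cping,
            depth_m=assign_depth(crow, rows_K, echogram.range_m),
            lat=lat, lon=lon, gps_valid=valid,
            volume_approx_m2=area * (echogram.range_m / rows_K) ** 2,
        ))
    provenance = {
        "params": {
            "median_size": params.median_size,
            "opening_size": params.opening_size,
            "threshold_factor": params.threshold_factor,
            "min_area_px": params.min_area_px,
            "margin_px": params.margin_px,
        },
        "rows": rows_K,
        "pings": echogram.intensity.shape[1],
        "range_m": echogram.range_m,
    }
    return DetectionTable(detections=detections, provenance=provenance)
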