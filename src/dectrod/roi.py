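"""Circular-ROI statistics on 2-D parameter maps.

Mirrors the measurement step of the study: a radiologist places a circular
ROI on the solid part of the lesion or node (avoiding necrotic and cystic
portions, here represented by an exclusion mask) on the slice where the
lesion is largest, and the workstation reports the ROI mean of each
quantitative map.  Input here is already that chosen 2-D slice.

Pixel membership: a pixel belongs to the ROI iff its centre lies within
Euclidean distance ``radius`` of the ROI centre (no partial-pixel
weighting).  Coordinates are 0-based (row, col); pixel spacing is isotropic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .params import SpectralMeasurement

__all__ = ["CircularROI", "ROIError", "roi_mean", "measure_pair", "MAP_KEYS"]

#: expected parameter-map keys for measure_pair
MAP_KEYS = ("att40", "att70", "ic", "wc", "effz")


class ROIError(ValueError):
    """ROI placement or extraction error."""


@dataclass(frozen=True)
class CircularROI:
    """Circular ROI: centre (row, col) in pixels, radius in pixels."""

    center: Tuple[float, float]
    radius: float
    pixel_spacing: float = 1.0  # mm / pixel

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ROIError(f"radius must be > 0, got {self.radius}")
        if self.pixel_spacing <= 0:
            raise ROIError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")

    @property
    def area_mm2(self) -> float:
        """Nominal (continuous) ROI area, pi * (radius * spacing)^2."""
        return math.pi * (self.radius * self.pixel_spacing) ** 2

    def member_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centres lie inside the disk."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        d2 = (rows - self.center[0]) ** 2 + (cols - self.center[1]) ** 2
        return d2 <= self.radius**2


def roi_mean(
    image: np.ndarray,
    roi: CircularROI,
    exclusion_mask: Optional[np.ndarray] = None,
) -> Tuple[float, int, float]:
    """Mean map value over the ROI, with pixel count and physical area.

    Parameters
    ----------
    image : 2-D array
        Parameter map.
    roi : CircularROI
    exclusion_mask : 2-D boolean array, optional
        True marks pixels to exclude (necrotic/cystic portions).

    Returns
    -------
    (mean, n_pixels, area_mm2)
        ``area_mm2`` is the physical area of the included pixels,
        ``n_pixels * pixel_spacing**2``.

    Raises
    ------
    ROIError
        If the ROI contains no grid pixel, or none remains after exclusion.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ROIError(f"expected a 2-D map, got ndim={img.ndim}")
    member = roi.member_mask(img.shape)
    if not member.any():
        raise ROIError("ROI lies outside the grid (no pixel centre inside the disk)")
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != img.shape:
            raise ROIError(
                f"exclusion mask shape {excl.shape} does not match map shape {img.shape}"
            )
        member = member & ~excl
        if not member.any():
            raise ROIError("ROI empty after applying the exclusion mask")
    n = int(member.sum())
    return float(img[member].mean()), n, n * roi.pixel_spacing**2


def _measure_site(
    maps: Mapping[str, np.ndarray],
    roi: CircularROI,
    mask: Optional[np.ndarray],
) -> SpectralMeasurement:
    missing = set(MAP_KEYS) - set(maps)
    if missing:
        raise ROIError(f"missing parameter maps: {sorted(missing)}")
    shapes = {k: np.asarray(maps[k]).shape for k in MAP_KEYS}
    if len(set(shapes.values())) != 1:
        raise ROIError(f"parameter maps of one site must share a shape, got {shapes}")
    values: Dict[str, float] = {}
    area = None
    for k in MAP_KEYS:
        values[k], _, area = roi_mean(maps[k], roi, mask)
    return SpectralMeasurement(
        att40=values["att40"],
        att70=values["att70"],
        ic=values["ic"],
        wc=values["wc"],
        effz=values["effz"],
        roi_area=area,
    )


def measure_pair(
    lesion_maps: Mapping[str, np.ndarray],
    node_maps: Mapping[str, np.ndarray],
    lesion_roi: CircularROI,
    node_roi: CircularROI,
    lesion_mask: Optional[np.ndarray] = None,
    node_mask: Optional[np.ndarray] = None,
) -> Tuple[SpectralMeasurement, SpectralMeasurement]:
    """Measure a lesion and a node from their five co-registered maps each.

    ``lesion_maps`` / ``node_maps`` map the keys ``att40, att70, ic, wc,
    effz`` to 2-D arrays.  Returns the two ``SpectralMeasurement``s with
    ``roi_area`` filled in.
    """
    lesion = _measure_site(lesion_maps, lesion_roi, lesion_mask)
    node = _measure_site(node_maps, node_roi, node_mask)
    return lesion, node
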