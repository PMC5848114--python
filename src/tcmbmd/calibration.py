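"""Derivation of TCM calibration entries from reference scans.

The calibration procedure scans a water vial (marrow surrogate) and a
cortical-bone-equivalent phantom of known mineral density at each tube
voltage, draws an ROI in each (30 mm x 30 mm in the reference protocol)
and takes the ROI means as CTN_mar and CTN_cor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CalibrationEntry, CalibrationError
from .image_io import CTImage

__all__ = ["ROIError", "ROISpec", "ROIStats", "build_calibration", "roi_stats"]

DEFAULT_ROI_EXTENT_MM = 30.0


class ROIError(ValueError):
    """Raised when an ROI does not fit the image it is applied to."""


@dataclass(frozen=True)
class ROISpec:
    """A rectangular or circular region of interest.

    ``center`` is a 0-based (row, col) pixel coordinate (fractional values
    allowed); ``extent_mm`` is the side length (rectangle) or diameter
    (circle) in mm, converted to pixels through the image's pixel spacing.
    A pixel belongs to the ROI iff its center lies inside the region;
    rectangle edges follow a half-open convention (low edge in, high edge
    out) so abutting ROIs never share pixels.
    """

    shape: str  # "rectangle" | "circle"
    center: tuple[float, float]
    extent_mm: float = DEFAULT_ROI_EXTENT_MM

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ROIError(f"unknown ROI shape {self.shape!r}")
        if self.extent_mm <= 0:
            raise ROIError(f"ROI extent must be positive, got {self.extent_mm}")

    def mask(self, image: CTImage, slice_index: int = 0) -> np.ndarray:
        """Boolean membership mask on the given slice."""
        arr = image.get_slice(slice_index)
        sr, sc = image.pixel_spacing
        hr, hc = self.extent_mm / (2 * sr), self.extent_mm / (2 * sc)  # px half-extents
        r0, c0 = self.center
        if (
            r0 - hr < -0.5
            or r0 + hr > arr.shape[0] - 0.5
            or c0 - hc < -0.5
            or c0 + hc > arr.shape[1] - 0.5
        ):
            raise ROIError(
                f"ROI spans rows [{r0 - hr:.1f}, {r0 + hr:.1f}] and cols "
                f"[{c0 - hc:.1f}, {c0 + hc:.1f}] px, outside image {arr.shape}"
            )
        rr = np.arange(arr.shape[0])[:, None]
        cc = np.arange(arr.shape[1])[None, :]
        if self.shape == "rectangle":
            return (
                (rr >= r0 - hr) & (rr < r0 + hr) & (cc >= c0 - hc) & (cc < c0 + hc)
            )
        return ((rr - r0) / hr) ** 2 + ((cc - c0) / hc) ** 2 <= 1.0


@dataclass(frozen=True)
class ROIStats:
    """Mean and sample standard deviation (HU) over an ROI."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ROIError("ROI must contain at least one pixel")
        if self.sd < 0:
            raise ROIError("SD must be non-negative")


def roi_stats(image: CTImage, roi: ROISpec, slice_index: int = 0) -> ROIStats:
    """Mean and sample SD (n-1 denominator) of HU over the ROI pixels."""
    arr = image.get_slice(slice_index)
    mask = roi.mask(image, slice_index)
    vals = arr[mask]
    if vals.size == 0:
        raise ROIError("ROI contains no pixel centers")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(mean=float(np.mean(vals)), sd=sd, n_pixels=int(vals.size))


def build_calibration(
    water_stats: ROIStats,
    cortical_stats: ROIStats,
    rho_cor: float,
    kvp: int,
) -> CalibrationEntry:
    """Assemble a calibration entry from water and cortical-phantom ROI stats."""
    if cortical_stats.mean <= water_stats.mean:
        raise CalibrationError(
            f"inverted calibration at {kvp} kVp: cortical mean "
            f"{cortical_stats.mean:.1f} HU <= water mean {water_stats.mean:.1f} HU"
        )
    return CalibrationEntry(
        kvp=kvp,
        ctn_mar=water_stats.mean,
        ctn_cor=cortical_stats.mean,
        rho_cor=rho_cor,
        ctn_mar_sd=water_stats.sd,
        ctn_cor_sd=cortical_stats.sd,
    )
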