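"""ROI bookkeeping and first-order image statistics: SNR, SDNR, COV.

Conventions (shared package-wide): ROIs are 0-based, half-open, (row0, col0,
height, width) in pixels; standard deviations are sample (n-1) throughout;
the console-style SNR subtracts the detector DC offset from the mean by
default (so SNR -> 0 at zero exposure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import DegenerateInputError, GeometryError
from .specs import Image

__all__ = [
    "ROI",
    "RoiStats",
    "standard_rois",
    "roi_stats",
    "snr",
    "sdnr",
    "cov",
    "percent_change",
    "fold_ratio",
    "roi_from_mm",
]

ArrayOrImage = Union[np.ndarray, Image]


@dataclass(frozen=True)
class ROI:
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise GeometryError("ROI height and width must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise GeometryError("ROI origin must be non-negative")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    def extract(self, image: ArrayOrImage) -> np.ndarray:
        pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
        if self.row1 > pixels.shape[0] or self.col1 > pixels.shape[1]:
            raise GeometryError(f"ROI {self} does not fit image of shape {pixels.shape}")
        return pixels[self.row0:self.row1, self.col0:self.col1]

    def overlaps(self, other: "ROI") -> bool:
        return not (self.row1 <= other.row0 or other.row1 <= self.row0
                    or self.col1 <= other.col0 or other.col1 <= self.col0)


@dataclass(frozen=True)
class RoiStats:
    label: str
    mean: float
    sd: float
    n: int
    snr: Optional[float] = None


def roi_from_mm(center_row_mm: float, center_col_mm: float, side_mm: float,
                pitch_mm: float) -> ROI:
    """Square ROI from a centre/side in mm (rounded to whole pixels)."""
    side = int(round(side_mm / pitch_mm))
    r0 = int(round(center_row_mm / pitch_mm - side / 2))
    c0 = int(round(center_col_mm / pitch_mm - side / 2))
    return ROI(r0, c0, side, side)


def standard_rois(image_shape: tuple[int, int], roi_size: Optional[int] = None,
                  margin: int = 16) -> dict[str, ROI]:
    """The five uniformity ROIs: centre C plus corners CW1, CW2, N1, N2.

    CW1/CW2 sit on the chest-wall side (low row index), N1/N2 on the nipple
    side; 1 is the low-column corner. Corner ROIs are inset by ``margin``
    pixels. The default size is 256 px for full frames and 64 px for
    desk-scale frames (anything smaller than 1024 rows).
    """
    n_rows, n_cols = image_shape
    if roi_size is None:
        roi_size = 256 if min(n_rows, n_cols) >= 1024 else 64
    if n_rows < 3 * roi_size or n_cols < 3 * roi_size:
        raise GeometryError(
            f"image {image_shape} too small for three {roi_size}-px ROIs per axis")
    far_r = n_rows - margin - roi_size
    far_c = n_cols - margin - roi_size
    rois = {
        "C": ROI((n_rows - roi_size) // 2, (n_cols - roi_size) // 2, roi_size, roi_size),
        "CW1": ROI(margin, margin, roi_size, roi_size),
        "CW2": ROI(margin, far_c, roi_size, roi_size),
        "N1": ROI(far_r, margin, roi_size, roi_size),
        "N2": ROI(far_r, far_c, roi_size, roi_size),
    }
    labels = list(rois)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if rois[a].overlaps(rois[b]):
                raise GeometryError("standard ROIs overlap; reduce roi_size or margin")
    return rois


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def snr(image: ArrayOrImage, roi: ROI, dc_offset: Optional[float] = None,
        *, subtract_offset: bool = True) -> float:
    """Console-style SNR: (mean - DC offset) / sd over the ROI.

    The exact console formula is undocumented; ``subtract_offset=False``
    selects the raw mean/sd convention instead.
    """
    if dc_offset is None:
        dc_offset = image.dc_offset if isinstance(image, Image) else 0.0
    mean, sd = _mean_sd(roi.extract(image))
    if sd == 0:
        raise DegenerateInputError("SNR undefined on a constant ROI (zero sd)")
    offset = dc_offset if subtract_offset else 0.0
    return (mean - offset) / sd


def roi_stats(image: ArrayOrImage, roi: ROI, label: str = "custom",
              dc_offset: Optional[float] = None) -> RoiStats:
    values = roi.extract(image)
    mean, sd = _mean_sd(values)
    s = None
    if sd > 0:
        if dc_offset is None:
            dc_offset = image.dc_offset if isinstance(image, Image) else 0.0
        s = (mean - dc_offset) / sd
    return RoiStats(label=label, mean=mean, sd=sd, n=values.size, snr=s)


def sdnr(image: ArrayOrImage, roi_al: ROI, roi_bg: ROI) -> float:
    """Signal-difference-to-noise ratio (S_bg - S_insert) / sigma_bg.

    Means and sd are taken on the raw signal; the DC offset cancels in the
    difference.
    """
    mean_al, _ = _mean_sd(roi_al.extract(image))
    mean_bg, sd_bg = _mean_sd(roi_bg.extract(image))
    if sd_bg == 0:
        raise DegenerateInputError("SDNR undefined with zero background sd")
    return (mean_bg - mean_al) / sd_bg


def cov(values: Sequence[float]) -> float:
    """Coefficient of variation: sample sd / mean."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise DegenerateInputError("COV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise DegenerateInputError("COV undefined at zero mean")
    return float(arr.std(ddof=1) / mean)


def percent_change(old: float, new: float) -> float:
    """100 * (new - old) / old. Rounding is the caller's concern."""
    if old == 0:
        raise DegenerateInputError("percent change undefined from zero")
    return 100.0 * (new - old) / old


def fold_ratio(a: float, b: float) -> float:
    """Plain ratio a / b (e.g. 'x was 2.6 times lower' style comparisons)."""
    if b == 0:
        raise DegenerateInputError("fold ratio undefined with zero denominator")
    return a / b
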