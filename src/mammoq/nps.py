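"""Normalised noise power spectrum (nNPS) from homogeneous phantom regions.

Procedure: a square homogeneous region (512 px full scale, 128 px desk
scale) is tiled by 9 half-overlapping square ROIs (side = half the region,
stride = a quarter); each ROI is detrended with a fitted 2D second-order
polynomial; the 2D periodogram, scaled by pitch^2/N^2, is averaged over
ROIs and frames; dividing by the squared offset-subtracted large-area mean
gives the nNPS. Axial 1D curves average the 7 frequency rows flanking each
axis; the radial curve averages annuli that exclude those axis bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError, GeometryError, MammoqError
from .specs import Image

__all__ = ["NPSCurve", "NnpsResult", "nnps"]


@dataclass(frozen=True)
class NPSCurve:
    """1D section of the normalised NPS (units mm^2)."""

    frequencies: np.ndarray  # cycles/mm
    values: np.ndarray
    axis: str  # "axial-u" | "axial-v" | "radial"


@dataclass(frozen=True)
class NnpsResult:
    axial_u: NPSCurve
    axial_v: NPSCurve
    radial: NPSCurve
    large_area_signal: float          # offset-subtracted grand mean
    nnps2d: np.ndarray                # fftshifted, mm^2
    nps2d: np.ndarray                 # fftshifted, counts^2 mm^2
    detrended_variance: float         # mean per-ROI pixel variance after detrend
    freq_step: float                  # Delta u = 1/(N * pitch), cycles/mm

    def radial_on_grid(self) -> NPSCurve:
        """Radial curve on the uniform grid k*Delta_u up to Nyquist.

        Annuli inside the excluded axis bands carry no samples; those
        leading bins are filled with the first measured value (they are
        down-weighted by the u-weighting of any detectability integral).
        """
        vals = self.radial.values.copy()
        valid = ~np.isnan(vals)
        if not valid.any():
            raise DegenerateInputError("radial nNPS has no valid bins")
        first = np.argmax(valid)
        vals[:first] = vals[first]
        # interior gaps (rare): linear interpolation
        if np.isnan(vals).any():
            idx = np.arange(vals.size)
            vals = np.interp(idx, idx[~np.isnan(vals)], vals[~np.isnan(vals)])
        return NPSCurve(frequencies=self.radial.frequencies, values=vals, axis="radial")


def _detrend2(roi: np.ndarray) -> np.ndarray:
    """Subtract a fitted 2D polynomial of total order 2 (6 terms)."""
    n0, n1 = roi.shape
    y, x = np.mgrid[0:n0, 0:n1]
    y = (y - (n0 - 1) / 2) / n0
    x = (x - (n1 - 1) / 2) / n1
    a = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y],
                 axis=-1).reshape(-1, 6)
    coef, *_ = np.linalg.lstsq(a, roi.ravel(), rcond=None)
    return roi - (a @ coef).reshape(roi.shape)


def nnps(
    images: Sequence[Image] | Image,
    region_origin: tuple[int, int],
    region_size: Optional[int] = None,
    *,
    axial_band: int = 7,
    dc_offset: Optional[float] = None,
) -> NnpsResult:
    """Estimate the normalised NPS from one or more homogeneous regions.

    ``region_origin`` is the (row0, col0) pixel origin of the square region;
    ``region_size`` defaults to 512 when the frame allows it, else 128.
    """
    if isinstance(images, Image):
        images = [images]
    if len(images) < 1:
        raise MammoqError("nnps needs at least one image")
    pitch = images[0].pitch_mm
    offset = dc_offset if dc_offset is not None else images[0].dc_offset
    r0, c0 = region_origin
    shape = images[0].shape
    if region_size is None:
        region_size = 512 if min(shape) - max(r0, c0) >= 512 else 128
    n = region_size // 2           # ROI side
    stride = n // 2                # half-overlap
    if r0 + region_size > shape[0] or c0 + region_size > shape[1]:
        raise GeometryError("nNPS region exceeds the image")

    starts = range(0, region_size - n + 1, stride)
    origins = [(r0 + i, c0 + j) for i in starts for j in starts]
    if len(origins) < 9:
        raise MammoqError("fewer than 9 half-overlapping ROIs; enlarge the region")

    acc = np.zeros((n, n))
    var_acc = 0.0
    signal_acc = 0.0
    count = 0
    for img in images:
        if img.shape != shape:
            raise GeometryError("all nNPS input frames must share a shape")
        region = img.pixels[r0:r0 + region_size, c0:c0 + region_size]
        signal_acc += float(region.mean())
        for (ri, ci) in origins:
            roi = img.pixels[ri:ri + n, ci:ci + n]
            d = _detrend2(roi)
            var_acc += float(d.var(ddof=0))
            acc += np.abs(np.fft.fft2(d)) ** 2
            count += 1

    nps2d = np.fft.fftshift(acc / count) * (pitch ** 2) / (n ** 2)
    large_area = signal_acc / len(images) - offset
    if large_area <= 0:
        raise DegenerateInputError("large-area signal at or below the DC offset")
    nnps2d = nps2d / (large_area ** 2)

    du = 1.0 / (n * pitch)
    center = n // 2
    k = np.arange(n) - center          # frequency index after fftshift
    half = np.arange(0, n // 2 + 1)    # folded positive frequencies
    freqs = half * du

    def _axial(along_cols: bool) -> np.ndarray:
        band = [center + s for s in range(1, axial_band + 1)]
        band += [center - s for s in range(1, axial_band + 1)]
        strip = nnps2d[band, :] if along_cols else nnps2d[:, band].T
        prof = strip.mean(axis=0)
        folded = np.empty(half.size)
        for m in half:
            cols = [center + m] + ([center - m] if 0 < m <= center else [])
            cols = [c for c in cols if 0 <= c < n]
            folded[m] = np.mean([prof[c] for c in cols])
        return folded

    axial_u = NPSCurve(freqs, _axial(along_cols=True), "axial-u")
    axial_v = NPSCurve(freqs, _axial(along_cols=False), "axial-v")

    ki, kj = np.meshgrid(k, k, indexing="ij")
    radius = np.hypot(ki, kj)
    keep = (np.abs(ki) > axial_band) & (np.abs(kj) > axial_band)
    rbin = np.rint(radius).astype(int)
    radial_vals = np.full(half.size, np.nan)
    for m in half:
        sel = keep & (rbin == m)
        if sel.any():
            radial_vals[m] = nnps2d[sel].mean()
    radial = NPSCurve(freqs, radial_vals, "radial")

    return NnpsResult(axial_u=axial_u, axial_v=axial_v, radial=radial,
                      large_area_signal=large_area, nnps2d=nnps2d, nps2d=nps2d,
                      detrended_variance=var_acc / count, freq_step=du)
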