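"""Presampled MTF estimation from slanted edges.

The estimator follows standard slanted-edge practice: per-line 50%-threshold
crossings give the edge angle and sub-pixel intercept; pixels are projected
onto the edge normal and binned into an oversampled edge-spread function
(default quarter-pixel bins); the ESF is differentiated to an LSF, Hann
windowed about its peak, and Fourier transformed. The finite-difference and
bin-aperture transfer functions (each a sinc in f*bin) are divided out so a
pure Gaussian blur is recovered to well under a percent at 0.8x Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BinningError, EdgeEstimationError, RangeError, UnsuitableEdgeError
from .roi import ROI, ArrayOrImage
from .specs import Image

__all__ = ["EdgeModel", "MTFCurve", "estimate_edge", "presampled_mtf", "average_orthogonal"]


@dataclass(frozen=True)
class MTFCurve:
    """Frequency-indexed presampled MTF, normalised to 1 at zero frequency."""

    frequencies: np.ndarray  # cycles/mm, ascending from 0
    values: np.ndarray

    def interp(self, target_freqs: np.ndarray) -> np.ndarray:
        target_freqs = np.asarray(target_freqs, dtype=np.float64)
        if target_freqs.max() > self.frequencies.max() + 1e-12:
            raise RangeError(
                f"target frequency {target_freqs.max():.3g} beyond MTF support "
                f"{self.frequencies.max():.3g} cycles/mm")
        return np.interp(target_freqs, self.frequencies, self.values)


@dataclass(frozen=True)
class EdgeModel:
    """A slanted edge: orientation, angle from the pixel axis, sub-pixel
    intercept, and the analysis band it was estimated in.

    For a "vertical" edge the edge line runs roughly along rows and the
    crossing column is intercept + tan(angle) * row (band-local coords);
    "horizontal" is the transposed case.
    """

    orientation: str  # "vertical" | "horizontal"
    angle_deg: float
    intercept_px: float
    band: ROI


def _as_array(image: ArrayOrImage) -> np.ndarray:
    return image.pixels if isinstance(image, Image) else np.asarray(image, dtype=np.float64)


def _band_lines(arr: np.ndarray, orientation: str) -> np.ndarray:
    # Return the band so that each *row* holds one threshold crossing.
    return arr if orientation == "vertical" else arr.T


def _detect_orientation(arr: np.ndarray) -> str:
    g_col = np.abs(np.diff(arr, axis=1)).sum()
    g_row = np.abs(np.diff(arr, axis=0)).sum()
    return "vertical" if g_col >= g_row else "horizontal"


def _line_crossing(line: np.ndarray, lo: float, hi: float) -> float:
    thr = 0.5 * (lo + hi)
    d = line - thr
    s0 = np.sign(d[0]) if d[0] != 0 else 1.0
    idx = np.nonzero(np.sign(d) != s0)[0]
    if idx.size == 0:
        raise EdgeEstimationError("no 50% threshold crossing found on a line")
    k = int(idx[0]) - 1
    if d[k] == d[k + 1]:
        return float(k)
    return k + float(d[k] / (d[k] - d[k + 1]))


def estimate_edge(image: ArrayOrImage, band: ROI, orientation: str | None = None,
                  *, min_contrast_snr: float = 5.0) -> EdgeModel:
    """Locate a slanted edge inside ``band`` and fit its angle and intercept.

    Raises :class:`UnsuitableEdgeError` if the fitted angle is outside
    [1, 10] degrees and :class:`EdgeEstimationError` if the contrast across
    the edge is below ``min_contrast_snr`` times the local noise or the edge
    hugs the band border.
    """
    arr = band.extract(_as_array(image))
    if orientation is None:
        orientation = _detect_orientation(arr)
    lines = _band_lines(arr, orientation)
    n_lines, n_across = lines.shape
    edge_tail = max(3, n_across // 8)
    lo_side = lines[:, :edge_tail]
    hi_side = lines[:, -edge_tail:]
    lo, hi = float(lo_side.mean()), float(hi_side.mean())
    noise = 0.5 * (lo_side.std(ddof=1) + hi_side.std(ddof=1))
    if noise > 0 and abs(hi - lo) < min_contrast_snr * noise:
        raise EdgeEstimationError(
            f"edge contrast {abs(hi - lo):.3g} below {min_contrast_snr}x noise {noise:.3g}")
    if noise == 0 and hi == lo:
        raise EdgeEstimationError("no contrast across the analysis band")
    crossings = np.array([_line_crossing(lines[i], lo, hi) for i in range(n_lines)])
    if crossings.mean() < 0.05 * n_across or crossings.mean() > 0.95 * n_across:
        raise EdgeEstimationError("edge lies at the border of the analysis band")
    slope, intercept = np.polyfit(np.arange(n_lines), crossings, 1)
    angle = float(np.degrees(np.arctan(slope)))
    if not 1.0 <= abs(angle) <= 10.0:
        raise UnsuitableEdgeError(
            f"edge angle {angle:.2f} deg outside the valid 1-10 degree band")
    return EdgeModel(orientation=orientation, angle_deg=angle,
                     intercept_px=float(intercept), band=band)


def presampled_mtf(image: ArrayOrImage, edge: EdgeModel,
                   bin_fraction: float = 0.25) -> MTFCurve:
    """Oversampled presampled MTF from a fitted slanted edge."""
    if isinstance(image, Image):
        pitch_mm = image.pitch_mm
    else:
        raise TypeError("presampled_mtf needs an Image (for the pixel pitch); "
                        "wrap arrays in mammoq.specs.Image")
    arr = edge.band.extract(_as_array(image))
    lines = _band_lines(arr, edge.orientation)
    n_lines, n_across = lines.shape
    slope = np.tan(np.radians(edge.angle_deg))
    rows = np.arange(n_lines)[:, None]
    cols = np.arange(n_across)[None, :]
    # signed distance (mm) from each pixel centre to the edge, along its normal
    dist = (cols - (edge.intercept_px + slope * rows)) * np.cos(np.radians(edge.angle_deg))
    dist_mm = dist * pitch_mm

    delta = bin_fraction * pitch_mm
    d = dist_mm.ravel()
    v = lines.ravel()
    k = np.floor((d - d.min()) / delta).astype(np.int64)
    n_bins = int(k.max()) + 1
    sums = np.bincount(k, weights=v, minlength=n_bins)
    counts = np.bincount(k, minlength=n_bins)
    # trim possibly-sparse extreme bins created by the band corners
    trim = int(np.ceil(abs(slope) * n_lines / (2 * bin_fraction))) + 1
    sl = slice(trim, n_bins - trim)
    if (counts[sl] == 0).any():
        raise BinningError("empty ESF bins; increase bin_fraction or the band size")
    esf = sums[sl] / counts[sl]
    if esf.size < 16:
        raise BinningError("analysis band too small for a usable ESF")

    lsf = np.diff(esf) / delta
    peak = int(np.argmax(np.abs(lsf)))
    n = lsf.size
    idx = np.arange(n) - peak
    window = np.where(np.abs(idx) <= n // 2,
                      0.5 * (1.0 + np.cos(2 * np.pi * idx / n)), 0.0)
    lsf_w = lsf * window

    spectrum = np.abs(np.fft.rfft(lsf_w))
    freqs = np.fft.rfftfreq(n, d=delta)
    if spectrum[0] == 0:
        raise BinningError("degenerate LSF (zero area); cannot normalise MTF")
    mtf = spectrum / spectrum[0]
    # undo the finite-difference and bin-aperture transfer functions
    corr = np.sinc(freqs * delta) ** 2
    mtf = mtf / np.where(corr > 0.05, corr, np.inf)
    return MTFCurve(frequencies=freqs, values=mtf)


def average_orthogonal(mtf_h: MTFCurve, mtf_v: MTFCurve,
                       target_freqs: np.ndarray) -> MTFCurve:
    """Interpolate two orthogonal MTFs onto a shared grid and average them."""
    target_freqs = np.asarray(target_freqs, dtype=np.float64)
    mean = 0.5 * (mtf_h.interp(target_freqs) + mtf_v.interp(target_freqs))
    return MTFCurve(frequencies=target_freqs, values=mean)
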