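"""Non-pre-whitening model observer with eye filter (NPWE).

The detectability index for a disc task of radius R and contrast C is

    d'^2 = [2 pi C Int S^2(u) MTF^2(u) VTF^2(u) u du]^2
           -----------------------------------------------
            2 pi Int S^2(u) MTF^2(u) VTF^4(u) nNPS(u) u du

with S(u) = R J1(2 pi u R) / u the disc's Fourier transform (S(0) = pi R^2),
MTF the presampled system MTF, VTF the visual transfer function and nNPS
the normalised noise power spectrum. With white noise nNPS = N0 and
MTF = VTF = 1 this collapses to d' = C sqrt(pi R^2 / N0) (Parseval), which
anchors the numerical implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import j1

from .exceptions import DegenerateInputError
from .mtf import MTFCurve
from .nps import NPSCurve
from .roi import ROI, ArrayOrImage, _mean_sd
from .specs import Image

__all__ = [
    "TaskSpec",
    "EyeFilterSpec",
    "DPrimeResult",
    "disc_task_ft",
    "eye_filter",
    "measure_contrast",
    "dprime",
]


@dataclass(frozen=True)
class TaskSpec:
    """A disc detection task: diameter in mm and relative signal contrast."""

    diameter_mm: float
    contrast: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("task diameter must be positive")
        if self.contrast < 0:
            raise ValueError("task contrast must be non-negative")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class EyeFilterSpec:
    """Band-pass contrast-sensitivity model VTF(f) = f^n exp(-c f^2).

    f is angular frequency in cycles/degree; c is set so the response peaks
    at ``peak_cyc_per_deg``; the curve is normalised to a maximum of 1.
    Image-plane frequencies map to angular ones through the display
    magnification and viewing distance.
    """

    viewing_distance_mm: float = 400.0
    magnification: float = 1.5
    peak_cyc_per_deg: float = 4.0
    exponent: float = 1.3

    def __post_init__(self) -> None:
        if self.viewing_distance_mm <= 0 or self.magnification <= 0:
            raise ValueError("viewing distance and magnification must be positive")

    @property
    def mm_per_degree(self) -> float:
        """Detector-plane mm subtending one visual degree on the display."""
        return self.viewing_distance_mm * np.pi / 180.0 / self.magnification


@dataclass(frozen=True)
class DPrimeResult:
    dprime: float
    numerator: float
    denominator: float
    frequencies: np.ndarray
    task: TaskSpec


def disc_task_ft(diameter_mm: float, u) -> np.ndarray:
    """Fourier transform of a uniform disc: S(u) = R J1(2 pi u R)/u, S(0)=pi R^2."""
    r = diameter_mm / 2.0
    u = np.asarray(u, dtype=np.float64)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    out = np.empty_like(u)
    nz = u != 0
    out[nz] = r * j1(2.0 * np.pi * u[nz] * r) / u[nz]
    out[~nz] = np.pi * r * r
    return float(out[0]) if scalar else out


def eye_filter(u_image, spec: Optional[EyeFilterSpec] = None) -> np.ndarray:
    """Evaluate the VTF at image-plane frequencies (cycles/mm), peak-normalised."""
    spec = spec or EyeFilterSpec()
    f = np.asarray(u_image, dtype=np.float64) * spec.mm_per_degree
    n = spec.exponent
    c = n / (2.0 * spec.peak_cyc_per_deg ** 2)
    peak = spec.peak_cyc_per_deg ** n * np.exp(-n / 2.0)
    with np.errstate(invalid="ignore"):
        v = np.where(f > 0, f ** n * np.exp(-c * f * f), 0.0)
    return v / peak


def measure_contrast(image: ArrayOrImage, roi_al: ROI, roi_bg: ROI,
                     dc_offset: Optional[float] = None) -> float:
    """Relative contrast of the Al target: (S_bg - S_al) / (S_bg - offset)."""
    if dc_offset is None:
        dc_offset = image.dc_offset if isinstance(image, Image) else 0.0
    mean_al, _ = _mean_sd(roi_al.extract(image))
    mean_bg, _ = _mean_sd(roi_bg.extract(image))
    if mean_bg - dc_offset <= 0:
        raise DegenerateInputError("background signal at or below the DC offset")
    return (mean_bg - mean_al) / (mean_bg - dc_offset)


def dprime(
    task: TaskSpec,
    mtf: MTFCurve,
    nnps_curve: NPSCurve,
    eye: Optional[EyeFilterSpec] = None,
    *,
    eye_values: Optional[np.ndarray] = None,
) -> DPrimeResult:
    """NPWE detectability index on the shared frequency grid of mtf/nnps.

    Both curves must be sampled on the same ascending grid (use
    :func:`mammoq.mtf.average_orthogonal` with the radial-nNPS grid).
    Integration is trapezoidal up to the top of the grid (Nyquist for
    measured curves). ``eye_values`` overrides the VTF pointwise (pass
    ones for a plain NPW observer).
    """
    u = np.asarray(mtf.frequencies, dtype=np.float64)
    if u.shape != np.shape(nnps_curve.frequencies) or not np.allclose(
            u, nnps_curve.frequencies):
        raise ValueError("MTF and nNPS must share one frequency grid")
    m = np.clip(np.asarray(mtf.values, dtype=np.float64), 0.0, None)
    w = np.asarray(nnps_curve.values, dtype=np.float64)
    if eye_values is not None:
        v = np.asarray(eye_values, dtype=np.float64)
    else:
        v = eye_filter(u, eye)
    s2 = disc_task_ft(task.diameter_mm, u) ** 2

    num = 2.0 * np.pi * task.contrast * np.trapezoid(s2 * m * m * v * v * u, u)
    den = 2.0 * np.pi * np.trapezoid(s2 * m * m * v ** 4 * w * u, u)
    if den <= 0:
        raise DegenerateInputError(
            "zero noise integral; d' diverges (use the analytic no-noise limit)")
    return DPrimeResult(dprime=float(num / np.sqrt(den)), numerator=float(num),
                        denominator=float(den), frequencies=u, task=task)
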