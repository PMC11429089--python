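"""Average glandular dose per the EUREF formalism: AGD = K * g * c * s.

K is the incident air kerma at the breast upper surface (inverse-square
from the tube output), g converts kerma to glandular dose for a
50%-glandularity breast, c corrects to the standard-breast glandularity of
the screening age group, and s accounts for the target/filter spectrum.
The factor tables ship as versioned CSV assets under ``mammoq/data``;
interpolation is bilinear in (HVL, thickness) with no extrapolation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .exceptions import ConfigurationError, MammoqError, RangeError
from .specs import BeamSpec

__all__ = [
    "DoseReport",
    "incident_air_kerma",
    "agd",
    "pmma_to_breast_equivalent",
    "agd_for_exposure",
]


@dataclass(frozen=True)
class DoseReport:
    incident_air_kerma_mgy: float
    g: float
    c: float
    s: float
    agd_mgy: float
    hvl_mm_al: float
    breast_thickness_mm: float
    target_filter: str


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("mammoq.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@functools.lru_cache(maxsize=None)
def _factor_interpolator(name: str) -> tuple[RegularGridInterpolator, float, float, float, float]:
    df = _read_table(name)
    thickness = df["thickness_cm"].to_numpy(dtype=float) * 10.0  # -> mm
    hvl = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    interp = RegularGridInterpolator((thickness, hvl), values, method="linear",
                                     bounds_error=True)
    return interp, thickness.min(), thickness.max(), hvl.min(), hvl.max()


@functools.lru_cache(maxsize=None)
def _s_factors() -> dict[str, float]:
    df = _read_table("s_factors.csv")
    return dict(zip(df["target_filter"], df["s"].astype(float)))


@functools.lru_cache(maxsize=None)
def _pmma_table() -> tuple[np.ndarray, np.ndarray]:
    df = _read_table("pmma_breast.csv")
    return (df["pmma_mm"].to_numpy(dtype=float), df["breast_mm"].to_numpy(dtype=float))


def incident_air_kerma(beam: BeamSpec, mas: float, source_to_surface_mm: float) -> float:
    """Inverse-square air kerma (mGy) at the entrance surface."""
    if source_to_surface_mm <= 0:
        raise MammoqError("source-to-surface distance must be positive")
    if mas < 0:
        raise MammoqError("mAs must be non-negative")
    d_m = source_to_surface_mm / 1000.0
    return beam.tube_output_mgy_per_mas * mas / (d_m * d_m)


def _lookup(name: str, hvl_mm_al: float, thickness_mm: float) -> float:
    interp, t_lo, t_hi, h_lo, h_hi = _factor_interpolator(name)
    if not t_lo <= thickness_mm <= t_hi:
        raise RangeError(
            f"breast thickness {thickness_mm:.1f} mm outside the factor table "
            f"[{t_lo:.0f}, {t_hi:.0f}] mm; no extrapolation")
    if not h_lo <= hvl_mm_al <= h_hi:
        raise RangeError(
            f"HVL {hvl_mm_al:.2f} mm Al outside the factor table "
            f"[{h_lo:.2f}, {h_hi:.2f}]; no extrapolation")
    return float(interp((thickness_mm, hvl_mm_al)))


def agd(
    incident_kerma_mgy: float,
    hvl_mm_al: float,
    breast_thickness_mm: float,
    target_filter: str = "W/Rh",
) -> DoseReport:
    """EUREF average glandular dose for an equivalent breast thickness."""
    g = _lookup("g_factors.csv", hvl_mm_al, breast_thickness_mm)
    c = _lookup("c_factors.csv", hvl_mm_al, breast_thickness_mm)
    s_map = _s_factors()
    if target_filter not in s_map:
        raise ConfigurationError(
            f"no s factor for target/filter {target_filter!r}; known: {sorted(s_map)}")
    s = s_map[target_filter]
    return DoseReport(
        incident_air_kerma_mgy=float(incident_kerma_mgy), g=g, c=c, s=s,
        agd_mgy=float(incident_kerma_mgy) * g * c * s,
        hvl_mm_al=hvl_mm_al, breast_thickness_mm=breast_thickness_mm,
        target_filter=target_filter)


def pmma_to_breast_equivalent(t_pmma_mm: float) -> float:
    """Breast thickness (mm) of equal absorption to a PMMA slab (EUREF table)."""
    pmma, breast = _pmma_table()
    if not pmma.min() <= t_pmma_mm <= pmma.max():
        raise RangeError(
            f"PMMA thickness {t_pmma_mm:.1f} mm outside the equivalence table "
            f"[{pmma.min():.0f}, {pmma.max():.0f}] mm")
    return float(np.interp(t_pmma_mm, pmma, breast))


def agd_for_exposure(beam: BeamSpec, mas: float, pmma_thickness_mm: float) -> DoseReport:
    """Convenience wrapper: AGD of a PMMA acquisition under a beam spec.

    The entrance surface sits at source_to_detector - breast_support -
    slab thickness; the equivalent breast thickness comes from the EUREF
    PMMA table.
    """
    ssd = beam.source_to_detector_mm - beam.breast_support_mm - pmma_thickness_mm
    k = incident_air_kerma(beam, mas, ssd)
    breast = pmma_to_breast_equivalent(pmma_thickness_mm)
    return agd(k, beam.hvl_mm_al, breast, beam.target_filter)
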