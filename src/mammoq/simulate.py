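"""Synthetic 'for processing' acquisitions of the QC phantom.

The forward model is deliberately simple: a monoenergetic-equivalent
Beer-Lambert transmission per material, a multiplicative heel field, a
Gaussian presampling blur of the mean map, then quantum noise (variance
proportional to offset-subtracted mean) plus Gaussian electronic noise.
All randomness flows through an explicit integer seed recorded in the
image metadata; the same (specs, seed) pair is bit-reproducible.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import AecConfig, RunConfig
from .exceptions import ConfigurationError, SaturationError
from .specs import BeamSpec, DetectorSpec, ExposureSettings, Image, PhantomSpec

__all__ = [
    "build_mean_signal_map",
    "simulate_acquisition",
    "emulate_aec",
    "generate_flat_field",
    "simulate_phantom",
]


def _thickness_maps(phantom: PhantomSpec, row_mm: np.ndarray, col_mm: np.ndarray) -> dict:
    """Per-material path length (mm) at each grid point."""
    maps = {"PMMA": np.full(np.broadcast_shapes(row_mm.shape, col_mm.shape),
                            phantom.pmma_thickness_mm)}
    for ins in phantom.inserts:
        t = np.where(ins.contains(row_mm, col_mm), ins.thickness_mm, 0.0)
        maps[ins.material] = maps.get(ins.material, 0.0) + t
    return maps


def build_mean_signal_map(
    phantom: PhantomSpec,
    beam: BeamSpec,
    detector: DetectorSpec,
    exposure: ExposureSettings,
    *,
    supersample: int = 4,
    shape: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Deterministic expected-signal grid (counts) before noise.

    Each pixel is dc_offset + gain * mAs * heel(x, y) * exp(-sum mu_m t_m),
    with the exposure-dependent part blurred by the detector PSF. Insert
    boundaries are rendered with ``supersample``-fold sub-pixel coverage so
    that slanted edges carry genuine sub-pixel phase for MTF estimation.
    """
    if supersample < 1:
        raise ConfigurationError("supersample must be >= 1")
    n_rows, n_cols = shape if shape is not None else detector.shape
    ss = int(supersample)
    p = detector.pitch_mm / ss
    row_mm = (np.arange(n_rows * ss) + 0.5)[:, None] * p
    col_mm = (np.arange(n_cols * ss) + 0.5)[None, :] * p

    atten = np.zeros((n_rows * ss, n_cols * ss))
    for material, t in _thickness_maps(phantom, row_mm, col_mm).items():
        atten += beam.mu_of(material) * t
    signal = detector.gain * exposure.mas * np.exp(-atten)
    signal *= detector.heel.field(signal.shape)

    if detector.psf_sigma_mm > 0 and exposure.mas > 0:
        signal = gaussian_filter(signal, sigma=detector.psf_sigma_mm / p, mode="nearest")
    if ss > 1:
        signal = signal.reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
    return detector.dc_offset + signal


def simulate_acquisition(
    mean_map: np.ndarray,
    detector: DetectorSpec,
    seed: int,
    *,
    meta: Optional[dict] = None,
) -> Image:
    """One noise realisation of a mean-signal map.

    Quantum noise is Gaussian with variance quantum_gain * (mean - offset)
    (the Gaussian limit of a gain-scaled Poisson process), electronic noise
    is additive Gaussian; pixels are clipped at zero.
    """
    mean_map = np.asarray(mean_map, dtype=np.float64)
    if mean_map.min() < detector.dc_offset - 1e-9:
        raise ConfigurationError("mean map falls below the DC offset")
    rng = np.random.default_rng(int(seed))
    var_q = detector.quantum_gain * np.clip(mean_map - detector.dc_offset, 0.0, None)
    pixels = mean_map + rng.standard_normal(mean_map.shape) * np.sqrt(var_q)
    if detector.electronic_noise_sd > 0:
        pixels += rng.normal(0.0, detector.electronic_noise_sd, mean_map.shape)
    pixels = np.clip(pixels, 0.0, None)
    info = {"seed": int(seed)}
    if meta:
        info.update(meta)
    return Image(pixels=pixels, pitch_um=detector.pitch_um,
                 dc_offset=detector.dc_offset, meta=info)


def _sensor_rate_per_mas(
    phantom: PhantomSpec, beam: BeamSpec, detector: DetectorSpec,
    aec: AecConfig, position: int, n_sub: int = 96,
) -> float:
    """Mean expected signal per mAs over the sensor footprint, heel-calibrated.

    The servo emulates a unit whose per-position sensitivity was calibrated
    on a flat field, so the heel profile cancels out of the reading.
    """
    r0, r1, c0, c1 = aec.sensor_bounds_mm(position)
    row_mm = np.linspace(r0, r1, n_sub, endpoint=False)[:, None] + (r1 - r0) / (2 * n_sub)
    col_mm = np.linspace(c0, c1, n_sub, endpoint=False)[None, :] + (c1 - c0) / (2 * n_sub)
    atten = np.zeros((n_sub, n_sub))
    for material, t in _thickness_maps(phantom, row_mm, col_mm).items():
        atten += beam.mu_of(material) * t
    return float(detector.gain * np.exp(-atten).mean())


def emulate_aec(
    phantom: PhantomSpec,
    beam: BeamSpec,
    detector: DetectorSpec,
    aec_position: int,
    *,
    aec: Optional[AecConfig] = None,
) -> ExposureSettings:
    """AEC servo: pick kVp from the thickness table and the mAs that drives
    the sensor-footprint signal to the configured target, quantised and capped."""
    aec = aec or AecConfig()
    rate = _sensor_rate_per_mas(phantom, beam, detector, aec, aec_position)
    if rate <= 0:
        raise SaturationError("sensor sees no signal; target unreachable")
    mas = aec.target_counts / rate
    mas = round(mas / aec.mas_quantum) * aec.mas_quantum
    if mas > aec.mas_cap:
        raise SaturationError(
            f"AEC position {aec_position}: required {mas:.1f} mAs exceeds the "
            f"{aec.mas_cap:.0f} mAs cap (sensor rate {rate:.3g} counts/mAs)")
    kvp = aec.kvp_for_thickness(phantom.pmma_thickness_mm)
    return ExposureSettings(kvp=kvp, mas=float(mas), mode="automatic",
                            aec_position=int(aec_position))


def generate_flat_field(
    pmma_thickness_mm: float,
    detector: DetectorSpec,
    beam: BeamSpec,
    exposure: ExposureSettings,
    seed: int,
    *,
    supersample: int = 1,
) -> Image:
    """Insert-free PMMA acquisition with the heel profile applied."""
    flat = PhantomSpec(pmma_thickness_mm=pmma_thickness_mm,
                       lateral_size_mm=detector.area_mm)
    mean_map = build_mean_signal_map(flat, beam, detector, exposure,
                                     supersample=supersample)
    meta = {"kvp": exposure.kvp, "mas": exposure.mas, "mode": exposure.mode,
            "aec_position": exposure.aec_position,
            "pmma_thickness_mm": pmma_thickness_mm, "flat_field": True}
    return simulate_acquisition(mean_map, detector, seed, meta=meta)


def simulate_phantom(
    config: RunConfig,
    exposure: ExposureSettings,
    seed: int,
    *,
    noise: bool = True,
) -> Image:
    """Full phantom acquisition under a run configuration.

    With ``noise=False`` the returned image is the blurred mean map itself
    (useful as a noiseless edge target).
    """
    mean_map = build_mean_signal_map(config.phantom, config.beam, config.detector,
                                     exposure, supersample=config.supersample)
    meta = {"kvp": exposure.kvp, "mas": exposure.mas, "mode": exposure.mode,
            "aec_position": exposure.aec_position,
            "mas_reduction_level": exposure.mas_reduction_level,
            "pmma_thickness_mm": config.phantom.pmma_thickness_mm,
            "scale": config.scale, "flat_field": False}
    if not noise:
        return Image(pixels=mean_map, pitch_um=config.detector.pitch_um,
                     dc_offset=config.detector.dc_offset,
                     meta={"seed": None, **meta, "noiseless": True})
    return simulate_acquisition(mean_map, config.detector, seed, meta=meta)
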