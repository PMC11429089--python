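"""Deterministic fixture corpus for tests and demonstrations.

Everything is generated from an explicit seed at run time; nothing binary
ships with the package. The corpus mirrors the acquisition protocol:
repeated flat fields, the phantom at all seven AEC positions, the manual
recommended/reduced pair, a noiseless edge target and a white-noise stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig, default_config
from .experiments import derive_seed
from .io import write_image
from .simulate import emulate_aec, generate_flat_field, simulate_phantom
from .specs import ExposureSettings, Image, PhantomSpec

__all__ = ["generate_fixtures", "synthetic_edge_image", "white_noise_image"]


def synthetic_edge_image(
    shape: tuple[int, int] = (160, 120),
    angle_deg: float = 3.0,
    edge_col_px: float = 60.0,
    lo: float = 200.0,
    hi: float = 1000.0,
    pitch_um: float = 70.0,
    blur_sigma_mm: float = 0.0,
    *,
    aperture: bool = False,
    supersample: int = 16,
) -> Image:
    """Noiseless slanted-edge target with known geometry.

    With ``blur_sigma_mm`` > 0 the edge is an analytic Gaussian-blurred step
    sampled at pixel centres (its presampled MTF is exactly the Gaussian
    exp(-2 pi^2 sigma^2 u^2)). With ``aperture=True`` an ideal sharp edge is
    area-sampled over the pixel aperture instead (MTF = pixel sinc).
    """
    from scipy.stats import norm

    n_rows, n_cols = shape
    pitch_mm = pitch_um / 1000.0
    slope = np.tan(np.radians(angle_deg))
    if aperture:
        ss = supersample
        rows = (np.arange(n_rows * ss) + 0.5)[:, None] / ss
        cols = (np.arange(n_cols * ss) + 0.5)[None, :] / ss
        mask = cols > (edge_col_px + slope * rows)
        pix = np.where(mask, hi, lo).reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
    else:
        rows = (np.arange(n_rows) + 0.5)[:, None]
        cols = (np.arange(n_cols) + 0.5)[None, :]
        dist_mm = (cols - (edge_col_px + slope * rows)) * np.cos(
            np.radians(angle_deg)) * pitch_mm
        if blur_sigma_mm > 0:
            pix = lo + (hi - lo) * norm.cdf(dist_mm / blur_sigma_mm)
        else:
            pix = np.where(dist_mm > 0, hi, lo)
    return Image(pixels=pix, pitch_um=pitch_um, dc_offset=0.0,
                 meta={"synthetic": "edge", "angle_deg": angle_deg,
                       "blur_sigma_mm": blur_sigma_mm, "aperture": aperture})


def white_noise_image(shape: tuple[int, int], mean: float, sd: float, seed: int,
                      pitch_um: float = 70.0, dc_offset: float = 50.0) -> Image:
    """Homogeneous Gaussian white-noise frame (nNPS oracle input)."""
    rng = np.random.default_rng(seed)
    pix = np.clip(rng.normal(mean, sd, shape), 0.0, None)
    return Image(pixels=pix, pitch_um=pitch_um, dc_offset=dc_offset,
                 meta={"synthetic": "white_noise", "mean": mean, "sd": sd, "seed": seed})


def generate_fixtures(out_dir: str | Path, seed: int,
                      config: RunConfig | None = None) -> dict:
    """Write the deterministic corpus; returns a manifest (also saved as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or default_config("test")
    manifest: dict = {"seed": int(seed), "files": []}

    def _save(image: Image, name: str) -> None:
        write_image(image, out / name)
        manifest["files"].append(name)

    flat_phantom = PhantomSpec(pmma_thickness_mm=config.flat_field_pmma_mm,
                               lateral_size_mm=config.detector.area_mm)
    flat_exp = emulate_aec(flat_phantom, config.beam, config.detector, 2,
                           aec=config.aec)
    for rep in range(5):
        img = generate_flat_field(config.flat_field_pmma_mm, config.detector,
                                  config.beam, flat_exp, derive_seed(seed, 1, rep))
        _save(img, f"flat_{rep}.tif")

    for pos in range(1, 8):
        exp = emulate_aec(config.phantom, config.beam, config.detector, pos,
                          aec=config.aec)
        img = simulate_phantom(config, exp, derive_seed(seed, 2, pos))
        _save(img, f"phantom_auto_p{pos}.tif")

    kvp_p = config.aec.kvp_for_thickness(config.phantom.pmma_thickness_mm)
    reduced = round(config.recommended_mas * (1 - config.mas_reduction_fraction)
                    / config.aec.mas_quantum) * config.aec.mas_quantum
    for name, mas, level in (("manual_recommended", config.recommended_mas, 0),
                             ("manual_reduced", reduced, 1)):
        exp = ExposureSettings(kvp=kvp_p, mas=mas, mode="manual",
                               mas_reduction_level=level)
        _save(simulate_phantom(config, exp, derive_seed(seed, 3, level)),
              f"{name}.tif")

    exp = ExposureSettings(kvp=kvp_p, mas=config.recommended_mas, mode="manual")
    _save(simulate_phantom(config, exp, 0, noise=False), "noiseless_edge.tif")

    for rep in range(4):
        _save(white_noise_image((192, 192), 550.0, 9.0, derive_seed(seed, 4, rep)),
              f"white_noise_{rep}.tif")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
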