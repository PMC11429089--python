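"""Shared fixtures: the desk-scale configuration and cached heavy runs.

Session scope keeps the expensive simulations (the AEC scan and the manual
study, 70 and 30 acquisitions) to one run each for the whole suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mammoq as mq
from mammoq.analyze import analysis_rois

warnings.filterwarnings("ignore", message="divide by zero")


@pytest.fixture(scope="session")
def cfg() -> mq.RunConfig:
    return mq.default_config("test")


@pytest.fixture(scope="session")
def rois(cfg):
    return analysis_rois(cfg)


@pytest.fixture(scope="session")
def ref_exposure(cfg):
    return mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector,
                          cfg.reference_aec_position, aec=cfg.aec)


@pytest.fixture(scope="session")
def ref_mean_map(cfg, ref_exposure):
    return mq.build_mean_signal_map(cfg.phantom, cfg.beam, cfg.detector,
                                    ref_exposure, supersample=cfg.supersample)


@pytest.fixture(scope="session")
def ref_image(cfg, ref_exposure, ref_mean_map):
    meta = {"kvp": ref_exposure.kvp, "mas": ref_exposure.mas,
            "mode": ref_exposure.mode, "aec_position": ref_exposure.aec_position}
    return mq.simulate_acquisition(ref_mean_map, cfg.detector, 11, meta=meta)


@pytest.fixture(scope="session")
def flat_exposure(cfg):
    flat = mq.PhantomSpec(pmma_thickness_mm=cfg.flat_field_pmma_mm,
                          lateral_size_mm=cfg.detector.area_mm)
    return mq.emulate_aec(flat, cfg.beam, cfg.detector, 2, aec=cfg.aec)


@pytest.fixture(scope="session")
def flat_stack(cfg, flat_exposure):
    """Five repeated flat fields at fixed settings (seeds 1-5)."""
    return [mq.generate_flat_field(cfg.flat_field_pmma_mm, cfg.detector, cfg.beam,
                                   flat_exposure, seed)
            for seed in range(1, 6)]


@pytest.fixture(scope="session")
def aec_report(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mq.run_aec_experiment(cfg, seed_base=1000, replicates=10)


@pytest.fixture(scope="session")
def manual_report(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mq.run_manual_experiment(cfg, seed_base=2000, replicates=10)


@pytest.fixture(scope="session")
def white_stack():
    from mammoq.fixtures import white_noise_image
    return [white_noise_image((192, 192), 550.0, 9.0, seed) for seed in range(16)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
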