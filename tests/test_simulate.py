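"""Simulator: mean-signal map, noise model, AEC servo and flat fields."""

import numpy as np
import pytest
from scipy import stats as sps

import mammoq as mq
from mammoq.exceptions import ConfigurationError, SaturationError
from mammoq.roi import ROI, cov, snr, standard_rois


def _uniform_setup(gain=10.0, mas=100.0, qg=0.16, enoise=2.0):
    det = mq.DetectorSpec(gain=gain, quantum_gain=qg, electronic_noise_sd=enoise,
                          heel=mq.HeelProfile(amplitude=0.0))
    phantom = mq.PhantomSpec(pmma_thickness_mm=45.0, lateral_size_mm=det.area_mm)
    beam = mq.BeamSpec()  # mu_PMMA = 0.06 -> mu * 45 mm = 2.7
    exposure = mq.ExposureSettings(kvp=28.0, mas=mas, mode="manual")
    return phantom, beam, det, exposure


class TestMeanSignalMap:
    def test_zero_exposure_gives_offset_everywhere(self):
        phantom, beam, det, _ = _uniform_setup()
        exp0 = mq.ExposureSettings(kvp=28.0, mas=0.0, mode="manual")
        m = mq.build_mean_signal_map(phantom, beam, det, exp0, supersample=1)
        assert np.allclose(m, det.dc_offset)

    def test_hand_beer_lambert_value(self):
        # gain 10, mAs 100, mu*t = 2.7, heel off -> 50 + 1000 e^-2.7 = 117.21
        phantom, beam, det, exposure = _uniform_setup()
        m = mq.build_mean_signal_map(phantom, beam, det, exposure, supersample=1)
        assert np.allclose(m, 50.0 + 1000.0 * np.exp(-2.7), rtol=1e-9)

    def test_attenuation_ordering_cu_below_al_below_background(self, cfg, rois):
        exposure = mq.ExposureSettings(kvp=28.0, mas=100.0, mode="manual")
        m = mq.build_mean_signal_map(cfg.phantom, cfg.beam, cfg.detector, exposure,
                                     supersample=2)
        cu_roi = ROI(40, 200, 64, 64)  # interior of the Cu plate
        assert cu_roi.extract(m).mean() < rois["al"].extract(m).mean() \
            < rois["bg"].extract(m).mean()

    def test_mean_linearity_in_mas(self):
        # with heel off, background mean - offset is proportional to mAs
        phantom, beam, det, _ = _uniform_setup()
        means = []
        for mas in (20.0, 200.0):
            e = mq.ExposureSettings(kvp=28.0, mas=mas, mode="manual")
            m = mq.build_mean_signal_map(phantom, beam, det, e, supersample=1)
            means.append(m.mean() - det.dc_offset)
        assert means[1] / means[0] == pytest.approx(10.0, rel=1e-2)

    def test_unknown_material_rejected(self):
        phantom, beam, det, exposure = _uniform_setup()
        phantom = mq.PhantomSpec(
            pmma_thickness_mm=45.0, lateral_size_mm=det.area_mm,
            cu=mq.Insert("Unobtainium", 5.0, 5.0, 1.0, 20.0, 20.0))
        with pytest.raises(ConfigurationError):
            mq.build_mean_signal_map(phantom, beam, det, exposure)


class TestNoiseModel:
    def test_same_seed_bit_identical(self, cfg, ref_mean_map):
        a = mq.simulate_acquisition(ref_mean_map, cfg.detector, seed=7)
        b = mq.simulate_acquisition(ref_mean_map, cfg.detector, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        c = mq.simulate_acquisition(ref_mean_map, cfg.detector, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_variance_matches_configured_model(self):
        phantom, beam, det, exposure = _uniform_setup(gain=84.0, mas=100.0)
        m = mq.build_mean_signal_map(phantom, beam, det, exposure, supersample=1)
        img = mq.simulate_acquisition(m, det, seed=3)
        mean_level = m[0, 0]
        expected = det.quantum_gain * (mean_level - det.dc_offset) \
            + det.electronic_noise_sd ** 2
        assert img.pixels.size >= 1e5
        assert img.pixels.var(ddof=1) == pytest.approx(expected, rel=0.05)

    def test_snr_doubles_when_mas_quadruples(self):
        # pure quantum noise: SNR ~ sqrt(mAs)
        roi = ROI(100, 100, 64, 64)
        snrs = []
        for mas in (50.0, 200.0):
            phantom, beam, det, exposure = _uniform_setup(gain=84.0, mas=mas, enoise=0.0)
            m = mq.build_mean_signal_map(phantom, beam, det, exposure, supersample=1)
            img = mq.simulate_acquisition(m, det, seed=int(mas))
            snrs.append(snr(img, roi))
        se = snrs[1] * np.sqrt(1.0 / (2 * (roi.height * roi.width - 1))) * np.sqrt(2)
        assert abs(snrs[1] / snrs[0] - 2.0) < 3 * se / snrs[0] + 0.02

    def test_mean_map_below_offset_rejected(self, cfg):
        bad = np.full((32, 32), cfg.detector.dc_offset - 5.0)
        with pytest.raises(ConfigurationError):
            mq.simulate_acquisition(bad, cfg.detector, seed=1)


class TestAecServo:
    def test_uniform_phantom_same_mas_everywhere(self, cfg):
        flat = mq.PhantomSpec(pmma_thickness_mm=45.0,
                              lateral_size_mm=cfg.detector.area_mm)
        mas = {p: mq.emulate_aec(flat, cfg.beam, cfg.detector, p, aec=cfg.aec).mas
               for p in range(1, 8)}
        assert len(set(mas.values())) == 1

    def test_cu_coverage_ratio_matches_transmission(self, cfg):
        # positions 1-2 fully under Cu, 4 fully clear: ratio = 1/T(Cu)
        m1 = mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector, 1, aec=cfg.aec).mas
        m4 = mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector, 4, aec=cfg.aec).mas
        t_cu = np.exp(-cfg.beam.mu_of("Cu") * cfg.phantom.cu.thickness_mm)
        assert abs(m1 - m4 / t_cu) <= 2 * cfg.aec.mas_quantum

    def test_misused_positions_draw_more_mas(self, cfg):
        mas = [mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector, p, aec=cfg.aec).mas
               for p in range(1, 8)]
        assert min(mas[:3]) > max(mas[3:])

    def test_mas_monotone_in_cu_coverage(self, cfg):
        # coverage decreases monotonically with position in this layout
        mas = [mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector, p, aec=cfg.aec).mas
               for p in range(1, 8)]
        assert all(a >= b for a, b in zip(mas, mas[1:]))

    def test_kvp_from_thickness_table(self, cfg):
        e = mq.emulate_aec(cfg.phantom, cfg.beam, cfg.detector, 4, aec=cfg.aec)
        assert e.kvp == 28.0
        assert e.mode == "automatic" and e.aec_position == 4

    def test_saturation_error_with_diagnostic(self, cfg):
        thick = mq.PhantomSpec(pmma_thickness_mm=190.0,
                               lateral_size_mm=cfg.detector.area_mm)
        with pytest.raises(SaturationError, match="cap"):
            mq.emulate_aec(thick, cfg.beam, cfg.detector, 4, aec=cfg.aec)


class TestFlatField:
    def test_heel_off_rois_agree_within_noise(self, cfg, flat_exposure):
        det = mq.DetectorSpec(heel=mq.HeelProfile(amplitude=0.0))
        img = mq.generate_flat_field(40.0, det, cfg.beam, flat_exposure, seed=5)
        rois = standard_rois(img.shape)
        stats = {k: (r.extract(img).mean(), r.extract(img).std(ddof=1),
                     r.height * r.width) for k, r in rois.items()}
        labels = list(stats)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                ma, sa, n = stats[a]
                mb, sb, _ = stats[b]
                z = (ma - mb) / np.sqrt(sa ** 2 / n + sb ** 2 / n)
                assert abs(z) < sps.norm.ppf(1 - 0.01 / 2) + 1e-9, (a, b, z)

    def test_default_heel_snr_pattern(self, flat_stack):
        rois = standard_rois(flat_stack[0].shape)
        means = {k: np.mean([snr(img, r) for img in flat_stack])
                 for k, r in rois.items()}
        for corner in ("N1", "N2"):
            drop = 100.0 * (means[corner] - means["C"]) / means["C"]
            assert -30.5 < drop < -20.0, (corner, drop)
        for corner in ("CW1", "CW2"):
            rise = 100.0 * (means[corner] - means["C"]) / means["C"]
            assert 0.0 < rise < 12.0, (corner, rise)

    def test_repeat_cov_within_bound(self, flat_stack):
        rois = standard_rois(flat_stack[0].shape)
        for k, r in rois.items():
            values = [snr(img, r) for img in flat_stack]
            assert cov(values) <= 0.02, (k, cov(values))


def test_scaled_and_larger_frames_agree_on_roi_stats(cfg, flat_exposure):
    """ROI statistics (fixed 64-px ROIs) transfer between frame scales."""
    big = mq.DetectorSpec(area_mm=(89.6, 71.68))
    assert big.shape == (1280, 1024)
    img_small = mq.generate_flat_field(40.0, cfg.detector, cfg.beam, flat_exposure, 21)
    img_big = mq.generate_flat_field(40.0, big, cfg.beam, flat_exposure, 22)
    small = standard_rois(img_small.shape, roi_size=64)
    large = standard_rois(img_big.shape, roi_size=64)
    for k in small:
        s1, s2 = snr(img_small, small[k]), snr(img_big, large[k])
        assert s2 == pytest.approx(s1, rel=0.08), (k, s1, s2)
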