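import numpy as np
import pandas as pd
import pytest

from accelharm.io_formats import RawSignal
from accelharm.measures import (AIParams, CalibrationModel, MIMSParams,
                                autocalibrate, compute_ai, compute_enmo,
                                compute_mad, compute_mims, summarize_minutes,
                                vector_magnitude)


def _sig(x, y, z, fs=80.0):
    return RawSignal(pd.Timestamp("2020-01-01"), fs, x, y, z, 8.0)


@pytest.mark.parametrize("xyz,expected", [
    ((0, 0, 1), 1.0),
    ((0.6, 0.8, 0), 1.0),
    ((0.3, 0.4, 1.2), 1.3),
])
def test_vector_magnitude(xyz, expected):
    assert vector_magnitude(*xyz) == pytest.approx(expected, abs=1e-12)


class TestENMO:
    def test_unit_norm_gives_zero(self):
        n = 80
        assert compute_enmo(_sig(np.zeros(n), np.zeros(n), np.ones(n))) == 0.0

    def test_constant_r_above_one(self):
        n = 80
        sig = _sig(np.zeros(n), np.zeros(n), np.full(n, 1.2))
        assert compute_enmo(sig) == pytest.approx(0.2, abs=1e-12)

    def test_negative_part_is_floored(self):
        # half the samples r=0.5 (floored to 0), half r=1.5 → mean 0.25
        r = np.r_[np.full(40, 0.5), np.full(40, 1.5)]
        sig = _sig(np.zeros(80), np.zeros(80), r)
        assert compute_enmo(sig) == pytest.approx(0.25, abs=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(0, 0.5, (4800, 3)) + [0, 0, 1]
        sig = _sig(*xyz.T)
        r = np.sqrt((xyz**2).sum(axis=1))
        expected = np.mean(np.maximum(r - 1, 0))
        assert compute_enmo(sig) == pytest.approx(expected, abs=1e-9)

    def test_calibration_is_applied(self):
        n = 80
        sig = _sig(np.zeros(n), np.zeros(n), np.full(n, 1.2))
        calib = CalibrationModel(gain=np.array([1, 1, 1 / 1.2]),
                                 offset=np.zeros(3))
        assert compute_enmo(sig, calib) == pytest.approx(0.0, abs=1e-12)


class TestMAD:
    def test_constant_r_gives_zero(self):
        n = 160
        assert compute_mad(_sig(np.zeros(n), np.zeros(n), np.ones(n))) == 0.0

    def test_alternating_r(self):
        r = np.tile([0.9, 1.1], 40)
        sig = _sig(np.zeros(80), np.zeros(80), r)
        assert compute_mad(sig) == pytest.approx(0.1, abs=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(0, 0.4, (80, 3)) + [0, 0, 1]
        sig = _sig(*xyz.T)
        r = np.sqrt((xyz**2).sum(axis=1))
        expected = np.mean(np.abs(r - r.mean()))
        assert compute_mad(sig) == pytest.approx(expected, abs=1e-9)

    def test_single_sample_is_missing(self):
        assert np.isnan(compute_mad(_sig([0.0], [0.0], [1.0])))


class TestAI:
    def test_constant_signal_gives_zero(self):
        n = 4800
        sig = _sig(np.zeros(n), np.zeros(n), np.ones(n))
        assert compute_ai(sig) == 0.0

    def test_noise_variance_cancels_exactly(self):
        # every axis alternates ±c in every sub-epoch → per-axis variance is
        # known; setting σ̄² to that variance cancels AI to 0
        c = 0.05
        n = 4800
        a = np.tile([c, -c], n // 2)
        var = np.var(a[:80], ddof=1)
        sig = _sig(a, a, a)
        # only float rounding in the variance sums survives
        assert compute_ai(sig, AIParams(noise_variance_g2=var)) == \
            pytest.approx(0.0, abs=1e-6)

    def test_single_active_sub_epoch_formula(self):
        # one 1-s sub-epoch with per-axis variance 4 g², rest constant → AI = 2
        fs = 80.0
        n = 4800
        xyz = np.zeros((n, 3))
        rng = np.random.default_rng(2)
        seg = rng.standard_normal((80, 3))
        seg = (seg - seg.mean(0)) / seg.std(0, ddof=1) * 2.0  # variance 4 each axis
        xyz[:80] = seg
        sig = _sig(*xyz.T, fs=fs)
        assert compute_ai(sig) == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(0, 0.3, (4800, 3))
        sig = _sig(*xyz.T)
        expected = 0.0
        for j in range(60):
            seg = xyz[j * 80:(j + 1) * 80]
            expected += np.sqrt(max(np.mean(seg.var(axis=0, ddof=1)), 0))
        assert compute_ai(sig) == pytest.approx(expected, abs=1e-9)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(4)
        xyz = rng.normal(0, 0.3, (4800, 3))
        a = compute_ai(_sig(*xyz.T))
        b = compute_ai(_sig(xyz[:, 2], xyz[:, 0], xyz[:, 1]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_short_sub_epoch_warns_and_contributes_zero(self):
        sig = _sig(np.zeros(81), np.zeros(81), np.ones(81))
        with pytest.warns(UserWarning, match="sub-epoch"):
            assert compute_ai(sig) == 0.0


class TestMIMS:
    def test_all_zero_signal(self):
        n = 4800
        assert compute_mims(_sig(np.zeros(n), np.zeros(n), np.zeros(n))) == 0.0

    def test_pure_gravity_is_removed_by_bandpass(self):
        n = 4800
        sig = _sig(np.zeros(n), np.zeros(n), np.ones(n))
        assert compute_mims(sig) == 0.0

    def test_degree_one_homogeneity_on_in_band_sine(self):
        n = 4800
        t = np.arange(n) / 80.0
        z = np.zeros(n)
        m1 = compute_mims(_sig(0.1 * np.sin(2 * np.pi * t), z, z))
        m2 = compute_mims(_sig(0.2 * np.sin(2 * np.pi * t), z, z))
        assert m2 == pytest.approx(2 * m1, rel=1e-6)
        assert m1 > 0

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(5)
        xyz = rng.normal(0, 0.2, (4800, 3))
        a = compute_mims(_sig(*xyz.T))
        b = compute_mims(_sig(xyz[:, 1], xyz[:, 2], xyz[:, 0]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_out_of_band_signal_is_suppressed(self):
        n = 4800
        t = np.arange(n) / 80.0
        z = np.zeros(n)
        in_band = compute_mims(_sig(0.1 * np.sin(2 * np.pi * 1.0 * t), z, z))
        out_band = compute_mims(_sig(0.1 * np.sin(2 * np.pi * 20.0 * t), z, z))
        assert out_band < 0.05 * in_band

    def test_clipped_run_extrapolation_increases_value(self):
        n = 4800
        t = np.arange(n) / 80.0
        x = 6 * np.sin(2 * np.pi * 1.0 * t)
        clipped = np.clip(x * 1.6, -8, 8)
        z = np.zeros(n)
        with_ext = compute_mims(_sig(clipped, z, z),
                                MIMSParams(extrapolate_clipped=True))
        without = compute_mims(_sig(clipped, z, z),
                               MIMSParams(extrapolate_clipped=False))
        assert with_ext >= without

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            MIMSParams(band_low_hz=6, band_high_hz=5).validate()


class TestAutocalibrate:
    @staticmethod
    def _still_orientation_signals(gain, offset, n_ori=8, seed=0, fs=80.0):
        rng = np.random.default_rng(seed)
        oris = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1],
                         [0.577, 0.577, 0.577], [-0.577, 0.577, -0.577]])[:n_ori]
        sigs = []
        for o in oris:
            true = o / np.linalg.norm(o) + rng.normal(0, 0.003, (int(60 * fs), 3))
            raw = (true - offset) / gain  # so that gain·raw + offset = true
            sigs.append(_sig(*raw.T, fs=fs))
        return sigs

    def test_already_calibrated_data_is_a_fixed_point(self):
        sigs = self._still_orientation_signals(np.ones(3), np.zeros(3))
        cal = autocalibrate(sigs)
        assert np.abs(cal.gain - 1).max() < 1e-3
        assert np.abs(cal.offset).max() < 1e-3

    def test_recovers_injected_miscalibration(self):
        gain = np.array([1.02, 0.98, 1.01])
        offset = np.array([0.01, -0.02, 0.0])
        cal = autocalibrate(self._still_orientation_signals(gain, offset))
        assert np.abs(cal.gain - gain).max() < 1e-3
        assert np.abs(cal.offset - offset).max() < 1e-3
        assert cal.residual_after <= cal.residual_before

    def test_single_orientation_falls_back_to_identity(self):
        sigs = self._still_orientation_signals(np.ones(3), np.zeros(3), n_ori=1)
        with pytest.warns(UserWarning, match="coverage"):
            cal = autocalibrate(sigs)
        assert np.array_equal(cal.gain, np.ones(3))
        assert np.array_equal(cal.offset, np.zeros(3))

    def test_no_still_windows_falls_back_to_identity(self):
        rng = np.random.default_rng(1)
        sig = _sig(*rng.normal(0, 0.5, (4800, 3)).T)
        with pytest.warns(UserWarning, match="still"):
            cal = autocalibrate(sig)
        assert np.array_equal(cal.gain, np.ones(3))


def test_summarize_minutes_aligns_to_calendar_minutes():
    rng = np.random.default_rng(6)
    n = int(80 * 150)  # 2.5 minutes starting at :30
    sig = RawSignal(pd.Timestamp("2020-01-01 08:00:30"), 80.0,
                    *(rng.normal(0, 0.05, (n, 3)) + [0, 0, 1]).T)
    out = summarize_minutes(sig)
    assert list(out.index) == [pd.Timestamp("2020-01-01 08:01"),
                               pd.Timestamp("2020-01-01 08:02")]
    assert set(out.columns) == {"mims", "enmo", "mad", "ai"}
    assert (out >= 0).all().all()
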