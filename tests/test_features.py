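import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ctgbemd.bemd import BivariateSignal, SiftConfig, bemd
from ctgbemd.features import (analytic, extract_features, feature_names,
                              joint_amplitude, joint_frequency, me, mjia,
                              mmam, psi, vmam, wmf)

from conftest import FS, interior, tone

finite_arrays = hnp.arrays(np.float64, st.integers(8, 60),
                           elements=st.floats(-1e6, 1e6, allow_nan=False))


class TestAnalytic:
    def test_pure_tone_amplitude_and_frequency(self):
        a = analytic(tone(0.1, 300), FS)
        assert np.allclose(interior(a.ia), 1.0, rtol=0.01)
        assert np.allclose(interior(a.ifreq), 2 * np.pi * 0.1, rtol=0.01)

    def test_amplitude_scaling(self):
        a = analytic(2.5 * tone(0.1, 300), FS)
        assert np.allclose(interior(a.ia), 2.5, rtol=0.01)

    def test_chirp_frequency_increases(self):
        from scipy.signal import chirp
        t = np.arange(int(600 * FS)) / FS
        x = chirp(t, f0=0.05, f1=0.4, t1=600)
        a = analytic(x, FS)
        f = interior(a.ifreq)
        # smooth out estimator ripple before testing monotonicity
        f_s = np.convolve(f, np.ones(41) / 41, mode="valid")
        assert np.mean(np.diff(f_s) > 0) > 0.95
        assert f_s[-1] > f_s[0] * 3

    def test_all_zero_series_flagged_degenerate(self):
        a = analytic(np.zeros(100), FS)
        assert a.degenerate
        np.testing.assert_array_equal(a.ip, 0.0)

    def test_unwrapped_phase_is_continuous(self):
        a = analytic(tone(0.25, 300), FS)
        assert np.abs(np.diff(a.ip)).max() < np.pi


class TestJointEstimates:
    def test_three_four_five(self):
        np.testing.assert_allclose(
            joint_amplitude(np.full(5, 3.0), np.full(5, 4.0)), 5.0)

    def test_zero_channel_collapses_to_other(self):
        ia = np.linspace(0, 2, 20)
        np.testing.assert_allclose(joint_amplitude(ia, np.zeros(20)), ia)

    @settings(deadline=None, derandomize=True)
    @given(finite_arrays)
    def test_pythagorean_identity_and_symmetry(self, x):
        y = np.abs(x[::-1])
        x = np.abs(x)
        am = joint_amplitude(x, y)
        np.testing.assert_allclose(am ** 2, x ** 2 + y ** 2, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(am, joint_amplitude(y, x))

    def test_joint_frequency_equal_amplitudes_is_mean(self):
        if_f, if_u = np.array([1.0, 2.0]), np.array([3.0, 6.0])
        ones = np.ones(2)
        np.testing.assert_allclose(joint_frequency(ones, if_f, ones, if_u),
                                   (if_f + if_u) / 2)

    def test_joint_frequency_single_channel_limit(self):
        if_f = np.array([0.5, 0.7])
        np.testing.assert_allclose(
            joint_frequency(np.ones(2), if_f, np.zeros(2), np.ones(2)), if_f)

    def test_joint_frequency_weighted_case(self):
        # amplitudes (1, 2) -> weights (1, 4); freqs (1, 4) -> 3.4 rad/s
        out = joint_frequency(np.array([1.0]), np.array([1.0]),
                              np.array([2.0]), np.array([4.0]))
        np.testing.assert_allclose(out, [3.4])

    def test_joint_frequency_undefined_sample_is_nan(self):
        out = joint_frequency(np.zeros(1), np.ones(1), np.zeros(1), np.ones(1))
        assert np.isnan(out[0])


class TestScalarFeatures:
    def test_mjia(self):
        assert mjia(np.full(7, 4.2)) == pytest.approx(4.2)
        assert mjia(np.array([0.0, 2.0])) == 1.0
        x = np.random.default_rng(0).uniform(size=50)
        assert mjia(x) == pytest.approx(mjia(x[::-1]))

    def test_mmam_constant_and_ramp(self):
        assert mmam(np.ones(100), FS) == 0.0
        ramp = np.linspace(0, 1, int(100 * FS) + 1)  # 0 -> 1 over 100 s
        assert mmam(ramp, FS) == pytest.approx(0.01)
        assert mmam(ramp[::-1], FS) == pytest.approx(-0.01)

    def test_vmam_ramp_zero_and_alternating(self):
        ramp = np.linspace(0, 3, 200)
        assert vmam(ramp, FS) == pytest.approx(0.0, abs=1e-20)
        d = 0.7
        saw = np.zeros(100)
        saw[1::2] = d  # derivative alternates +-d at fs = 1
        assert vmam(saw, 1.0) == pytest.approx(d ** 2, rel=1e-3)
        assert vmam(saw, 1.0) >= 0

    def test_wmf_closed_forms(self):
        assert wmf(np.ones(10), np.full(10, 0.9)) == pytest.approx(0.9)
        assert wmf(np.array([1.0, 1.0]), np.array([1.0, 3.0])) == pytest.approx(2.5)
        # scale invariance in amplitude
        ia = np.array([0.2, 1.4, 0.7])
        f = np.array([1.0, 2.0, 3.0])
        assert wmf(5.0 * ia, f) == pytest.approx(wmf(ia, f))

    def test_wmf_undefined_for_nonpositive_denominator(self):
        assert np.isnan(wmf(np.ones(4), np.array([-1.0, -1.0, 1.0, 1.0])))

    def test_me_closed_forms(self):
        assert me(np.ones(10)) == 0.0
        assert me(np.full(10, 3.0)) == pytest.approx(2 * np.log(3.0))
        assert me(tone(0.1, 3000)) == pytest.approx(np.log(0.5), abs=5e-3)
        assert np.isnan(me(np.zeros(10)))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_me_scaling_law(self, c):
        x = np.sin(np.arange(64.0))
        assert me(c * x) == pytest.approx(me(x) + 2 * np.log(c), rel=1e-9)


class TestPSI:
    def test_identical_phases_give_exactly_one(self):
        ip = np.cumsum(np.random.default_rng(1).uniform(0, 0.5, 500))
        assert psi(ip, ip) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_gives_one(self):
        ip = np.linspace(0, 40, 700)
        assert psi(ip, ip - 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_random_phases_near_zero(self):
        rng = np.random.default_rng(2)
        dphi = rng.uniform(0, 2 * np.pi, 10_000)
        assert psi(dphi, np.zeros(10_000)) < 0.05

    @settings(deadline=None, derandomize=True)
    @given(finite_arrays, st.floats(-50, 50))
    def test_bounds_and_shift_invariance(self, ip, c):
        ip2 = np.sin(ip)  # a second, different phase series
        val = psi(ip, ip2)
        assert 0.0 <= val <= 1.0
        assert psi(ip + c, ip2) == pytest.approx(val, abs=1e-9)


class TestExtractFeatures:
    def test_forty_finite_features_from_five_imfs(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=2400) + 1j * rng.normal(size=2400)
        res = bemd(BivariateSignal(z, FS), SiftConfig(max_imfs=5))
        assert res.n_imfs == 5
        feats = extract_features(res)
        assert list(feats.index) == feature_names(5)
        assert feats.size == 40
        assert np.isfinite(feats.to_numpy()).all()

    def test_identical_channels_have_unit_psi_everywhere(self):
        x = tone(0.25, 300) + 1.5 * tone(0.02, 300)
        res = bemd(BivariateSignal(x + 1j * x, FS), SiftConfig(max_imfs=5))
        feats = extract_features(res)
        for m in range(1, res.n_imfs + 1):
            assert feats[f"psi_{m}"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_imfs_yield_nan_features(self):
        # a pure rotation has a single mode; higher-index features are absent
        t = np.arange(int(300 * FS)) / FS
        z = np.exp(2j * np.pi * 0.1 * t)
        res = bemd(BivariateSignal(z, FS), SiftConfig(max_imfs=5))
        feats = extract_features(res)
        assert res.n_imfs < 5
        assert np.isnan(feats[f"mjia_{5}"])

    def test_time_reversal_symmetry_of_definitions(self):
        rng = np.random.default_rng(12)
        a = np.abs(rng.normal(size=200)) + 0.5
        assert mjia(a[::-1]) == pytest.approx(mjia(a))
        assert vmam(a[::-1], FS) == pytest.approx(vmam(a, FS))
        assert mmam(a[::-1], FS) == pytest.approx(-mmam(a, FS))
        x = rng.normal(size=200)
        assert me(x[::-1]) == pytest.approx(me(x))
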