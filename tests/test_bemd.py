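import numpy as np
import pytest

from ctgbemd.bemd import (BivariateSignal, DecompositionError, SiftConfig,
                          bemd, directional_envelopes, emd_univariate,
                          local_mean, project, sift)

from conftest import FS, fft_peak_hz, interior, rotation, tone


class TestProject:
    def test_theta_zero_returns_real_channel(self):
        z = np.arange(10.0) + 1j * np.ones(10)
        np.testing.assert_allclose(project(z, 0.0), np.arange(10.0))

    def test_theta_half_pi_returns_imaginary_channel(self):
        rng = np.random.default_rng(0)
        f, u = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(project(f + 1j * u, np.pi / 2), u, atol=1e-12)

    def test_periodic_in_theta(self):
        z = rotation(0.1, 60)
        np.testing.assert_allclose(project(z, 1.3), project(z, 1.3 + 2 * np.pi),
                                   atol=1e-12)


class TestEnvelopes:
    def test_pure_rotation_envelopes_on_unit_circle(self):
        z = rotation(0.05, 600)
        envs = directional_envelopes(z, SiftConfig())
        assert envs.shape[0] >= 60
        mods = np.abs(interior(envs.T)).T  # trim ends, keep direction axis
        np.testing.assert_allclose(mods, 1.0, rtol=0.02)

    def test_constant_signal_has_no_envelopes(self):
        envs = directional_envelopes(np.full(100, 2.0 + 1j), SiftConfig())
        assert envs.shape[0] == 0
        with pytest.raises(DecompositionError):
            local_mean(np.full(100, 2.0 + 1j))

    def test_four_direction_maxima_phases(self):
        # z = e^{j w t}: projection onto theta peaks where phase = theta
        z = rotation(0.05, 400)
        cfg = SiftConfig(n_directions=4)
        t = np.arange(z.size) / FS
        phase = (2 * np.pi * 0.05 * t) % (2 * np.pi)
        from scipy.signal import find_peaks
        for k in range(1, 5):
            theta = 2 * np.pi * k / 4
            idx, _ = find_peaks(project(z, theta))
            # maxima occur where the rotation passes direction theta
            want = theta % (2 * np.pi)
            err = np.abs(np.angle(np.exp(1j * (phase[idx] - want))))
            assert err.max() < 0.1


class TestLocalMean:
    def test_small_oscillation_about_constant(self):
        c = 3.0 - 2.0j
        eps = 0.05
        z = c + eps * rotation(0.1, 300)
        m = local_mean(z, SiftConfig())
        assert np.abs(interior(m) - c).max() < 5 * eps

    def test_shift_equivariance(self):
        z = rotation(0.1, 300) + 0.3 * rotation(0.02, 300)
        c = 1.5 + 0.7j
        m0 = local_mean(z, SiftConfig())
        m1 = local_mean(z + c, SiftConfig())
        assert np.abs(interior(m1 - m0) - c).max() < 0.05 * abs(c)


class TestSift:
    def test_first_imf_takes_fast_component(self):
        z = rotation(0.25, 600) + 2.0 * rotation(0.02, 600)
        imf, rest, capped = sift(z, SiftConfig())
        assert fft_peak_hz(imf.real) == pytest.approx(0.25, abs=1 / 600)
        assert fft_peak_hz(imf.imag) == pytest.approx(0.25, abs=1 / 600)

    def test_pure_rotation_is_its_own_imf(self):
        z = rotation(0.1, 600)
        imf, rest, _ = sift(z, SiftConfig())
        assert np.mean(np.abs(rest) ** 2) < 0.01 * np.mean(np.abs(z) ** 2)

    def test_monotonic_signal_stops_decomposition(self):
        t = np.arange(200.0)
        out = bemd(BivariateSignal(t + 2j * t, FS))
        assert out.n_imfs == 0
        np.testing.assert_array_equal(out.residual, t + 2j * t)


class TestBEMD:
    def test_two_tone_mode_alignment(self, two_tone_imfs):
        res = two_tone_imfs
        n = res.residual.size
        bin_hz = FS / n
        # fast tone in IMF1, both channels
        assert abs(fft_peak_hz(res.channel(1, "fhr")) - 0.25) <= bin_hz
        assert abs(fft_peak_hz(res.channel(1, "uc")) - 0.25) <= bin_hz
        # slow tone in a common later IMF, both channels
        slow = [m for m in range(2, res.n_imfs + 1)
                if abs(fft_peak_hz(res.channel(m, "fhr")) - 0.02) <= bin_hz
                and abs(fft_peak_hz(res.channel(m, "uc")) - 0.02) <= bin_hz]
        assert slow, "no IMF carries the 0.02 Hz tone in both channels"

    def test_completeness(self, two_tone_signal, two_tone_imfs):
        z = two_tone_signal.z
        err = np.abs(two_tone_imfs.reconstruct() - z).max() / np.abs(z).max()
        assert err < 1e-9

    def test_broadband_yields_requested_imf_count(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=2400) + 1j * rng.normal(size=2400)
        res = bemd(BivariateSignal(z, FS), SiftConfig(max_imfs=5))
        assert res.n_imfs == 5
        err = np.abs(res.reconstruct() - z).max() / np.abs(z).max()
        assert err < 1e-9

    def test_spectral_ordering_on_broadband(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=2400) + 1j * rng.normal(size=2400)
        res = bemd(BivariateSignal(z, FS), SiftConfig(max_imfs=5))
        peaks = [max(fft_peak_hz(res.channel(m, "fhr")),
                     fft_peak_hz(res.channel(m, "uc")))
                 for m in range(1, res.n_imfs + 1)]
        for a, b in zip(peaks, peaks[1:]):
            assert b <= a * 1.1

    def test_direction_count_stability(self, two_tone_signal):
        # doubling K moves each IMF's energy by < 5% of the signal energy
        r32 = bemd(two_tone_signal, SiftConfig(n_directions=32))
        r64 = bemd(two_tone_signal, SiftConfig(n_directions=64))
        total = np.mean(np.abs(two_tone_signal.z) ** 2)
        for m in range(1, min(r32.n_imfs, r64.n_imfs) + 1):
            e32 = np.mean(np.abs(r32.imfs[m - 1]) ** 2)
            e64 = np.mean(np.abs(r64.imfs[m - 1]) ** 2)
            assert abs(e64 - e32) / total < 0.05

    def test_too_short_input_rejected(self):
        with pytest.raises(DecompositionError):
            bemd(BivariateSignal(np.ones(4, complex), FS))


class TestUnivariateEMD:
    def test_pure_tone_recovered_in_first_imf(self):
        x = tone(0.1, 600)
        imfs, res = emd_univariate(x, SiftConfig())
        c = np.corrcoef(interior(imfs[0]), interior(x))[0, 1]
        assert c > 0.99

    def test_tone_plus_trend_separates(self):
        t = np.arange(int(600 * FS)) / FS
        x = tone(0.1, 600) + 0.01 * t
        imfs, res = emd_univariate(x, SiftConfig())
        assert np.corrcoef(interior(imfs[0]), interior(tone(0.1, 600)))[0, 1] > 0.99
        # trend ends up in the residual chain, not IMF1
        tail = res + sum(imfs[1:]) if len(imfs) > 1 else res
        assert np.corrcoef(interior(tail), interior(0.01 * t))[0, 1] > 0.95

    def test_completeness(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=1200)
        imfs, res = emd_univariate(x, SiftConfig())
        err = np.abs(sum(imfs) + res - x).max() / np.abs(x).max()
        assert err < 1e-9
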