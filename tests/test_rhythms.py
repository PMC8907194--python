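"""Periodograms, cosinor phase, nonparametric indices and DFA."""

import numpy as np
import pytest

from actimetry import rhythms
from actimetry.errors import ParameterError, RangeError
from actimetry.rhythms import (
    chi_square_periodogram,
    cosinor_phase,
    dfa,
    lomb_scargle_periodogram,
    nonparametric_stats,
)


class TestChiSquare:
    def test_exact_periodicity_identity(self, rng):
        # on an exactly P-periodic series, Q_P = P (bins per period)
        for _ in range(5):
            P = int(rng.integers(18, 30))
            profile = rng.poisson(5.0, P).astype(float)
            if profile.std() == 0:
                profile[0] += 1
            x = np.tile(profile, 6)
            pg = chi_square_periodogram(x, (16.0, 32.0), bin_h=1.0)
            j = int(np.argmin(np.abs(pg.periods_h - P)))
            assert pg.power[j] == pytest.approx(P, rel=1e-12)

    def test_constant_series_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            pg = chi_square_periodogram(np.full(200, 3.0), (16.0, 32.0), bin_h=1.0)
        assert np.isnan(pg.peak_period_h)

    def test_poisson_sinusoid_peak_at_24h(self):
        rng = np.random.default_rng(7)
        bin_h = 1 / 6  # 10-min bins
        t = np.arange(0, 240, bin_h)
        rate = 10 + 6 * np.cos(2 * np.pi * t / 24)
        x = rng.poisson(rate).astype(float)
        pg = chi_square_periodogram(x, (16.0, 32.0), bin_h=bin_h)
        assert abs(pg.peak_period_h - 24.0) <= bin_h + 1e-9
        assert pg.peak_significant

    def test_too_short_series_rejected(self):
        with pytest.raises(RangeError):
            chi_square_periodogram(np.ones(20), (16.0, 32.0), bin_h=1.0)

    def test_significance_line_scaling(self):
        # chi2 quantile with P-1 dof, Bonferroni over the grid, divided by
        # the K complete cycles that the power normalization folds away
        from scipy import stats

        x = np.tile(np.arange(24.0), 4)
        pg = chi_square_periodogram(x, (20.0, 28.0), alpha=0.05, bin_h=1.0)
        m = len(pg.periods_h)
        j = int(np.argmin(np.abs(pg.periods_h - 24)))
        expected = stats.chi2.ppf(1 - 0.05 / m, 24 - 1) / (96 // 24)
        assert pg.significance_level[j] == pytest.approx(expected)


class TestLombScargle:
    def test_noiseless_sinusoid_peak(self):
        t = np.arange(0, 120, 0.25)
        y = 4 + 2 * np.cos(2 * np.pi * t / 21.5)
        pg = lomb_scargle_periodogram(y, (16.0, 32.0), bin_h=0.25)
        step = pg.periods_h[1] - pg.periods_h[0]
        assert abs(pg.peak_period_h - 21.5) <= step

    def test_gaps_allowed(self):
        t = np.arange(0, 96, 0.5)
        y = 3 + np.cos(2 * np.pi * t / 24)
        y[50:70] = np.nan
        pg = lomb_scargle_periodogram(y, (16.0, 32.0), bin_h=0.5)
        assert abs(pg.peak_period_h - 24.0) < 0.5

    def test_circatidal_distinguished_from_daily(self):
        rng = np.random.default_rng(11)
        bin_h = 1 / 6
        t = np.arange(0, 8 * 24, bin_h)
        rate = 40 + 30 * np.cos(2 * np.pi * t / 12.4)
        x = rng.poisson(rate).astype(float)
        pg = lomb_scargle_periodogram(x, (8.0, 32.0), n_periods=1024, bin_h=bin_h)
        assert abs(pg.peak_period_h - 12.4) < 0.2

    def test_shuffled_counts_rarely_significant(self):
        # permutation calibration of the alpha=0.05 false-alarm line
        rng = np.random.default_rng(3)
        base = rng.poisson(5.0, 288).astype(float)
        n_exceed = 0
        n_perm = 60
        for _ in range(n_perm):
            y = rng.permutation(base)
            pg = lomb_scargle_periodogram(y, (16.0, 32.0), n_periods=256,
                                          bin_h=1 / 6)
            if pg.peak_power > pg.significance_level[0]:
                n_exceed += 1
        assert n_exceed <= 0.05 * n_perm + 2

    def test_constant_series_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            pg = lomb_scargle_periodogram(np.full(100, 2.0), (16.0, 32.0), bin_h=1.0)
        assert np.isnan(pg.peak_period_h)


class TestCosinor:
    def test_generating_phase_recovered(self):
        t = np.arange(72.0)
        y = np.cos(2 * np.pi * (t - 6) / 24)
        out = cosinor_phase(y, bin_h=1.0)
        assert out["acrophase_h"] == pytest.approx(6.0, abs=0.05)
        assert out["activity_phase_h"] == pytest.approx(6.0, abs=0.05)

    def test_constant_offset_leaves_acrophase(self):
        t = np.arange(72.0)
        y = np.cos(2 * np.pi * (t - 6) / 24)
        a = cosinor_phase(y, bin_h=1.0)
        b = cosinor_phase(y + 11.0, bin_h=1.0)
        assert b["acrophase_h"] == pytest.approx(a["acrophase_h"], abs=0.05)

    def test_square_wave_acrophase_at_center(self):
        # active during the 10 light hours (ZT0-10): peak at the window center
        t = np.arange(0, 96, 0.25)
        y = (np.mod(t, 24) < 10).astype(float) * 5
        out = cosinor_phase(y, bin_h=0.25)
        assert out["acrophase_h"] == pytest.approx(5.0, abs=0.5)

    def test_stage1_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 96, 0.5)
        y = 3 + 2 * np.cos(2 * np.pi * (t - 17.2) / 24) + rng.normal(0, 0.3, t.size)
        out = cosinor_phase(y, bin_h=0.5)
        # oracle: dense grid search over phase of a unit cosine regressor
        phis = np.arange(0, 24, 0.01)
        rss = [
            np.linalg.lstsq(
                np.column_stack([np.ones_like(t), np.cos(2 * np.pi * (t - p) / 24)]),
                y, rcond=None,
            )[1][0]
            for p in phis
        ]
        best = phis[int(np.argmin(rss))]
        assert out["stage1_acrophase_h"] == pytest.approx(best, abs=0.02)

    def test_too_short_span_rejected(self):
        with pytest.raises(ParameterError):
            cosinor_phase(np.ones(30), bin_h=1.0)


class TestNonparametric:
    def test_is_one_on_replicated_profile(self, rng):
        profile = rng.poisson(4.0, 24).astype(float)
        profile[0] += 1
        x = np.tile(profile, 5)
        out = nonparametric_stats(x)
        assert out["IS"] == pytest.approx(1.0)

    def test_iid_noise_expectations(self):
        # E[IS] ~ 1/K and E[IV] ~ 2 for white noise over K days
        rng = np.random.default_rng(42)
        K = 8
        iss, ivs = [], []
        for _ in range(200):
            x = rng.normal(10, 2, K * 24)
            out = nonparametric_stats(x)
            iss.append(out["IS"])
            ivs.append(out["IV"])
        assert np.mean(iss) == pytest.approx(1 / K, abs=0.02)
        assert np.mean(ivs) == pytest.approx(2.0, abs=0.05)

    def test_block_profile_ra_one(self):
        profile = np.concatenate([np.full(10, 7.0), np.zeros(14)])
        x = np.tile(profile, 3)
        out = nonparametric_stats(x)
        assert out["RA"] == pytest.approx(1.0)
        assert out["M10"] == pytest.approx(7.0)
        assert out["L5"] == pytest.approx(0.0)
        assert out["M10_onset_h"] == 0.0

    def test_m10_l5_wrap_around_midnight(self):
        # most active block crossing the day boundary is still found
        profile = np.zeros(24)
        profile[19:] = 9.0
        profile[:5] = 9.0
        x = np.tile(profile, 3)
        out = nonparametric_stats(x)
        assert out["M10"] == pytest.approx(9.0)
        assert out["M10_onset_h"] == 19.0

    def test_bounds(self, rng):
        for _ in range(10):
            x = rng.poisson(3.0, 96).astype(float)
            if x.std() == 0:
                continue
            out = nonparametric_stats(x)
            assert 0 <= out["IS"] <= 1 + 1e-12
            assert out["IV"] >= 0
            assert 0 <= out["RA"] <= 1

    def test_constant_series_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            out = nonparametric_stats(np.full(72, 5.0))
        assert np.isnan(out["IS"])


class TestDFA:
    def test_white_noise_exponent(self):
        rng = np.random.default_rng(8)
        alphas = [
            dfa(rng.standard_normal(4096), scale_range=(4, 512))["scaling_exponent"]
            for _ in range(5)
        ]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.06)

    def test_brownian_exponent(self):
        rng = np.random.default_rng(9)
        alphas = [
            dfa(np.cumsum(rng.standard_normal(4096)),
                scale_range=(4, 512))["scaling_exponent"]
            for _ in range(5)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    @pytest.mark.parametrize("target", [0.6, 0.8, 1.0])
    def test_spectral_surrogate_recovery(self, target):
        # 1/f^beta surrogates with beta = 2*alpha - 1 have DFA exponent alpha
        rng = np.random.default_rng(int(target * 10))
        beta = 2 * target - 1
        n = 8192
        freqs = np.fft.rfftfreq(n, d=1.0)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** (-beta / 2)
        phases = rng.uniform(0, 2 * np.pi, len(freqs))
        spec = amp * np.exp(1j * phases)
        x = np.fft.irfft(spec, n)
        out = dfa(x, scale_range=(8, 1024))
        assert out["scaling_exponent"] == pytest.approx(target, abs=0.1)

    def test_affine_invariance(self, rng):
        x = rng.poisson(5.0, 2048).astype(float)
        a = dfa(x, scale_range=(4, 256))["scaling_exponent"]
        b = dfa(3.5 * x + 11, scale_range=(4, 256))["scaling_exponent"]
        assert b == pytest.approx(a, rel=1e-9)

    def test_bad_scale_range_rejected(self):
        with pytest.raises(ParameterError):
            dfa(np.random.default_rng(0).normal(size=100), scale_range=(4, 50))
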