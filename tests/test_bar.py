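"""BAR identification, K2/CK2 spectral causality, band averaging."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import linalg as sla
from scipy import signal as ssig
from scipy import stats

from ckcoh import (
    BARModel,
    CausalCoherence,
    band_average,
    causal_squared_coherence,
    fit_bar,
    normalize_and_detrend,
    preset,
    simulate_coupled_pair,
    spectral_matrix,
    squared_coherence,
)
from ckcoh.exceptions import DegenerateSeriesError, EmptyBandError
from conftest import random_stable_bar_model


class TestNormalizeAndDetrend:
    def test_pure_ramp_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            normalize_and_detrend(np.arange(1.0, 257.0))

    def test_zero_mean_unit_variance(self, rng):
        out = normalize_and_detrend(rng.normal(5.0, 3.0, 256))
        assert abs(out.mean()) < 1e-10
        assert abs(out.var() - 1.0) < 1e-10

    def test_trend_removed(self):
        n = np.arange(256.0)
        x = np.sin(2 * np.pi * 0.1 * n) + 0.01 * n
        out = normalize_and_detrend(x)
        slope = np.polyfit(n, out, 1)[0]
        assert abs(slope) < 1e-10
        assert abs(out.var() - 1.0) < 1e-10


def _unidirectional_pair(rng, n=2048, gain=0.8):
    """y(n) = gain * x(n-1) + w(n), x white noise."""
    x = rng.normal(size=n)
    y = np.empty(n)
    y[0] = rng.normal()
    y[1:] = gain * x[:-1] + rng.normal(size=n - 1)
    return x, y


class TestFitBAR:
    def test_cross_coefficient_recovery(self, rng):
        hits = 0
        for _ in range(100):
            x, y = _unidirectional_pair(rng)
            model = fit_bar(x, y, order_range=(5, 5), latency=(1, 1))
            hits += abs(model.coef[1, 1, 0] - 0.8) <= 0.05
        assert hits >= 90

    def test_independent_noise_cross_coefficients_small(self, rng):
        pooled = []
        for _ in range(100):
            x = rng.normal(size=256)
            y = rng.normal(size=256)
            model = fit_bar(x, y, latency=(0, 1))
            pooled.extend(np.abs(model.coef[:, 0, 1]))
            pooled.extend(np.abs(model.coef[1:, 1, 0]))
        pooled = np.array([v for v in pooled if v != 0.0])
        assert np.mean(pooled < 2.5 / np.sqrt(256)) >= 0.93

    def test_deterministic(self, rng):
        x = rng.normal(size=256)
        y = rng.normal(size=256)
        m1 = fit_bar(x, y)
        m2 = fit_bar(x, y)
        assert np.array_equal(m1.coef, m2.coef)
        assert m1.lambdas == m2.lambdas

    def test_latency_structure_enforced(self, rng):
        x, y = rng.normal(size=(2, 256))
        model = fit_bar(x, y, latency=(0, 1))
        assert model.coef[0, 1, 0] != 0.0  # instantaneous x -> y allowed
        assert model.coef[0, 0, 1] == 0.0  # y -> x starts at lag 1
        with pytest.raises(ValueError):
            fit_bar(x, y, latency=(0, 0))

    def test_order_within_range(self, rng):
        x, y = rng.normal(size=(2, 300))
        model = fit_bar(x, y, order_range=(5, 14))
        assert 5 <= model.order <= 14


def _companion(model):
    p = model.order
    red = model.reduced_form()
    comp = np.zeros((2 * p, 2 * p))
    for k in range(p):
        comp[0:2, 2 * k : 2 * k + 2] = red[k]
    comp[2:, :-2] = np.eye(2 * (p - 1))
    return comp


def _stationary_covariance(model):
    """Oracle: VAR(1) companion-form discrete Lyapunov solve."""
    comp = _companion(model)
    a0 = model.coef[0]
    inv0 = np.linalg.inv(np.eye(2) - a0)
    q = np.zeros_like(comp)
    q[0:2, 0:2] = inv0 @ np.diag(model.lambdas) @ inv0.T
    sigma = sla.solve_discrete_lyapunov(comp, q)
    return sigma[0:2, 0:2]


class TestSpectralMatrix:
    def test_decoupled_channels_have_zero_cross_spectrum(self, rng):
        model = random_stable_bar_model(rng)
        model.coef[:, 0, 1] = 0.0
        model.coef[:, 1, 0] = 0.0
        _, s = spectral_matrix(model)
        assert np.max(np.abs(s[:, 0, 1])) < 1e-14

    def test_diagonal_ar1_closed_form(self):
        coef = np.zeros((2, 2, 2))
        coef[1] = np.diag([0.5, 0.5])
        model = BARModel(order=1, coef=coef, lambdas=(1.0, 1.0),
                         latency=(1, 1), n_samples=256, stable=True)
        f, s = spectral_matrix(model, n_freq=1025)
        assert s[0, 0, 0].real == pytest.approx(4.0)  # 1/|1-0.5|^2 at f=0
        expected = 1.0 / np.abs(1.0 - 0.5 * np.exp(-2j * np.pi * f)) ** 2
        assert np.allclose(s[:, 0, 0].real, expected)

    def test_parseval_against_lyapunov_oracle(self, rng):
        for _ in range(10):
            model = random_stable_bar_model(rng, target_radius=0.8)
            f, s = spectral_matrix(model, n_freq=4097)
            var1 = 2.0 * np.trapezoid(s[:, 0, 0].real, f)
            oracle = _stationary_covariance(model)[0, 0]
            assert var1 == pytest.approx(oracle, rel=1e-4)


class TestSquaredCoherence:
    def test_decoupled_is_zero(self, rng):
        model = random_stable_bar_model(rng)
        model.coef[:, 0, 1] = 0.0
        model.coef[:, 1, 0] = 0.0
        _, k2 = squared_coherence(model)
        assert np.max(k2) < 1e-20

    def test_deterministic_copy_is_one(self):
        # y = x instantaneously, vanishing innovation on channel 2
        coef = np.zeros((2, 2, 2))
        coef[0, 1, 0] = 1.0
        coef[1, 0, 0] = 0.5
        model = BARModel(order=1, coef=coef, lambdas=(1.0, 1e-10),
                         latency=(0, 1), n_samples=256, stable=True)
        _, k2 = squared_coherence(model)
        assert k2.min() > 1.0 - 1e-8

    def test_matches_welch_oracle_on_long_realization(self, rng):
        x, y = _unidirectional_pair(rng, n=2 ** 17)
        model = fit_bar(x[:2048], y[:2048], order_range=(5, 5), latency=(1, 1))
        f, k2 = squared_coherence(model, n_freq=513)
        f_w, coh = ssig.coherence(x, y, fs=1.0, nperseg=1024)
        k2_interp = np.interp(f_w, f, k2)
        # theory: flat coherence 0.64/1.64; compare peak values
        assert abs(k2.max() - coh.max()) < 0.05

    def test_channel_swap_invariance(self, rng):
        model = random_stable_bar_model(rng)
        swap = replace(
            model,
            coef=model.coef[:, ::-1, ::-1].copy(),
            lambdas=model.lambdas[::-1],
            latency=model.latency[::-1],
        )
        _, k2 = squared_coherence(model)
        _, k2s = squared_coherence(swap)
        assert np.max(np.abs(k2 - k2s)) < 1e-10


class TestCausalSquaredCoherence:
    def test_identity_when_reverse_path_absent(self, rng):
        for _ in range(20):
            model = random_stable_bar_model(rng)
            model.coef[:, 0, 1] = 0.0  # structurally unidirectional x -> y
            _, k2 = squared_coherence(model)
            _, ck2 = causal_squared_coherence(model, "xy")
            assert np.max(np.abs(ck2 - k2)) < 1e-10

    def test_reverse_direction_bias_small_at_n256(self, rng):
        cfg = preset("LADDER_5")
        reverse = []
        for seed in range(60):
            x, y, _ = simulate_coupled_pair(replace(cfg, seed=seed))
            est = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(np.column_stack([x, y]))
            if est.stable_:
                reverse.append(est.band_markers()["ck2_yx_hf"])
        assert np.median(reverse) < 0.1

    def test_bidirectional_strictly_below_k2_at_coupling_frequency(self, rng):
        cfg = replace(preset("LADDER_3"), pair_gain_y_to_x=0.6,
                      pair_coupling_lag=1, n_beats=8192, seed=11)
        x, y, _ = simulate_coupled_pair(cfg)
        est = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(np.column_stack([x, y]))
        peak = int(np.argmax(est.k2_))
        assert est.ck2_xy_[peak] > 0.05
        assert est.ck2_yx_[peak] > 0.05
        assert est.ck2_xy_[peak] < est.k2_[peak]
        assert est.ck2_yx_[peak] < est.k2_[peak]

    def test_zeroing_both_pathways_kills_coherence(self, rng):
        model = random_stable_bar_model(rng)
        model.coef[:, 0, 1] = 0.0
        _, ck2 = causal_squared_coherence(model, "yx")  # zeroes x -> y too
        assert np.max(ck2) < 1e-20


class TestBandAverage:
    def test_constant_function(self):
        f = np.linspace(0, 0.5, 1025)
        assert band_average(np.full_like(f, 0.7), f, "lf") == pytest.approx(0.7)
        assert band_average(np.full_like(f, 0.7), f, "hf") == pytest.approx(0.7)

    def test_band_indicator(self):
        f = np.linspace(0, 0.5, 1025)
        indicator = ((f >= 0.15) & (f < 0.4)).astype(float)
        assert band_average(indicator, f, "hf") == pytest.approx(1.0)
        assert band_average(indicator, f, "lf") == pytest.approx(0.0)

    def test_empty_band_error(self):
        f = np.linspace(0.0, 0.02, 11)
        with pytest.raises(EmptyBandError):
            band_average(np.ones_like(f), f, "hf")

    def test_band_selectivity_of_hf_coupling(self):
        cfg = preset("LADDER_4")
        hits, total = 0, 0
        for seed in range(50):
            x, y, _ = simulate_coupled_pair(replace(cfg, seed=seed))
            est = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(np.column_stack([x, y]))
            if not est.stable_:
                continue
            m = est.band_markers()
            total += 1
            hits += m["ck2_xy_hf"] > m["ck2_xy_lf"]
        assert hits / total >= 0.95


class TestInvariants:
    def test_scale_invariance_of_markers(self, rng):
        cfg = preset("LADDER_3", seed=5)
        x, y, _ = simulate_coupled_pair(cfg)
        est1 = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(np.column_stack([x, y]))
        est2 = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(
            np.column_stack([3.7 * x, 0.04 * y])
        )
        m1, m2 = est1.band_markers(), est2.band_markers()
        for key in m1:
            assert abs(m1[key] - m2[key]) < 1e-10

    def test_gain_ladder_monotone_recovery(self):
        """Median coupled-direction CK2 increases along the gain ladder."""
        medians = []
        gains = []
        for i in range(1, 6):
            cfg = preset(f"LADDER_{i}")
            vals = []
            for seed in range(40):
                x, y, truth = simulate_coupled_pair(replace(cfg, seed=seed))
                est = CausalCoherence(mean_hp_s=cfg.mean_hp_s).fit(
                    np.column_stack([x, y])
                )
                if est.stable_:
                    vals.append(est.band_markers()["ck2_xy_hf"])
            medians.append(np.median(vals))
            gains.append(cfg.pair_gain_x_to_y)
        rho = stats.spearmanr(gains, medians).statistic
        assert rho > 0.9

    def test_estimator_sklearn_compatible(self, rng):
        from sklearn.base import clone

        est = CausalCoherence(order_range=(5, 8), mean_hp_s=0.8)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
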