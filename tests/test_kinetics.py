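"""Analytic IRF-convolved kinetics against independent numerical oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from astakin import (
    IRFModel,
    KineticScheme,
    concentrations,
    exp_conv_gauss,
    sequential_amplitudes,
    sequential_scheme,
)
from astakin.kinetics import _ode_concentrations, RATE_SCALE

from conftest import random_scheme


class TestExpConvGauss:
    def test_step_centered_at_mu(self):
        # k = 0 is a Heaviside step convolved with the Gaussian: half height at mu
        assert exp_conv_gauss(0.0, 5.0, 5.0, 0.3) == pytest.approx(0.5)

    def test_delta_irf_limit(self):
        # sigma -> 0 recovers the bare exponential
        val = exp_conv_gauss(0.1, 10.0, 0.0, 1e-6)
        assert val == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_matches_quadrature_convolution(self):
        # independent oracle: numerically convolve exp(-kt)*theta(t) with a
        # unit-area Gaussian by adaptive quadrature
        k, mu, sigma = 0.185, 0.0, 0.05

        def oracle(t):
            val, _ = quad(
                lambda s: np.exp(-k * (t - s))
                * np.exp(-0.5 * ((s - mu) / sigma) ** 2)
                / (sigma * np.sqrt(2 * np.pi)),
                mu - 10 * sigma,
                t,
                limit=200,
            )
            return val

        ts = np.linspace(-0.5, 20.0, 41)
        got = exp_conv_gauss(k, ts, mu, sigma)
        want = np.array([oracle(t) if t > mu - 10 * sigma else 0.0 for t in ts])
        scale = np.abs(want).max()
        assert np.abs(got - want).max() / scale < 1e-6

    def test_no_overflow_for_large_k_sigma(self):
        # naive erfc form overflows around k*sigma ~ 40; the scaled form must not
        val = exp_conv_gauss(50.0, np.array([-1.0, 0.0, 1.0, 100.0]), 0.0, 2.0)
        assert np.all(np.isfinite(val))
        assert np.all(val >= 0)

    def test_monotone_decreasing_after_pulse(self):
        # once the Gaussian pulse has passed, the population can only decay
        k, mu, sigma = 0.5, 0.0, 0.1
        t = np.linspace(mu + 5 * sigma, 30.0, 500)
        v = exp_conv_gauss(k, t, mu, sigma)
        assert np.all(np.diff(v) < 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_input_rejected(self, bad):
        with pytest.raises(ValueError):
            exp_conv_gauss(bad, 1.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            exp_conv_gauss(0.1, bad, 0.0, 0.1)


class TestConcentrations:
    def test_single_compartment_printed_rate(self, sharp_irf):
        # 183 ns^-1 corresponds to a 1000/183 ~ 5.46 ps lifetime
        scheme = KineticScheme(labels=["S1"], K=[[-183.0]], input=[1.0])
        tau = 1000.0 / 183.0
        t = np.array([tau, 2 * tau, 3 * tau])
        C = concentrations(scheme, sharp_irf, t).C[:, 0]
        assert C == pytest.approx(np.exp(-np.array([1.0, 2.0, 3.0])), rel=1e-8)

    def test_two_compartment_chain_vs_expm(self, sharp_irf):
        scheme = sequential_scheme(np.array([800.0, 90.0]))
        t = np.linspace(0.5, 40, 60)
        C = concentrations(scheme, sharp_irf, t).C
        ref = np.array([expm(scheme.K * RATE_SCALE * ti) @ scheme.input for ti in t])
        assert np.abs(C - ref).max() < 1e-8

    def test_closed_two_state_conserves_population(self, fs_irf):
        # forward/backward exchange with zero ground-state loss
        K = np.array([[-300.0, 100.0], [300.0, -100.0]])
        scheme = KineticScheme(labels=["a", "b"], K=K, input=[1.0, 0.0])
        t = np.linspace(1.0, 100.0, 50)  # after the pulse
        C = concentrations(scheme, fs_irf, t).C
        assert C.sum(axis=1) == pytest.approx(np.ones(t.size), abs=1e-9)

    def test_analytic_equals_ode_for_random_schemes(self, fs_irf, rng):
        # 100 random valid schemes: closed form vs stiff numerical integration
        t = np.concatenate([np.linspace(-0.3, 2, 15), np.geomspace(2.5, 3000, 25)])
        worst = 0.0
        for _ in range(100):
            scheme = random_scheme(rng)
            C = concentrations(scheme, fs_irf, t).C
            ref = _ode_concentrations(scheme.K * RATE_SCALE, scheme.input, fs_irf, t)
            peak = np.abs(ref).max()
            worst = max(worst, np.abs(C - ref).max() / peak)
        assert worst < 1e-6

    def test_population_conservation_with_loss(self, fs_irf, rng):
        # augmenting the scheme with an explicit ground-state sink that
        # collects every loss channel makes conservation exact: compartments
        # plus cumulative loss must account for the whole pulse
        for _ in range(10):
            scheme = random_scheme(rng, n_max=4)
            n = scheme.n
            K_aug = np.zeros((n + 1, n + 1))
            K_aug[:n, :n] = scheme.K
            K_aug[n, :n] = scheme.ground_loss()
            aug = KineticScheme(
                labels=scheme.labels + ["sink"],
                K=K_aug,
                input=np.append(scheme.input, 0.0),
            )
            t = np.concatenate([np.linspace(-0.3, 2, 20), np.geomspace(2.5, 3000, 20)])
            C = concentrations(aug, fs_irf, t).C
            after_pulse = t > fs_irf.mu + 6 * fs_irf.sigma
            assert C[after_pulse].sum(axis=1) == pytest.approx(
                np.ones(after_pulse.sum()), abs=1e-6
            )

    def test_degenerate_rates_fall_back_to_ode(self, fs_irf):
        # two identical eigenvalues make the closed form singular; the
        # fallback must still produce the correct kinetics
        scheme = sequential_scheme(np.array([500.0, 500.0]))
        t = np.linspace(-0.3, 30, 80)
        C = concentrations(scheme, fs_irf, t).C
        # oracle: the analytic path on an almost-degenerate chain (relative
        # split 1e-5, well above the 1e-9 fallback threshold) approximates
        # the degenerate kinetics to O(1e-5)
        near = sequential_scheme(np.array([500.0, 500.0 * (1 + 1e-5)]))
        ref = concentrations(near, fs_irf, t).C
        assert np.abs(C - ref).max() < 1e-4 * np.abs(ref).max()

    def test_unsorted_times_rejected(self, fs_irf):
        scheme = sequential_scheme(np.array([100.0]))
        with pytest.raises(ValueError):
            concentrations(scheme, fs_irf, np.array([1.0, 0.5, 2.0]))


class TestSequentialAmplitudes:
    def test_single_component_is_unity(self):
        assert np.allclose(sequential_amplitudes(np.array([3.0])), [[1.0]])

    def test_chain_matches_expm_oracle(self, sharp_irf):
        rates = np.array([1.0, 0.5, 0.1])  # ps^-1
        b = sequential_amplitudes(rates)
        t = np.linspace(0.5, 50, 40)
        g = np.array([exp_conv_gauss(k, t, 0.0, sharp_irf.sigma) for k in rates])
        pop = (b.T @ g).T  # population of compartment l
        Kps = np.diag(-rates) + np.diag(rates[:-1], -1)
        ref = np.array([expm(Kps * ti) @ np.array([1.0, 0, 0]) for ti in t])
        assert np.abs(pop - ref).max() < 1e-8

    def test_equals_general_concentrations_on_chain(self, fs_irf):
        rates_ns = np.array([5000.0, 370.0, 128.0, 4.0])
        t = np.concatenate([np.linspace(-0.3, 2, 30), np.geomspace(2.5, 3500, 40)])
        C = concentrations(sequential_scheme(rates_ns), fs_irf, t).C
        b = sequential_amplitudes(rates_ns * RATE_SCALE)
        g = np.array(
            [exp_conv_gauss(k, t, fs_irf.mu, fs_irf.sigma) for k in rates_ns * RATE_SCALE]
        )
        assert np.abs((b.T @ g).T - C).max() < 1e-9

    def test_506nm_fit_components_peak_in_lifetime_order(self, fs_irf):
        # the six global-analysis rates of the Car-excitation fit, including
        # the printed 2.7 and 7.8 ps components (1000/2.7 and 1000/7.8 ns^-1)
        taus = np.array([0.05, 0.17, 2.7, 7.8, 250.0, 2000.0])
        t = np.concatenate([np.linspace(-0.4, 2, 200), np.geomspace(2.01, 3500, 400)])
        C = concentrations(sequential_scheme(1000.0 / taus), fs_irf, t).C
        peak_times = t[np.argmax(C, axis=0)]
        assert np.all(np.diff(peak_times) > 0)

    def test_near_degenerate_rates_rejected(self):
        with pytest.raises(ValueError, match="concentrations"):
            sequential_amplitudes(np.array([1.0, 1.0 + 1e-12]))

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            sequential_amplitudes(np.array([1.0, -0.5]))


class TestSchemeValidation:
    def test_negative_offdiagonal_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(labels=["a", "b"], K=[[-1.0, -2.0], [0.5, -3.0]], input=[1, 0])

    def test_outflow_exceeding_total_rejected(self):
        # column sum of transfers above the total decay rate is unphysical
        with pytest.raises(ValueError, match="loss"):
            KineticScheme(labels=["a", "b"], K=[[-1.0, 0.0], [2.0, -1.0]], input=[1, 0])

    def test_input_must_normalise(self):
        with pytest.raises(ValueError, match="sum"):
            KineticScheme(labels=["a"], K=[[-1.0]], input=[0.5])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            KineticScheme(labels=["a", "a"], K=np.diag([-1.0, -2.0]), input=[1, 0])
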