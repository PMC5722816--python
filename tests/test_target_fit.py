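"""Target analysis: variable projection, constraints, yields, recovery."""

import numpy as np
import pytest

from astakin import (
    BandShape,
    ConstraintSet,
    FreeRate,
    IRFModel,
    TADataset,
    branching_yields,
    concentrations,
    fit_target,
    generate_dataset,
    load_scheme,
    project_spectra,
)
from astakin.schemes import SchemeDef
from astakin.synthetic_data import default_time_grid


def small_scheme():
    """Compact branched scheme used throughout: a -> (b | ground), b -> ground."""
    return SchemeDef(
        name="toy",
        compartments=["a", "b"],
        transfers={("a", "b"): 300.0},
        losses={"a": 100.0, "b": 50.0},
        input={"a": 1.0},
        irf=IRFModel.from_fwhm_fs(120.0),
    )


def toy_shapes():
    return {
        "a": BandShape([(520, 15, -5.0), (590, 20, 4.0)]),
        "b": BandShape([(560, 25, 6.0)]),
    }


class TestProjectSpectra:
    def test_orthonormal_columns_collapse_to_projection(self, rng):
        # with orthonormal concentration columns the least-squares solution
        # is the plain projection S = C^T Psi
        times = np.linspace(0, 10, 40)
        wl = np.linspace(480, 610, 15)
        M = rng.normal(size=(40, 3))
        Q, _ = np.linalg.qr(M)
        Psi = rng.normal(size=(40, 15))
        from astakin.kinetics import ConcentrationMatrix

        C = ConcentrationMatrix(times=times, C=Q, labels=["x", "y", "z"])
        data = TADataset(times=times, wavelengths=wl, dA=Psi)
        S = project_spectra(C, data).spectra
        assert np.allclose(S, Q.T @ Psi, atol=1e-10)

    def test_noiseless_recovery_is_exact(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 30)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.0, seed=0
        )
        C = concentrations(scheme.to_kinetic_scheme(), fs_irf, times)
        S = project_spectra(C, ds).spectra
        S_true = np.vstack([toy_shapes()[lab](wl) for lab in ["a", "b"]])
        assert np.abs(S - S_true).max() < 1e-10

    def test_zero_region_enforced_exactly(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 720, 40)
        shapes = {
            "a": BandShape([(520, 15, -5.0)]),
            "b": BandShape([(560, 25, 6.0)], zero_regions=[(630.0, 1e4)]),
        }
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), shapes, fs_irf, times, wl, 0.02, seed=1
        )
        cons = ConstraintSet(zero_regions={"b": [(630.0, 1e4)]})
        C = concentrations(scheme.to_kinetic_scheme(), fs_irf, times)
        spec = project_spectra(C, ds, cons)
        band = ds.wavelengths >= 630.0
        assert np.all(spec.spectrum("b")[band] == 0.0)
        # in the zeroed band the remaining compartment alone must fit as well
        # as it would without b present at all
        resid_with = ds.dA[:, band] - C.C @ spec.spectra[:, band]
        S_solo, *_ = np.linalg.lstsq(C.C[:, [0]], ds.dA[:, band], rcond=None)
        resid_solo = ds.dA[:, band] - C.C[:, [0]] @ S_solo
        assert np.sum(resid_with**2) == pytest.approx(np.sum(resid_solo**2), rel=1e-12)

    def test_collinear_compartments_named(self, fs_irf):
        from astakin.kinetics import ConcentrationMatrix

        times = np.linspace(0, 10, 30)
        wl = np.linspace(480, 610, 8)
        col = np.exp(-times / 3.0)
        C = ConcentrationMatrix(
            times=times, C=np.column_stack([col, col]), labels=["p", "q"]
        )
        data = TADataset(times=times, wavelengths=wl, dA=np.outer(col, np.ones(8)))
        with pytest.raises(ValueError, match="p.*q|q.*p"):
            project_spectra(C, data)

    def test_variable_projection_optimality(self, fs_irf, rng):
        # perturbing any spectrum away from the VarPro solution raises cost
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 20)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.05, seed=2
        )
        C = concentrations(scheme.to_kinetic_scheme(), fs_irf, times)
        S = project_spectra(C, ds).spectra
        base = np.sum((ds.dA - C.C @ S) ** 2)
        for _ in range(10):
            dS = rng.normal(0, 0.01, S.shape)
            cost = np.sum((ds.dA - C.C @ (S + dS)) ** 2)
            assert cost > base


class TestFitTarget:
    def test_zero_free_parameters_reduces_to_projection(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 20)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.02, seed=3
        )
        fit = fit_target([ds], [scheme], free=[])
        C = concentrations(scheme.to_kinetic_scheme(), fs_irf, times)
        S = project_spectra(C, ds).spectra
        assert np.allclose(fit.spectra[0].spectra, S)
        assert fit.cost == pytest.approx(np.sum((ds.dA - C.C @ S) ** 2), rel=1e-9)

    def test_cost_matches_recomputed_residual_norm(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 20)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.02, seed=4
        )
        fit = fit_target(
            [ds], [scheme], free=[FreeRate("a->b", [(0, "a", "b")], 250.0)], seed=0
        )
        recomputed = sum(float(np.sum(r**2)) for r in fit.residuals)
        assert fit.cost == pytest.approx(recomputed, abs=1e-9)

    def test_noiseless_rates_recovered_exactly(self, fs_irf):
        # self-consistency at zero noise: free rates return to the
        # generating values to 1e-4 relative
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 30)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.0, seed=5
        )
        free = [
            FreeRate("a->b", [(0, "a", "b")], 450.0),
            FreeRate("b->ground", [(0, "b", None)], 30.0),
        ]
        fit = fit_target([ds], [scheme], free, seed=0, n_starts=1)
        assert fit.rates["a->b"] == pytest.approx(300.0, rel=1e-4)
        assert fit.rates["b->ground"] == pytest.approx(50.0, rel=1e-4)

    def test_noiseless_fig3b_rates_recovered(self, fs_irf):
        # the shipped Car-excitation model, single blue-window dataset
        scheme = load_scheme("fig3b_508")
        from astakin.synthetic_data import _TARGET_SHAPES, window_axis

        times = default_time_grid()
        wl = window_axis("blue")
        ks = scheme.to_kinetic_scheme()
        ds = generate_dataset(ks, _TARGET_SHAPES, scheme.irf, times, wl, 0.0, seed=6)
        free = [
            FreeRate("S1->Chl", [(0, "S1", "Chl")], 500.0),
            FreeRate("Sstar->ground", [(0, "Sstar", None)], 100.0),
        ]
        fit = fit_target([ds], [scheme], free, seed=0, n_starts=1)
        assert fit.rates["S1->Chl"] == pytest.approx(366.0, rel=1e-4)
        assert fit.rates["Sstar->ground"] == pytest.approx(133.0, rel=1e-4)

    def test_bias_shrinks_with_noise(self, fs_irf):
        # parameter-recovery consistency: median bias of a free rate falls
        # as the noise level drops (3 levels, 6 seeded replicates each)
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 30)
        levels = [0.3, 0.03, 0.0]
        med_bias = []
        for noise in levels:
            errs = []
            for rep in range(6):
                ds = generate_dataset(
                    scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl,
                    noise, seed=100 + rep,
                )
                fit = fit_target(
                    [ds], [scheme],
                    [FreeRate("a->b", [(0, "a", "b")], 380.0)],
                    seed=rep, n_starts=1,
                )
                errs.append(abs(fit.rates["a->b"] / 300.0 - 1.0))
            med_bias.append(np.median(errs))
        assert med_bias[0] > med_bias[1] > med_bias[2]
        assert med_bias[2] < 1e-4

    def test_linked_fit_never_beats_unlinked(self, fs_irf):
        # nesting inequality: forcing a spectral link cannot lower the cost
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 20)
        ds1 = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.05, seed=7
        )
        ds2 = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.05, seed=8
        )
        unlinked = fit_target([ds1, ds2], [scheme, scheme], free=[])
        linked = fit_target(
            [ds1, ds2], [scheme, scheme], free=[],
            constraints=ConstraintSet(spectral_links=[[(0, "b"), (1, "b")]]),
        )
        assert linked.cost >= unlinked.cost - 1e-12

    def test_residuals_have_no_structure_when_model_is_correct(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 40)
        noise = 0.05
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, noise, seed=9
        )
        fit = fit_target([ds], [scheme], free=[])
        frac_large = np.mean(np.abs(fit.residuals[0]) > 3 * noise)
        assert frac_large < 0.01

    def test_unknown_edge_rejected(self, fs_irf):
        scheme = small_scheme()
        times = default_time_grid()
        wl = np.linspace(480, 610, 10)
        ds = generate_dataset(
            scheme.to_kinetic_scheme(), toy_shapes(), fs_irf, times, wl, 0.0, seed=0
        )
        with pytest.raises(ValueError, match="not present"):
            fit_target(
                [ds], [scheme], [FreeRate("bad", [(0, "b", "a")], 10.0)]
            )


class TestBranchingYields:
    def test_single_edge_yield_is_one(self):
        scheme = SchemeDef(
            name="s", compartments=["a", "b"],
            transfers={("a", "b"): 100.0}, losses={"b": 10.0}, input={"a": 1.0},
        )
        res = branching_yields(scheme)
        assert res.fractions["a -> b"] == pytest.approx(1.0)
        assert res.yields["a -> b"] == pytest.approx(1.0)
        assert res.ground_yields["b"] == pytest.approx(1.0)

    def test_two_way_split_fractions(self):
        scheme = SchemeDef(
            name="s", compartments=["a", "b", "c"],
            transfers={("a", "b"): 3000.0, ("a", "c"): 1000.0},
            losses={"b": 1.0, "c": 1.0}, input={"a": 1.0},
        )
        res = branching_yields(scheme)
        assert res.fractions["a -> b"] == pytest.approx(0.75)
        assert res.fractions["a -> c"] == pytest.approx(0.25)

    def test_fig3b_yields_match_gillespie(self, rng):
        # stochastic oracle: 10^6 seeded random walkers through the shipped
        # Car-excitation scheme; agreement within 3 binomial sigmas
        scheme = load_scheme("fig3b_508")
        res = branching_yields(scheme)
        comps = scheme.compartments
        idx = {c: i for i, c in enumerate(comps)}
        totals = np.array([scheme.total_rate(c) for c in comps])
        n_walk = 1_000_000
        ground_counts = dict.fromkeys(comps, 0)
        # vectorised Gillespie on the embedded jump chain (exponential
        # waiting times do not affect branch statistics)
        start = rng.choice(
            len(comps), size=n_walk,
            p=[scheme.input.get(c, 0.0) for c in comps],
        )
        state = start.copy()
        alive = np.ones(n_walk, dtype=bool)
        dest = {}
        for j, c in enumerate(comps):
            outs = [(idx[d], r) for (s, d), r in scheme.transfers.items() if s == c]
            loss = scheme.losses.get(c, 0.0)
            targets = [t for t, _ in outs] + [-1]
            probs = np.array([r for _, r in outs] + [loss]) / totals[j]
            dest[j] = (np.array(targets), probs)
        for _ in range(50):  # depth bound; the scheme is a DAG
            if not alive.any():
                break
            for j in np.unique(state[alive]):
                sel = alive & (state == j)
                targets, probs = dest[j]
                nxt = targets[rng.choice(targets.size, size=sel.sum(), p=probs)]
                died = nxt == -1
                ground_counts[comps[j]] += int(died.sum())
                state[sel] = np.where(died, state[sel], nxt)
                alive[sel] &= ~died
        for c, analytic in res.ground_yields.items():
            mc = ground_counts[c] / n_walk
            sigma = np.sqrt(max(analytic * (1 - analytic), 1e-12) / n_walk)
            assert abs(mc - analytic) <= 3 * sigma + 1e-9, c

    def test_zero_total_rate_compartment_rejected(self):
        scheme = SchemeDef(
            name="s", compartments=["a", "b"],
            transfers={("a", "b"): 10.0}, losses={}, input={"a": 1.0},
        )
        with pytest.raises(ValueError, match="zero total"):
            branching_yields(scheme)
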