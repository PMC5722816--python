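"""Parameter-recovery experiments on synthetic data.

These harnesses close the loop the package exists for: generate synthetic
experiments from the shipped kinetic models (or the sequential
global-analysis view), refit them blind, and compare the recovered rate
constants with the generating ones.  They are used by the validation suite
and by the reproduction script, and are importable for interactive use.
"""

from __future__ import annotations

import numpy as np

from .containers import FitResult
from .global_analysis import fit_sequential
from .kinetics import IRFModel
from .schemes import load_scheme
from .synthetic_data import SEQUENTIAL_LIFETIMES_PS, generate_paper_like
from .target_fit import ConstraintSet, FreeRate, fit_target

__all__ = [
    "paper_constraints",
    "paper_free_rates",
    "TARGET_TRUTH_NS",
    "recover_target_rates",
    "recover_global_lifetimes",
    "ps_range_components",
]

#: generating values (ns^-1) of the five rates the target-recovery
#: experiment re-estimates
TARGET_TRUTH_NS = {
    "S1->Chl": 366.0,
    "S1->ground": 183.0,
    "Sstar->ground": 133.0,
    "Sq->ground": 84.0,
    "Chl_a3->Sq": 5.07,
}


def paper_constraints() -> ConstraintSet:
    """The spectral assumptions of the simultaneous two-excitation fit.

    Dataset order convention: 0 = 508 nm/blue window, 1 = 508 nm/red,
    2 = 690 nm/blue, 3 = 690 nm/red.  The constraints are: triplet
    zero-regions (Chl T zero above 630 nm, Car T below); one S_q spectrum
    shared across the two models per window; the unconnected-astaxanthin
    spectra equal to their connected counterparts; and the equilibrated
    Chl spectrum of the Car-excitation model equal to the terminal Chl
    pool of the Chl-excitation model.
    """
    return ConstraintSet(
        zero_regions={"ChlT": [(630.0, 1e4)], "CarT": [(0.0, 630.0)]},
        spectral_links=[
            [(0, "Sq"), (2, "Sq")],
            [(1, "Sq"), (3, "Sq")],
            [(0, "S1"), (0, "uS1")],
            [(1, "S1"), (1, "uS1")],
            [(0, "S2"), (0, "uS2")],
            [(1, "S2"), (1, "uS2")],
            [(0, "Chl"), (2, "Chl_a3")],
            [(1, "Chl"), (3, "Chl_a3")],
        ],
    )


def paper_free_rates(rng: np.random.Generator | None = None, spread: float = 0.2) -> list[FreeRate]:
    """The five free rates of the recovery experiment, with the S_q decay
    linked across all four datasets; inits are log-normally perturbed so
    the fit does not start on the generating values."""

    def init(v: float) -> float:
        if rng is None:
            return v
        return float(v * np.exp(rng.normal(0.0, spread)))

    return [
        FreeRate("S1->Chl", [(0, "S1", "Chl"), (1, "S1", "Chl")], init(366.0)),
        FreeRate("S1->ground", [(0, "S1", None), (1, "S1", None)], init(183.0)),
        FreeRate("Sstar->ground", [(0, "Sstar", None), (1, "Sstar", None)], init(133.0)),
        FreeRate(
            "Sq->ground",
            [(0, "Sq", None), (1, "Sq", None), (2, "Sq", None), (3, "Sq", None)],
            init(84.0),
        ),
        FreeRate("Chl_a3->Sq", [(2, "Chl_a3", "Sq"), (3, "Chl_a3", "Sq")], init(5.07)),
    ]


def recover_target_rates(
    seed: int,
    noise_fraction: float = 0.02,
    n_starts: int = 4,
    perturb: float = 0.15,
) -> FitResult:
    """One replicate of the simultaneous 508/690-nm target recovery.

    Generates both excitations (two windows each) with the given seed,
    then refits the five free rates of :func:`paper_free_rates` from
    perturbed initial values under :func:`paper_constraints`.
    """
    b508, r508 = generate_paper_like(508, seed=seed, noise_fraction=noise_fraction)
    b690, r690 = generate_paper_like(690, seed=seed + 1000, noise_fraction=noise_fraction)
    s508 = load_scheme("fig3b_508")
    s690 = load_scheme("fig3d_690")
    rng = np.random.default_rng(seed + 5)
    return fit_target(
        [b508, r508, b690, r690],
        [s508, s508, s690, s690],
        paper_free_rates(rng),
        paper_constraints(),
        seed=seed,
        n_starts=n_starts,
        perturb=perturb,
    )


def ps_range_components(lifetimes_ps: np.ndarray, lo: float = 1.0, hi: float = 20.0) -> np.ndarray:
    """Fitted lifetimes falling in the picosecond window (sorted ascending);
    for the 508-nm experiment these are the two carotenoid decay constants."""
    taus = np.sort(np.asarray(lifetimes_ps, dtype=float))
    return taus[(taus >= lo) & (taus <= hi)]


def recover_global_lifetimes(
    excitation: int,
    seed: int,
    noise_fraction: float = 0.02,
    n_starts: int = 4,
) -> FitResult:
    """One replicate of the sequential (global-analysis) recovery.

    Generates the excitation's two-window experiment from the unbranched
    chain with the printed lifetimes, then refits the window carrying the
    excitation's reporter bands (blue/carotenoid window at 508 nm,
    red/Chl window at 690 nm) with the generating component count.
    """
    blue, red = generate_paper_like(
        excitation, seed=seed, kind="sequential", noise_fraction=noise_fraction
    )
    dataset = blue if excitation == 508 else red
    n = SEQUENTIAL_LIFETIMES_PS[excitation].size
    return fit_sequential(
        dataset,
        n,
        IRFModel.from_fwhm_fs(120.0),
        seed=seed,
        n_starts=n_starts,
    )
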