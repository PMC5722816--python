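"""Sequential-scheme (global) analysis of a single TA dataset.

Global analysis fits the data matrix with an unbranched kinetic chain
1 → 2 → … → n: every component decays exponentially into the next with
lifetime τ_l, all convolved with the Gaussian IRF.  The spectra of the
chain compartments are the evolution-associated difference spectra (EADS);
the amplitude spectra of the mathematically equivalent parallel
sum-of-exponentials model are the decay-associated difference spectra
(DADS).  Both describe the same fitted matrix exactly — the conversion is
the invertible linear map :func:`dads_from_eads`.

The nonlinear parameters (log-lifetimes, plus the IRF centre and width)
are optimised by seeded multi-start least squares; the EADS are eliminated
by variable projection at every step.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .containers import FitResult, SpectrumSet, TADataset
from .kinetics import IRFModel, concentrations, sequential_amplitudes, sequential_scheme

__all__ = ["fit_sequential", "dads_from_eads", "eads_from_dads"]


def _separate_rates(rates: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    """Nudge (near-)equal rates apart so the chain's eigensystem stays
    regular; the perturbation is far below any fit tolerance but keeps the
    variable-projection objective smooth when the optimizer momentarily
    collapses two lifetimes onto each other."""
    r = rates.copy()
    order = np.argsort(r)
    for a, b in zip(order[:-1], order[1:]):
        gap = rel * max(abs(r[a]), abs(r[b]))
        if r[b] - r[a] < gap:
            r[b] = r[a] + gap
    return r


def _sequential_C(
    lifetimes_ps: np.ndarray, irf: IRFModel, times: np.ndarray
) -> np.ndarray:
    """Concentration matrix of a chain with the given lifetimes (ps)."""
    rates_ns = _separate_rates(1000.0 / lifetimes_ps)
    scheme = sequential_scheme(rates_ns)
    return concentrations(scheme, irf, times).C


def fit_sequential(
    dataset: TADataset,
    n_components: int,
    irf: IRFModel,
    init_lifetimes: np.ndarray | None = None,
    seed: int | None = None,
    n_starts: int = 8,
    perturb: float = 0.3,
    fit_irf: bool = True,
    max_nfev: int | None = None,
) -> FitResult:
    """Global analysis: fit ``n_components`` sequentially decaying species.

    Parameters
    ----------
    dataset : TADataset
        The ΔA matrix to fit.
    n_components : int
        Number of chain compartments; must not exceed the matrix rank.
    irf : IRFModel
        Initial instrument-response centre/width (ps); refined during the
        fit unless ``fit_irf=False``.
    init_lifetimes : array, optional
        Initial lifetimes in ps, positive and increasing.  Default:
        log-spaced between the IRF width and the last delay.
    seed : int
        Seeds the multi-start perturbations (fit is deterministic given it).

    Returns
    -------
    FitResult
        With ascending ``lifetimes`` (ps), equivalent rates (ns^-1), EADS
        and DADS in ``spectra``, the residual matrix and diagnostics.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    rank = np.linalg.matrix_rank(dataset.dA)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the data matrix rank {rank}"
        )
    times, Psi = dataset.times, dataset.dA

    if init_lifetimes is None:
        lo = max(2.0 * irf.sigma, 1e-3)
        hi = max(times[-1] / 2.0, 10 * lo)
        init_lifetimes = np.geomspace(lo, hi, n_components)
    init_lifetimes = np.asarray(init_lifetimes, dtype=float)
    if init_lifetimes.size != n_components:
        raise ValueError("init_lifetimes length must equal n_components")
    if np.any(init_lifetimes <= 0):
        raise ValueError("init lifetimes must be positive")

    def unpack(theta):
        tau = np.exp(theta[:n_components])
        if fit_irf:
            mu, sigma = theta[n_components], np.exp(theta[n_components + 1])
        else:
            mu, sigma = irf.mu, irf.sigma
        return tau, IRFModel(mu=mu, sigma=sigma)

    def residual(theta):
        tau, f = unpack(theta)
        C = _sequential_C(tau, f, times)
        S, *_ = np.linalg.lstsq(C, Psi, rcond=None)
        return (Psi - C @ S).ravel()

    theta0 = np.log(init_lifetimes)
    lb = np.full(n_components, np.log(1e-4))
    ub = np.full(n_components, np.log(1e6))
    if fit_irf:
        theta0 = np.concatenate([theta0, [irf.mu, np.log(irf.sigma)]])
        lb = np.concatenate([lb, [times[0], np.log(irf.sigma / 10.0)]])
        ub = np.concatenate([ub, [times[-1], np.log(irf.sigma * 10.0)]])

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_starts - 1, 0)):
        d = np.zeros_like(theta0)
        d[:n_components] = rng.normal(0.0, perturb, n_components)
        starts.append(theta0 + d)

    best, best_idx = None, 0
    for idx, th0 in enumerate(starts):
        try:
            res = least_squares(
                residual,
                np.clip(th0, lb + 1e-9, ub - 1e-9),
                bounds=(lb, ub),
                method="trf",
                x_scale="jac",
                max_nfev=max_nfev,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or res.cost < best.cost:
            best, best_idx = res, idx
    if best is None:
        raise RuntimeError("global fit failed to converge from any start")

    tau, f = unpack(best.x)
    # canonical ordering: ascending lifetime (the chain is re-solved in
    # that order, so the EADS match the reported lifetimes)
    order = np.argsort(tau)
    tau = tau[order]
    C = _sequential_C(tau, f, times)
    eads_mat, *_ = np.linalg.lstsq(C, Psi, rcond=None)
    residual_matrix = Psi - C @ eads_mat
    cost = float(np.sum(residual_matrix**2))

    labels = [f"comp{i + 1}" for i in range(n_components)]
    eads = SpectrumSet(
        kind="EADS", wavelengths=dataset.wavelengths, spectra=eads_mat, labels=labels
    )
    rates_ns = 1000.0 / tau
    dads = dads_from_eads(eads, rates_ns)

    # approximate lifetime standard errors from the Gauss-Newton Jacobian
    stderr: dict[str, float] = {}
    m, p = best.fun.size, best.x.size
    if m > p:
        s2 = 2.0 * best.cost / (m - p)
        JtJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JtJ) * s2
            # map back through the sort order of the lifetimes
            for rank_i, orig_i in enumerate(order):
                stderr[f"tau{rank_i + 1}_ps"] = float(
                    tau[rank_i] * np.sqrt(max(cov[orig_i, orig_i], 0.0))
                )
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        rates={f"k{i + 1}": float(r) for i, r in enumerate(rates_ns)},
        stderr=stderr,
        spectra=[eads, dads],
        residuals=[residual_matrix],
        cost=cost,
        irf=[(f.mu, f.sigma)],
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        start_index=best_idx,
        seed=seed,
        lifetimes=tau,
        extra={"singular_values": np.linalg.svd(Psi, compute_uv=False)[: n_components + 2]},
    )


def dads_from_eads(eads: SpectrumSet, rates: np.ndarray) -> SpectrumSet:
    """Convert sequential-model EADS to the equivalent parallel-model DADS.

    With b the sequential amplitude matrix (``sequential_amplitudes``), the
    fitted matrix Σ_l c_l(t)·EADS_l(λ) re-groups as Σ_j g(k_j, t)·DADS_j(λ)
    with DADS_j = Σ_{l≥j} b[j, l]·EADS_l — an exact, invertible linear
    transform between the two representations.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size != len(eads.labels):
        raise ValueError("rate count must equal the number of EADS")
    b = sequential_amplitudes(rates)
    dads_mat = b @ eads.spectra
    return SpectrumSet(
        kind="DADS",
        wavelengths=eads.wavelengths,
        spectra=dads_mat,
        labels=list(eads.labels),
    )


def eads_from_dads(dads: SpectrumSet, rates: np.ndarray) -> SpectrumSet:
    """Inverse of :func:`dads_from_eads` (b is triangular and nonsingular)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size != len(dads.labels):
        raise ValueError("rate count must equal the number of DADS")
    b = sequential_amplitudes(rates)
    eads_mat = np.linalg.solve(b, dads.spectra)
    return SpectrumSet(
        kind="EADS",
        wavelengths=dads.wavelengths,
        spectra=eads_mat,
        labels=list(dads.labels),
    )
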