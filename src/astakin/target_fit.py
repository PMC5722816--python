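"""Compartmental target analysis with variable projection.

The estimation problem: given one or more difference-absorption matrices
Ψ_d (time × wavelength) and a compartmental scheme per dataset, find the
free rate constants minimising

    Σ_d ‖ Ψ_d − C_d(rates) · S_dᵀ ‖²

where C_d is the IRF-convolved concentration matrix of dataset d's scheme
and S_d its species-associated difference spectra (SADS).  The spectra are
*linear* parameters and are eliminated analytically at every evaluation of
the nonlinear objective (variable projection): for each wavelength channel
the optimal S is the least-squares solution of Ψ(·, λ) ≈ C · S(λ).

Spectral assumptions supported:

* zero-regions — wavelength intervals where a compartment's SADS is forced
  to be exactly zero (its column is removed from the design there);
* links — groups of (dataset, compartment) pairs sharing a single spectrum;
  the linked datasets' design matrices are stacked and solved jointly;
* shared rates — one free parameter may drive edges in several schemes.

Rates are parametrised on the log scale (they are positive and span four
orders of magnitude) and optimised by seeded multi-start nonlinear least
squares; approximate standard errors come from the Gauss–Newton Jacobian
at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import FitResult, SpectrumSet, TADataset
from .kinetics import IRFModel, concentrations
from .schemes import GROUND, SchemeDef, _edge_key

__all__ = [
    "ConstraintSet",
    "FreeRate",
    "BranchingResult",
    "project_spectra",
    "fit_target",
    "branching_yields",
]


@dataclass
class ConstraintSet:
    """Spectral assumptions applied during the linear (spectra) step.

    ``zero_regions`` maps a compartment label to wavelength intervals
    (nm, inclusive) where its spectrum is forced to zero, in every dataset
    whose scheme contains that label.  ``spectral_links`` lists groups of
    ``(dataset_index, label)`` pairs constrained to share one spectrum;
    the linked datasets must share an identical wavelength axis.
    """

    zero_regions: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    spectral_links: list[list[tuple[int, str]]] = field(default_factory=list)

    def is_zero(self, label: str, wl: np.ndarray) -> np.ndarray:
        """Boolean mask over ``wl`` where ``label``'s spectrum is forced to 0."""
        mask = np.zeros(wl.size, dtype=bool)
        for lo, hi in self.zero_regions.get(label, []):
            mask |= (wl >= lo) & (wl <= hi)
        return mask


@dataclass
class FreeRate:
    """One free rate parameter, possibly shared across schemes.

    ``edges`` lists ``(dataset_index, src, dst)`` triples; ``dst`` of
    ``None`` (or ``"ground"``) denotes the loss-to-ground channel of
    ``src``.  All listed edges are set to the parameter's current value at
    every objective evaluation, which is how the package expresses "this
    rate is constrained to be the same in both models".
    """

    name: str
    edges: list[tuple[int, str, str | None]]
    init: float  # ns^-1

    def __post_init__(self) -> None:
        if self.init <= 0:
            raise ValueError(f"free rate {self.name!r}: init must be positive")
        if not self.edges:
            raise ValueError(f"free rate {self.name!r}: no edges")


# ---------------------------------------------------------------------------
# linear (spectra) step


def _link_groups(n_datasets: int, constraints: ConstraintSet) -> list[list[int]]:
    """Connected components of datasets under the spectral links."""
    parent = list(range(n_datasets))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for group in constraints.spectral_links:
        base = find(group[0][0])
        for ds, _ in group[1:]:
            parent[find(ds)] = base
    comps: dict[int, list[int]] = {}
    for i in range(n_datasets):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _solve_spectra(
    datasets: list[TADataset],
    Cs: list[np.ndarray],
    labels: list[list[str]],
    constraints: ConstraintSet,
    check_conditioning: bool = False,
    weights: list[float] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Optimal constrained spectra for all datasets.

    Returns per-dataset SADS matrices ``S_d`` (n_comp × n_wl), residual
    matrices, and the worst condition number seen over the solved blocks.
    ``weights`` (one scalar per dataset, typically 1/noise σ) make the
    joint solve of linked spectra a weighted least-squares problem.
    """
    n_ds = len(datasets)
    if weights is None:
        weights = [1.0] * n_ds
    # column identity: (ds, label) -> shared column key
    col_of: dict[tuple[int, str], tuple] = {}
    for group in constraints.spectral_links:
        key = ("link",) + tuple(sorted(map(tuple, group)))
        for ds, lab in group:
            if lab not in labels[ds]:
                raise ValueError(f"link references unknown compartment {lab!r} in dataset {ds}")
            col_of[(ds, lab)] = key
    for ds in range(n_ds):
        for lab in labels[ds]:
            col_of.setdefault((ds, lab), (ds, lab))

    S_out = [np.zeros((len(labels[d]), datasets[d].wavelengths.size)) for d in range(n_ds)]
    worst_cond = 0.0

    for group in _link_groups(n_ds, constraints):
        wl = datasets[group[0]].wavelengths
        for d in group[1:]:
            if not np.array_equal(datasets[d].wavelengths, wl):
                raise ValueError(
                    "spectrally linked datasets must share an identical wavelength axis"
                )
        # columns of this group's joint design, in stable order
        cols: list[tuple] = []
        owners: dict[tuple, list[tuple[int, str]]] = {}
        for d in group:
            for lab in labels[d]:
                key = col_of[(d, lab)]
                if key not in owners:
                    owners[key] = []
                    cols.append(key)
                owners[key].append((d, lab))
        n_cols = len(cols)
        # zero-mask per column per channel (a column is zeroed if its label is)
        zero = np.zeros((n_cols, wl.size), dtype=bool)
        for ci, key in enumerate(cols):
            lab = owners[key][0][1]
            zero[ci] = constraints.is_zero(lab, wl)
        # stacked design
        offsets = {}
        total_rows = 0
        for d in group:
            offsets[d] = total_rows
            total_rows += datasets[d].times.size
        A_full = np.zeros((total_rows, n_cols))
        for ci, key in enumerate(cols):
            for d, lab in owners[key]:
                r0 = offsets[d]
                # += so that two linked compartments of the same dataset
                # contribute the sum of their concentration columns
                A_full[r0 : r0 + datasets[d].times.size, ci] += (
                    weights[d] * Cs[d][:, labels[d].index(lab)]
                )
        Psi = np.concatenate([weights[d] * datasets[d].dA for d in group], axis=0)

        # group channels by identical active-column pattern
        patterns: dict[bytes, list[int]] = {}
        for ch in range(wl.size):
            patterns.setdefault((~zero[:, ch]).tobytes(), []).append(ch)
        for patt, channels in patterns.items():
            active = np.frombuffer(patt, dtype=bool)
            if not active.any():
                continue
            A = A_full[:, active]
            if check_conditioning:
                sv = np.linalg.svd(A, compute_uv=False)
                cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
                worst_cond = max(worst_cond, cond)
                if cond > 1e10:
                    bad = _collinear_labels(A, [cols[i] for i in np.where(active)[0]], owners)
                    raise ValueError(
                        "concentration matrix is rank-deficient on the "
                        f"unconstrained set; collinear compartments: {bad}"
                    )
            coef, *_ = np.linalg.lstsq(A, Psi[:, channels], rcond=None)
            for pos, ci in enumerate(np.where(active)[0]):
                for d, lab in owners[cols[ci]]:
                    S_out[d][labels[d].index(lab), channels] = coef[pos]

    residuals = [datasets[d].dA - Cs[d] @ S_out[d] for d in range(n_ds)]
    return S_out, residuals, worst_cond


def _collinear_labels(A: np.ndarray, keys: list, owners: dict) -> list[str]:
    """Name the most correlated compartment pair in a deficient design."""
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    G = np.abs((A / norms).T @ (A / norms))
    np.fill_diagonal(G, 0.0)
    i, j = np.unravel_index(np.argmax(G), G.shape)
    return sorted({owners[keys[i]][0][1], owners[keys[j]][0][1]})


def project_spectra(
    C,
    data: TADataset,
    constraints: ConstraintSet | None = None,
) -> SpectrumSet:
    """Per-wavelength least-squares spectra for one dataset (VarPro linear step).

    For wavelengths inside a compartment's zero-region that compartment's
    column is removed before solving and its spectrum entry set to exactly
    zero.  Raises if the active concentration columns are numerically
    collinear, naming the offending compartments.
    """
    constraints = constraints or ConstraintSet()
    S, _, _ = _solve_spectra(
        [data], [np.asarray(C.C, float)], [list(C.labels)], constraints,
        check_conditioning=True,
    )
    return SpectrumSet(
        kind="SADS",
        wavelengths=data.wavelengths,
        spectra=S[0],
        labels=list(C.labels),
        zero_regions={
            lab: list(constraints.zero_regions[lab])
            for lab in C.labels
            if lab in constraints.zero_regions
        },
    )


# ---------------------------------------------------------------------------
# nonlinear (rates) step


def _resolve_irfs(
    schemes: list[SchemeDef], irf: IRFModel | list[IRFModel] | None, n: int
) -> list[IRFModel]:
    if irf is None:
        out = []
        for s in schemes:
            if s.irf is None:
                raise ValueError(f"scheme {s.name!r} declares no IRF and none was given")
            out.append(s.irf)
        return out
    if isinstance(irf, IRFModel):
        return [irf] * n
    return list(irf)


def fit_target(
    datasets: list[TADataset],
    schemes: list[SchemeDef],
    free: list[FreeRate],
    constraints: ConstraintSet | None = None,
    irf: IRFModel | list[IRFModel] | None = None,
    seed: int | None = None,
    n_starts: int = 4,
    perturb: float = 0.3,
    max_nfev: int | None = None,
) -> FitResult:
    """Simultaneous target fit of several datasets with shared parameters.

    One scheme per dataset (the same ``SchemeDef`` object may serve several
    spectral windows of one experiment; its concentrations are computed
    once per evaluation).  ``free`` selects the adjustable rates; all other
    rates stay at their declared values.  Spectra are eliminated by
    variable projection at every evaluation, honouring ``constraints``.

    Multi-start: start 0 uses the declared inits, further starts perturb
    them log-normally (scale ``perturb``) with the given seed.
    """
    if len(datasets) != len(schemes):
        raise ValueError("need exactly one scheme per dataset")
    constraints = constraints or ConstraintSet()
    irfs = _resolve_irfs(schemes, irf, len(datasets))
    for p in free:
        for ds, src, dst in p.edges:
            sch = schemes[ds]
            if dst in (None, GROUND):
                continue  # losses may be created on the fly
            if (src, dst) not in sch.transfers:
                raise ValueError(
                    f"free rate {p.name!r}: edge {_edge_key(src, dst)} "
                    f"not present in scheme {sch.name!r}"
                )

    work = [s.copy() for s in schemes]
    # unique scheme objects (identity on the caller's list) -> datasets
    uniq: dict[int, list[int]] = {}
    for d, s in enumerate(schemes):
        uniq.setdefault(id(s), []).append(d)
    groups = list(uniq.values())
    labels = [list(s.compartments) for s in schemes]

    def apply(theta: np.ndarray) -> None:
        for p, th in zip(free, theta):
            val = float(np.exp(th))
            for ds, src, dst in p.edges:
                work[ds].set_rate(src, None if dst == GROUND else dst, val)

    def model_concentrations() -> list[np.ndarray]:
        Cs: list[np.ndarray] = [None] * len(datasets)  # type: ignore[list-item]
        for members in groups:
            d0 = members[0]
            # datasets sharing a scheme may still have different time axes
            by_axis: dict[tuple, list[int]] = {}
            for d in members:
                key = (datasets[d].times.tobytes(), irfs[d].mu, irfs[d].sigma)
                by_axis.setdefault(key, []).append(d)
            for ds_list in by_axis.values():
                cm = concentrations(
                    work[d0].to_kinetic_scheme(), irfs[ds_list[0]], datasets[ds_list[0]].times
                )
                for d in ds_list:
                    Cs[d] = cm.C
        return Cs

    # maximum-likelihood weighting: datasets with a known noise level enter
    # the pooled objective with weight 1/sigma
    weights = [
        1.0 / d.noise_sigma if d.noise_sigma else 1.0 for d in datasets
    ]

    def residual(theta: np.ndarray) -> np.ndarray:
        apply(theta)
        Cs = model_concentrations()
        _, res, _ = _solve_spectra(datasets, Cs, labels, constraints, weights=weights)
        return np.concatenate([(w * r).ravel() for w, r in zip(weights, res)])

    theta0 = np.log([p.init for p in free]) if free else np.zeros(0)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(theta0 + rng.normal(0.0, perturb, size=theta0.size))

    best = None
    best_idx = 0
    lb = theta0 + np.log(1e-4)
    ub = theta0 + np.log(1e4)
    if free:
        for idx, th0 in enumerate(starts):
            try:
                res = least_squares(
                    residual,
                    np.clip(th0, lb, ub),
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
            raise RuntimeError("target fit failed to converge from any start")
        theta_hat = best.x
        converged = bool(best.status > 0)
        nfev = int(best.nfev)
    else:
        theta_hat = theta0
        converged = True
        nfev = 1

    # final state, spectra and diagnostics at the optimum
    apply(theta_hat)
    Cs = model_concentrations()
    S, residuals, _ = _solve_spectra(datasets, Cs, labels, constraints, weights=weights)
    cost = float(sum(np.sum(r * r) for r in residuals))
    chi2 = float(sum(np.sum((w * r) ** 2) for w, r in zip(weights, residuals)))

    rates = {p.name: float(np.exp(th)) for p, th in zip(free, theta_hat)}
    stderr: dict[str, float] = {}
    if free and best is not None:
        m = best.fun.size
        dof = max(m - len(free), 1)
        s2 = 2.0 * best.cost / dof
        JtJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JtJ) * s2
            for i, p in enumerate(free):
                stderr[p.name] = rates[p.name] * float(np.sqrt(max(cov[i, i], 0.0)))
        except np.linalg.LinAlgError:
            sing = [free[i].name for i in np.where(np.diag(JtJ) < 1e-12)[0]]
            warnings.warn(
                f"singular Jacobian: parameter(s) {sing or '(unknown)'} may be "
                "unidentifiable; standard errors unavailable"
            )

    link_id = {}
    for gi, group in enumerate(constraints.spectral_links):
        for ds, lab in group:
            link_id[(ds, lab)] = f"link{gi}"
    spectra = []
    for d in range(len(datasets)):
        spectra.append(
            SpectrumSet(
                kind="SADS",
                wavelengths=datasets[d].wavelengths,
                spectra=S[d],
                labels=labels[d],
                zero_regions={
                    lab: list(constraints.zero_regions[lab])
                    for lab in labels[d]
                    if lab in constraints.zero_regions
                },
                links={lab: link_id[(d, lab)] for lab in labels[d] if (d, lab) in link_id},
            )
        )

    return FitResult(
        rates=rates,
        stderr=stderr,
        spectra=spectra,
        residuals=residuals,
        cost=cost,
        irf=[(f.mu, f.sigma) for f in irfs],
        converged=converged,
        n_iter=nfev,
        start_index=best_idx,
        seed=seed,
        extra={"schemes": work, "chi2": chi2, "weights": weights},
    )


# ---------------------------------------------------------------------------
# branching yields


@dataclass
class BranchingResult:
    """Per-edge branch fractions and cumulative pathway yields.

    ``fractions`` maps "src -> dst" (dst may be "ground") to the fraction
    of src's decays through that edge; ``yields`` maps the same keys to the
    fraction of the *total absorbed excitation* flowing through the edge;
    ``ground_yields`` is the slice of ``yields`` for loss channels.
    """

    fractions: dict[str, float]
    yields: dict[str, float]
    ground_yields: dict[str, float]
    visits: dict[str, float]


def branching_yields(scheme: SchemeDef) -> BranchingResult:
    """Decay-pathway yields of a compartmental scheme.

    The fraction of a compartment's decays through an edge is the edge rate
    over the compartment's total rate.  Cumulative yields follow from the
    expected number of visits v = (I − B)⁻¹ j, where B holds the branching
    probabilities (this linear solve also handles cyclic schemes, where
    plain chain multiplication would not terminate).
    """
    comps = scheme.compartments
    n = len(comps)
    idx = {c: i for i, c in enumerate(comps)}
    totals = np.array([scheme.total_rate(c) for c in comps])
    reachable = _reachable(scheme)
    dead = [c for c in comps if totals[idx[c]] <= 0 and reachable[idx[c]]]
    if dead:
        raise ValueError(f"compartment(s) with zero total decay rate: {dead}")

    B = np.zeros((n, n))
    for (src, dst), rate in scheme.transfers.items():
        if totals[idx[src]] > 0:
            B[idx[dst], idx[src]] = rate / totals[idx[src]]
    j = np.zeros(n)
    for c, frac in scheme.input.items():
        j[idx[c]] = frac
    v = np.linalg.solve(np.eye(n) - B, j)

    fractions: dict[str, float] = {}
    yields: dict[str, float] = {}
    ground: dict[str, float] = {}
    for (src, dst), rate in scheme.transfers.items():
        frac = rate / totals[idx[src]] if totals[idx[src]] > 0 else 0.0
        key = _edge_key(src, dst)
        fractions[key] = frac
        yields[key] = v[idx[src]] * frac
    for c in comps:
        if totals[idx[c]] <= 0:
            continue
        loss = scheme.losses.get(c, 0.0)
        frac = loss / totals[idx[c]]
        key = _edge_key(c, None)
        fractions[key] = frac
        y = v[idx[c]] * frac
        yields[key] = y
        ground[c] = y
    return BranchingResult(
        fractions=fractions,
        yields=yields,
        ground_yields=ground,
        visits={c: float(v[idx[c]]) for c in comps},
    )


def _reachable(scheme: SchemeDef) -> np.ndarray:
    comps = scheme.compartments
    idx = {c: i for i, c in enumerate(comps)}
    reach = np.zeros(len(comps), dtype=bool)
    stack = [c for c, f in scheme.input.items() if f > 0]
    while stack:
        c = stack.pop()
        if reach[idx[c]]:
            continue
        reach[idx[c]] = True
        for (src, dst), rate in scheme.transfers.items():
            if src == c and rate > 0 and not reach[idx[dst]]:
                stack.append(dst)
    return reach
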