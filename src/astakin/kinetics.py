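"""Analytic first-order compartmental kinetics convolved with a Gaussian IRF.

The forward model for every fit in this package: populations c(t) solving

    dc/dt = K c + j * g(t; mu, sigma)

where K is the transfer-rate matrix (column = source compartment), j the
excitation input vector and g a unit-area Gaussian instrument response.
The solution is evaluated analytically through the eigendecomposition of K,
each eigenmode rendered by the closed-form exponential-Gaussian convolution
:func:`exp_conv_gauss`; near-degenerate or complex spectra fall back to a
stiff numerical integration of the driven system.

Rates are *stored* in ns^-1 (the convention of printed target models) and
converted to ps^-1 in exactly one place (:data:`RATE_SCALE`), because the
delay axes of femtosecond experiments are in ps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig, solve
from scipy.special import erfc, erfcx

__all__ = [
    "RATE_SCALE",
    "KineticScheme",
    "IRFModel",
    "ConcentrationMatrix",
    "exp_conv_gauss",
    "concentrations",
    "sequential_amplitudes",
]

#: ns^-1 -> ps^-1 conversion; applied in exactly one place.
RATE_SCALE = 1.0e-3

_SQRT2 = np.sqrt(2.0)
#: relative tolerance below which two eigenvalues count as degenerate
DEGENERACY_RTOL = 1e-9


@dataclass
class IRFModel:
    """Gaussian instrument response: center ``mu`` and width ``sigma`` in ps."""

    mu: float = 0.0
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise ValueError("IRF parameters must be finite")
        if self.sigma <= 0:
            raise ValueError("IRF sigma must be positive")

    @classmethod
    def from_fwhm_fs(cls, fwhm_fs: float, mu: float = 0.0) -> "IRFModel":
        sigma_ps = fwhm_fs * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return cls(mu=mu, sigma=sigma_ps)


@dataclass
class KineticScheme:
    """A first-order compartmental scheme.

    ``K`` is square with column-stochastic orientation: off-diagonal
    ``K[i, j] >= 0`` is the rate (ns^-1) from compartment ``j`` into ``i``;
    the diagonal ``K[j, j]`` is minus the *total* decay rate of ``j``
    including loss to the ground state, so the ground-state loss of ``j``
    is ``-K[j, j] - sum_i!=j K[i, j] >= 0``.
    """

    labels: list[str]
    K: np.ndarray
    input: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.labels)
        if self.input is None:
            self.input = np.zeros(n)
            self.input[0] = 1.0
        self.input = np.asarray(self.input, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.labels)

    def validate(self, atol: float = 1e-9) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("compartment labels must be unique")
        if self.K.shape != (n, n):
            raise ValueError(f"K must be {n}x{n}, got {self.K.shape}")
        off = self.K - np.diag(np.diag(self.K))
        if np.any(off < -atol):
            raise ValueError("off-diagonal rates must be nonnegative")
        loss = -np.diag(self.K) - off.sum(axis=0)
        if np.any(loss < -atol * max(1.0, np.abs(self.K).max())):
            bad = [self.labels[j] for j in np.where(loss < -atol)[0]]
            raise ValueError(
                f"ground-state loss negative for {bad}: each column's total "
                "decay must cover its outgoing transfer rates"
            )
        if self.input.shape != (n,):
            raise ValueError("input vector length must match labels")
        if np.any(self.input < -atol):
            raise ValueError("input fractions must be nonnegative")
        if abs(self.input.sum() - 1.0) > 1e-6:
            raise ValueError("input fractions must sum to 1")

    def ground_loss(self) -> np.ndarray:
        """Loss-to-ground rate (ns^-1) of each compartment."""
        off = self.K - np.diag(np.diag(self.K))
        return -np.diag(self.K) - off.sum(axis=0)

    def total_rates(self) -> np.ndarray:
        """Total decay rate (ns^-1) of each compartment."""
        return -np.diag(self.K)


@dataclass
class ConcentrationMatrix:
    """IRF-convolved populations: one column per compartment."""

    times: np.ndarray
    C: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (self.times.size, len(self.labels)):
            raise ValueError("C shape does not match times/labels")


def exp_conv_gauss(k: float, t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Exponential decay exp(-k t)·θ(t) convolved with a unit-area Gaussian.

    Returns ``1/2 · exp(k²σ²/2 − k(t−μ)) · erfc((μ + kσ² − t)/(σ√2))``,
    evaluated in an overflow-safe form: where the erfc argument is positive
    the scaled complementary error function is used, which keeps large
    ``k·σ`` products finite.

    Parameters are ``k`` in 1/ps, ``t``, ``mu``, ``sigma`` in ps; the result
    is dimensionless (population of a compartment excited by a unit pulse).
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if not (np.isfinite(k) and np.isfinite(mu) and np.isfinite(sigma)):
        raise ValueError("exp_conv_gauss: non-finite parameter")
    if not np.all(np.isfinite(t)):
        raise ValueError("exp_conv_gauss: non-finite time value")
    if sigma <= 0:
        raise ValueError("exp_conv_gauss: sigma must be positive")
    if k < 0:
        raise ValueError("exp_conv_gauss: rate must be nonnegative")

    x = (mu + k * sigma * sigma - t) / (sigma * _SQRT2)
    out = np.empty_like(x)
    pos = x >= 0
    # erfc(x) = erfcx(x) exp(-x²) and the exponents combine exactly to the
    # Gaussian tail -(t-μ)²/(2σ²), so this branch can never overflow.
    z = (t[pos] - mu) / sigma
    out[pos] = 0.5 * erfcx(x[pos]) * np.exp(-0.5 * z * z)
    # for x < 0 we have t-μ > kσ², hence the plain exponent is negative.
    neg = ~pos
    out[neg] = 0.5 * np.exp(k * k * sigma * sigma / 2.0 - k * (t[neg] - mu)) * erfc(x[neg])
    return out[0] if scalar else out


def _gaussian_pulse(t: np.ndarray | float, mu: float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def _ode_concentrations(
    K_ps: np.ndarray, j: np.ndarray, irf: IRFModel, times: np.ndarray
) -> np.ndarray:
    """Stiff numerical integration of the IRF-driven system (fallback path)."""
    t0 = min(times[0], irf.mu - 8.0 * irf.sigma) - 1e-6
    t_pulse = irf.mu + 8.0 * irf.sigma  # source is negligible beyond here

    def rhs(t, c):
        return K_ps @ c + j * _gaussian_pulse(t, irf.mu, irf.sigma)

    out = np.empty((times.size, j.size))
    cut = np.searchsorted(times, t_pulse, side="right")
    b1 = min(t_pulse, times[-1])

    # phase 1: through the pulse, with steps small enough to resolve it
    te = times[:cut]
    t_eval1 = te if te.size and te[-1] >= b1 else np.append(te, b1)
    sol = solve_ivp(
        rhs,
        (t0, b1),
        np.zeros(j.size),
        t_eval=t_eval1,
        method="Radau",
        jac=lambda t, c: K_ps,
        rtol=1e-9,
        atol=1e-12,
        max_step=irf.sigma / 4.0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE fallback failed: {sol.message}")
    out[:cut] = sol.y.T[: te.size]
    c0 = sol.y[:, -1]

    # phase 2: free relaxation after the pulse
    if cut < times.size:
        sol = solve_ivp(
            rhs,
            (b1, times[-1]),
            c0,
            t_eval=times[cut:],
            method="Radau",
            jac=lambda t, c: K_ps,
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE fallback failed: {sol.message}")
        out[cut:] = sol.y.T
    return out


def concentrations(
    scheme: KineticScheme, irf: IRFModel, times: np.ndarray
) -> ConcentrationMatrix:
    """IRF-convolved populations of every compartment of ``scheme``.

    Solves dc/dt = K·c driven by the Gaussian pulse analytically via the
    eigendecomposition of K (rates converted ns^-1 → ps^-1), with each
    eigenmode rendered by :func:`exp_conv_gauss`.  If the spectrum of K is
    degenerate within a relative tolerance of 1e-9, or not real, the
    closed form is singular and a stiff ODE integration is used instead.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    scheme.validate()

    K_ps = scheme.K * RATE_SCALE
    j = scheme.input

    w, V = eig(K_ps)
    scale = max(np.abs(w).max(), 1e-30)
    degenerate = False
    if np.abs(w.imag).max() > 1e-12 * scale:
        degenerate = True  # complex pair: treat via numerical path
    else:
        w = w.real
        V = V.real
        ws = np.sort(w)
        if ws.size > 1:
            pair_scale = np.maximum(np.abs(ws[:-1]), np.abs(ws[1:]))
            if np.any(np.diff(ws) <= DEGENERACY_RTOL * np.maximum(pair_scale, 1e-30)):
                degenerate = True

    if degenerate:
        C = _ode_concentrations(K_ps, j, irf, times)
        return ConcentrationMatrix(times=times, C=C, labels=list(scheme.labels))

    try:
        a = solve(V, j)
    except np.linalg.LinAlgError:
        C = _ode_concentrations(K_ps, j, irf, times)
        return ConcentrationMatrix(times=times, C=C, labels=list(scheme.labels))

    C = np.zeros((times.size, scheme.n))
    for lam, v, amp in zip(w, V.T, a):
        if amp == 0.0:
            continue
        g = exp_conv_gauss(max(-lam, 0.0), times, irf.mu, irf.sigma)
        C += np.outer(g, amp * v)
    return ConcentrationMatrix(times=times, C=C, labels=list(scheme.labels))


def sequential_amplitudes(rates: np.ndarray) -> np.ndarray:
    """Amplitude matrix of an irreversible sequential chain.

    For a chain 1 → 2 → … → n with distinct total decay rates ``k_l``
    (any consistent unit), the population of compartment ``l`` is

        c_l(t) = Σ_{j<=l} b[j, l] · g(k_j, t)

    with ``g`` the IRF-convolved exponential and

        b[j, l] = Π_{m=1}^{l-1} k_m / Π_{m=1, m≠j}^{l} (k_m − k_j).

    The returned matrix is upper-triangular in (j, l) with ``b[0, 0] = 1``.
    This closed form is singular at equal rates; near-degenerate chains
    must use the general :func:`concentrations` path.
    """
    k = np.asarray(rates, dtype=float)
    if k.ndim != 1 or k.size == 0:
        raise ValueError("rates must be a nonempty 1-D sequence")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    n = k.size
    for i in range(n):
        for j in range(i + 1, n):
            if abs(k[i] - k[j]) <= 1e-9 * max(abs(k[i]), abs(k[j])):
                raise ValueError(
                    "near-degenerate sequential rates: use the general "
                    "concentrations() path for (quasi-)equal lifetimes"
                )
    b = np.zeros((n, n))
    for l in range(n):
        forward = np.prod(k[:l])  # Π_{m<l} k_m ; empty product = 1
        for j in range(l + 1):
            denom = 1.0
            for m in range(l + 1):
                if m != j:
                    denom *= k[m] - k[j]
            b[j, l] = forward / denom
    return b


def sequential_scheme(rates_ns: np.ndarray, labels: list[str] | None = None) -> KineticScheme:
    """Unidirectional chain scheme from total decay rates in ns^-1.

    Compartment ``l`` decays entirely into ``l+1``; the last compartment
    decays to the ground state.  This is the kinetic model underlying
    global analysis (EADS).
    """
    rates_ns = np.asarray(rates_ns, dtype=float)
    n = rates_ns.size
    if labels is None:
        labels = [f"comp{i + 1}" for i in range(n)]
    K = np.diag(-rates_ns)
    for l in range(n - 1):
        K[l + 1, l] = rates_ns[l]
    inp = np.zeros(n)
    inp[0] = 1.0
    return KineticScheme(labels=labels, K=K, input=inp)
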