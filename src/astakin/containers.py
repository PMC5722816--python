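"""Shared data containers for transient-absorption analysis.

Conventions used throughout the package:

* time axes are in picoseconds (ps), wavelength axes in nanometres (nm),
  difference absorption in milli-OD (mOD);
* first-order rate constants are stored in ns^-1 (the usual convention for
  printed target models) and converted to ps^-1 only inside the kinetic
  forward model;
* a ``SpectrumSet`` holds one difference spectrum per kinetic component,
  whether those components are sequential (EADS), parallel (DADS) or
  physical compartments (SADS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TADataset",
    "SpectrumSet",
    "FitResult",
]


@dataclass
class TADataset:
    """A pump-probe difference-absorption matrix with its axes.

    Parameters
    ----------
    times : array of shape (n_t,)
        Pump-probe delays in ps, strictly increasing.
    wavelengths : array of shape (n_wl,)
        Detection wavelengths in nm, strictly increasing.
    dA : array of shape (n_t, n_wl)
        Difference absorption in mOD.
    excitation : float
        Pump wavelength in nm.
    window : tuple (min, max)
        Nominal spectral window of the detection channel in nm.
    noise_sigma : float or None
        Known or estimated additive noise level (mOD).
    truth : dict or None
        Ground-truth generating parameters when the dataset is synthetic.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    dA: np.ndarray
    excitation: float | None = None
    window: tuple[float, float] | None = None
    noise_sigma: float | None = None
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.dA.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"dA shape {self.dA.shape} does not match axes "
                f"({self.times.size}, {self.wavelengths.size})"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dA.shape


@dataclass
class SpectrumSet:
    """A set of component-associated difference spectra (EADS/DADS/SADS)."""

    kind: str  # "EADS" | "DADS" | "SADS"
    wavelengths: np.ndarray
    spectra: np.ndarray  # (n_components, n_wl)
    labels: list[str]
    zero_regions: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    links: dict[str, str] = field(default_factory=dict)  # label -> link id

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.kind not in ("EADS", "DADS", "SADS"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.spectra.shape != (len(self.labels), self.wavelengths.size):
            raise ValueError("spectra shape does not match labels/wavelength axis")

    def spectrum(self, label: str) -> np.ndarray:
        return self.spectra[self.labels.index(label)]


@dataclass
class FitResult:
    """Outcome of a global or target fit.

    ``rates`` are in ns^-1; for sequential (global) fits ``lifetimes``
    additionally reports 1000/rate in ps.  ``cost`` is the plain sum of
    squared residuals over all fitted datasets.
    """

    rates: dict[str, float]
    stderr: dict[str, float]
    spectra: list[SpectrumSet]
    residuals: list[np.ndarray]
    cost: float
    irf: list[tuple[float, float]]  # (mu, sigma) per dataset, ps
    converged: bool
    n_iter: int
    start_index: int
    seed: int | None
    lifetimes: np.ndarray | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def rss(self) -> float:
        return self.cost
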