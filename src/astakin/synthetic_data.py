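"""Synthetic pump–probe datasets with the structure of the real experiment.

The generator emulates the instrument that motivated this package: a
femtosecond pump–probe setup recording ΔA(t, λ) on a 76-channel photodiode
array, two spectral windows of ≈130 nm (Soret/carotenoid region 480–610 nm
and Chl Q_X/Q_Y region 590–720 nm), delays from before time zero out to
3.5 ns, a ≈120-fs-FWHM Gaussian IRF and additive white Gaussian noise.

Synthetic species spectra are stylised sums of Gaussian bands — negative
for ground-state bleach, positive for excited-state absorption — loosely
shaped after the carotenoid/chlorophyll difference spectra of the system
(Car bleach near 500 nm, dark-state ESA near 595/630 nm, Chl Q_Y bleach
near 680 nm).  They exist to give the kinetic components distinguishable,
linearly independent spectral signatures; no physical meaning attaches to
their amplitudes.

Every dataset records its generating parameters in ``truth`` so recovery
experiments have an unambiguous ground truth, and identical seeds yield
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TADataset
from .kinetics import IRFModel, KineticScheme, concentrations, sequential_scheme
from .schemes import SchemeDef, load_scheme

__all__ = [
    "BandShape",
    "default_time_grid",
    "window_axis",
    "generate_dataset",
    "generate_paper_like",
    "SEQUENTIAL_LIFETIMES_PS",
    "WINDOWS",
]

#: spectral windows of the two detection channels (nm)
WINDOWS = {"blue": (480.0, 610.0), "red": (590.0, 720.0)}
N_CHANNELS = 76
MAX_DELAY_PS = 3500.0

#: lifetimes (ps) of the sequential, global-analysis view of each
#: excitation: the printed ps-range constants (170 fs, 2.7/7.8 ps at
#: 508 nm; 2.2 ps at 690 nm) padded with an ultrafast initial state and
#: slower quenched/long-lived tails.
SEQUENTIAL_LIFETIMES_PS = {
    508: np.array([0.05, 0.17, 2.7, 7.8, 250.0, 2000.0]),
    690: np.array([2.2, 30.0, 250.0, 2500.0]),
}

DEFAULT_IRF_FWHM_FS = 120.0
DEFAULT_NOISE_FRACTION = 0.02  # of peak |ΔA|


@dataclass
class BandShape:
    """Stylised difference spectrum: a sum of signed Gaussian bands.

    Each band is (center nm, width nm, amplitude mOD); negative amplitude
    models ground-state bleach, positive excited-state absorption.
    ``zero_regions`` force the evaluated spectrum to exactly zero inside
    the listed intervals (used for triplet spectra carrying a hard
    spectral assumption).
    """

    bands: list[tuple[float, float, float]]
    zero_regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError("band width must be positive")

    def __call__(self, wl: np.ndarray) -> np.ndarray:
        wl = np.asarray(wl, dtype=float)
        out = np.zeros_like(wl)
        for c, w, a in self.bands:
            out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        for lo, hi in self.zero_regions:
            out[(wl >= lo) & (wl <= hi)] = 0.0
        return out


def default_time_grid(
    n_linear: int = 50,
    linear_span: tuple[float, float] = (-0.5, 2.0),
    n_log: int = 70,
    max_delay: float = MAX_DELAY_PS,
) -> np.ndarray:
    """Delay axis mimicking a delay-line scan: dense linear steps through
    time zero, then log-spaced points out to 3.5 ns."""
    lin = np.linspace(*linear_span, n_linear)
    log = np.geomspace(linear_span[1], max_delay, n_log + 1)[1:]
    return np.concatenate([lin, log])


def window_axis(window: str | tuple[float, float], n_channels: int = N_CHANNELS) -> np.ndarray:
    """Wavelength axis of one detection window (76 equally spaced channels)."""
    if isinstance(window, str):
        window = WINDOWS[window]
    return np.linspace(window[0], window[1], n_channels)


def generate_dataset(
    scheme: KineticScheme,
    shapes: dict[str, BandShape],
    irf: IRFModel,
    times: np.ndarray,
    wavelengths: np.ndarray,
    noise_sigma: float,
    seed: int,
    excitation: float | None = None,
    window: tuple[float, float] | None = None,
    truth: dict | None = None,
) -> TADataset:
    """ΔA = C(scheme, irf)·Sᵀ(shapes) + N(0, noise_sigma), seeded.

    ``shapes`` must provide one :class:`BandShape` per scheme compartment.
    """
    missing = [lab for lab in scheme.labels if lab not in shapes]
    if missing:
        raise ValueError(f"no band shape for compartment(s): {missing}")
    times = np.asarray(times, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    C = concentrations(scheme, irf, times).C
    S = np.vstack([shapes[lab](wavelengths) for lab in scheme.labels])
    dA = C @ S
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        dA = dA + rng.normal(0.0, noise_sigma, size=dA.shape)
    record = {
        "labels": list(scheme.labels),
        "K_ns": scheme.K.tolist(),
        "input": scheme.input.tolist(),
        "irf_mu_ps": irf.mu,
        "irf_sigma_ps": irf.sigma,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "spectra": S.tolist(),
    }
    if truth:
        record.update(truth)
    return TADataset(
        times=times,
        wavelengths=wavelengths,
        dA=dA,
        excitation=excitation,
        window=(float(wavelengths[0]), float(wavelengths[-1])) if window is None else window,
        noise_sigma=noise_sigma,
        truth=record,
    )


# ---------------------------------------------------------------------------
# stylised species spectra for the shipped target models

_TARGET_SHAPES: dict[str, BandShape] = {
    # carotenoid singlet manifold: shared ~500 nm bleach, state-specific ESA
    "S2": BandShape([(500, 22, -8.0), (560, 30, 5.0)]),
    "hotS1": BandShape([(500, 22, -6.0), (660, 55, 7.0)]),
    "S1": BandShape([(500, 22, -6.0), (595, 16, 6.0), (630, 16, 5.0)]),
    "Sstar": BandShape([(500, 22, -5.0), (565, 18, 4.0), (595, 18, 6.5)]),
    "Sq": BandShape([(500, 25, -2.0), (590, 45, 5.0)]),
    # the equilibrated Chl pool of the Car-excitation model carries the same
    # stylised spectrum as the terminal Chl pool of the Chl-excitation model,
    # which is what lets the target fit link them across experiments
    "Chl": BandShape([(672, 10, -8.0), (550, 90, 1.0)]),
    # unconnected astaxanthin: same chromophore, same difference spectra
    # (the matching SADS link is a standard assumption in the target fit)
    "uS2": BandShape([(500, 22, -8.0), (560, 30, 5.0)]),
    "uS1": BandShape([(500, 22, -6.0), (595, 16, 6.0), (630, 16, 5.0)]),
    # chlorophyll pools at 690 nm excitation: Q_Y bleach walking blue
    "Chl_a1": BandShape([(686, 10, -10.0), (550, 90, 0.8)]),
    "Chl_a2": BandShape([(678, 10, -9.0), (550, 90, 0.9)]),
    "Chl_a3": BandShape([(672, 10, -8.0), (550, 90, 1.0)]),
    # triplets with their hard spectral assumptions
    "ChlT": BandShape([(510, 30, 2.5)], zero_regions=[(630.0, 1e4)]),
    "CarT": BandShape([(650, 22, 4.0)], zero_regions=[(0.0, 630.0)]),
}

# sequential (global-analysis) component spectra per excitation, ordered
# along the chain: EADS-style stand-ins
_SEQ_SHAPES = {
    508: [
        _TARGET_SHAPES["S2"],
        _TARGET_SHAPES["hotS1"],
        _TARGET_SHAPES["S1"],
        _TARGET_SHAPES["Sstar"],
        BandShape([(680, 11, -8.0), (590, 45, 2.0)]),  # quenched Chl + Sq ESA
        BandShape([(680, 11, -1.5), (650, 22, 0.8)]),  # long-lived tail
    ],
    690: [
        _TARGET_SHAPES["Chl_a1"],
        _TARGET_SHAPES["Chl_a2"],
        BandShape([(674, 10, -8.0), (590, 45, 1.5)]),  # quenched pool + Sq
        BandShape([(676, 11, -1.2), (650, 22, 0.6)]),  # long-lived tail
    ],
}


def _peak_noise(scheme: KineticScheme, shapes, irf, times, wl, fraction) -> float:
    C = concentrations(scheme, irf, times).C
    S = np.vstack([shapes[lab](wl) for lab in scheme.labels])
    return fraction * float(np.abs(C @ S).max())


def generate_paper_like(
    excitation: int,
    seed: int,
    kind: str = "target",
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    irf: IRFModel | None = None,
) -> tuple[TADataset, TADataset]:
    """A two-window synthetic experiment for one excitation wavelength.

    Parameters
    ----------
    excitation : {508, 690}
        Pump wavelength: 508 nm excites the carotenoid, 690 nm the red
        edge of the Chl Q_Y band.
    kind : {"target", "sequential"}
        ``target`` generates from the shipped compartmental scheme for the
        excitation; ``sequential`` generates from the unbranched chain
        with the excitation's global-analysis lifetimes
        (:data:`SEQUENTIAL_LIFETIMES_PS`).
    noise_fraction : float
        Noise σ as a fraction of the peak |ΔA| (homoscedastic, white).

    Returns
    -------
    (blue, red) : pair of TADataset
        The 480–610 nm and 590–720 nm windows, 76 channels each, sharing
        the kinetics but with independent noise (seeded from ``seed``).
    """
    if excitation not in (508, 690):
        raise ValueError("excitation must be 508 or 690 (nm)")
    if kind not in ("target", "sequential"):
        raise ValueError("kind must be 'target' or 'sequential'")
    times = default_time_grid()
    if kind == "target":
        scheme_def = load_scheme("fig3b_508" if excitation == 508 else "fig3d_690")
        kscheme = scheme_def.to_kinetic_scheme()
        shapes = {lab: _TARGET_SHAPES[lab] for lab in kscheme.labels}
        truth = {"scheme": scheme_def.name, "kind": kind}
    else:
        taus = SEQUENTIAL_LIFETIMES_PS[excitation]
        kscheme = sequential_scheme(1000.0 / taus)
        shapes = dict(zip(kscheme.labels, _SEQ_SHAPES[excitation]))
        truth = {"lifetimes_ps": taus.tolist(), "kind": kind}
    if irf is None:
        irf = (
            scheme_def.irf
            if kind == "target" and scheme_def.irf is not None
            else IRFModel.from_fwhm_fs(DEFAULT_IRF_FWHM_FS)
        )

    out = []
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s) for s in ss.generate_state(2)]
    for name, sub in zip(("blue", "red"), subseeds):
        wl = window_axis(name)
        sigma = _peak_noise(kscheme, shapes, irf, times, wl, noise_fraction)
        out.append(
            generate_dataset(
                kscheme,
                shapes,
                irf,
                times,
                wl,
                noise_sigma=sigma,
                seed=sub % (2**31),
                excitation=float(excitation),
                window=WINDOWS[name],
                truth=dict(truth),
            )
        )
    return out[0], out[1]
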