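"""Readers/writers for the delimited TA-matrix dialect and run manifests.

The package uses a single plain-text matrix dialect: the first row is the
wavelength axis (nm) with an empty leading cell, each following row starts
with the delay (ps) followed by ΔA (mOD) per channel.  Delimiters tab,
comma and semicolon are auto-detected.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SpectrumSet, TADataset

__all__ = [
    "RunConfig",
    "read_ta_matrix",
    "write_ta_matrix",
    "write_spectra",
    "write_manifest",
    "ParseError",
]

_DELIMITERS = ("\t", ",", ";")


class ParseError(ValueError):
    """A TA-matrix file that cannot be parsed; message carries the line."""


@dataclass
class RunConfig:
    """Declarative description of one fitting run.

    Collects everything needed to reproduce a run: input paths, scheme
    references, link declarations, optimizer settings, the seed and the
    output directory.  Unknown keys are rejected on load so that typos in
    config files fail loudly instead of being ignored.
    """

    data: list[str] = field(default_factory=list)
    schemes: list[str] = field(default_factory=list)
    links: str | None = None
    seed: int = 0
    starts: int = 4
    max_iterations: int | None = None
    out: str = "out"
    log_level: str = "info"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def _detect_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[best] == 0:
        raise ParseError("could not detect delimiter (expected tab, comma or semicolon)")
    return best


def read_ta_matrix(path) -> TADataset:
    """Read a ΔA(t, λ) matrix: row 1 wavelengths, column 1 delays.

    Non-monotonic axes are sorted with a warning; ragged rows, non-numeric
    cells and duplicate axis values raise :class:`ParseError` with the
    offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    delim = _detect_delimiter(lines[0])

    header = lines[0].split(delim)
    try:
        wl = np.array([float(x) for x in header[1:]])
    except ValueError as e:
        raise ParseError(f"{path}:1: non-numeric wavelength cell ({e})") from None

    times = []
    rows = []
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = line.split(delim)
        if len(cells) != wl.size + 1:
            raise ParseError(
                f"{path}:{ln_no}: ragged row ({len(cells)} cells, expected {wl.size + 1})"
            )
        try:
            values = [float(x) for x in cells]
        except ValueError as e:
            raise ParseError(f"{path}:{ln_no}: non-numeric cell ({e})") from None
        times.append(values[0])
        rows.append(values[1:])
    times = np.array(times)
    dA = np.array(rows)

    for name, axis in (("wavelength", wl), ("time", times)):
        if np.unique(axis).size != axis.size:
            raise ParseError(f"{path}: duplicate {name} axis values")
    if np.any(np.diff(times) <= 0):
        warnings.warn(f"{path}: time axis not sorted; sorting rows")
        order = np.argsort(times)
        times, dA = times[order], dA[order]
    if np.any(np.diff(wl) <= 0):
        warnings.warn(f"{path}: wavelength axis not sorted; sorting columns")
        order = np.argsort(wl)
        wl, dA = wl[order], dA[:, order]
    return TADataset(times=times, wavelengths=wl, dA=dA)


def write_ta_matrix(path, dataset: TADataset, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join([""] + [repr(float(w)) for w in dataset.wavelengths]) + "\n")
        for t, row in zip(dataset.times, dataset.dA):
            fh.write(
                delimiter.join([repr(float(t))] + [repr(float(v)) for v in row]) + "\n"
            )


def write_spectra(path, spectra: SpectrumSet, delimiter: str = "\t") -> None:
    """One column per component, first column the wavelength axis."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["wavelength_nm"] + list(spectra.labels)) + "\n")
        for i, w in enumerate(spectra.wavelengths):
            fh.write(
                delimiter.join([repr(float(w))] + [repr(float(v)) for v in spectra.spectra[:, i]])
                + "\n"
            )


def write_manifest(out_dir, seed: int | None, config: dict) -> Path:
    """Reproducibility manifest: versions, seed, and a config hash."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "astakin_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
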