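"""Declarative kinetic schemes, the shipped target models and stoichiometry.

A :class:`SchemeDef` is the human-editable form of a compartmental model:
compartments, transfer edges ("from -> to" in ns^-1), loss-to-ground rates,
the excitation input vector and an optional per-scheme IRF.  It compiles to
the matrix-level :class:`~astakin.kinetics.KineticScheme` used by the
forward model.

Two models ship with the package, named after the excitation wavelength
they describe:

``fig3b_508``
    Carotenoid excitation.  The astaxanthin S2 state branches into a hot-S1
    channel (relaxing to S1) and an S* channel; S2, hot S1 and S1 transfer
    to the chlorophyll pool at 7000, 3000 and 366 ns^-1; the Chl pool is
    quenched by the dark state S_q.  A parallel branch models astaxanthin
    molecules unconnected to the Chls.  Dark-state ground losses are
    183 (S1), 133 (S*) and 84 (S_q) ns^-1.

``fig3d_690``
    Chlorophyll excitation.  Three Chl a pools equilibrate uphill and are
    each quenched into the shared S_q compartment at rates between 1.59 and
    5.07 ns^-1; minor triplet channels (Chl T -> Car T) complete the model.

Every edge carries a provenance note: ``printed`` if its value is a
published rate constant, ``free`` if it is an unpublished parameter that a
fit should treat as adjustable.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .kinetics import IRFModel, KineticScheme

__all__ = [
    "SchemeDef",
    "PaperScheme",
    "GROUND",
    "load_scheme",
    "available_schemes",
    "unconnected_carotenoids",
]

#: pseudo-label for the ground state in edge keys
GROUND = "ground"


def _edge_key(src: str, dst: str | None) -> str:
    return f"{src} -> {dst if dst is not None else GROUND}"


@dataclass
class SchemeDef:
    """Declarative compartmental scheme (rates in ns^-1)."""

    name: str
    compartments: list[str]
    transfers: dict[tuple[str, str], float] = field(default_factory=dict)
    losses: dict[str, float] = field(default_factory=dict)
    input: dict[str, float] = field(default_factory=dict)
    irf: IRFModel | None = None
    provenance: dict[str, str] = field(default_factory=dict)
    description: str = ""

    # -- construction / validation ------------------------------------
    def __post_init__(self) -> None:
        for (src, dst) in self.transfers:
            for lab in (src, dst):
                if lab not in self.compartments:
                    raise ValueError(f"transfer references unknown compartment {lab!r}")
        for lab in list(self.losses) + list(self.input):
            if lab not in self.compartments:
                raise ValueError(f"unknown compartment {lab!r}")

    def copy(self) -> "SchemeDef":
        return copy.deepcopy(self)

    # -- rate access ---------------------------------------------------
    def get_rate(self, src: str, dst: str | None) -> float:
        if dst is None or dst == GROUND:
            return self.losses.get(src, 0.0)
        return self.transfers[(src, dst)]

    def set_rate(self, src: str, dst: str | None, value: float) -> None:
        if value < 0:
            raise ValueError("rates must be nonnegative")
        if dst is None or dst == GROUND:
            self.losses[src] = value
        else:
            if (src, dst) not in self.transfers:
                raise KeyError(f"no edge {_edge_key(src, dst)} in scheme {self.name}")
            self.transfers[(src, dst)] = value

    def total_rate(self, comp: str) -> float:
        out = self.losses.get(comp, 0.0)
        out += sum(v for (s, _), v in self.transfers.items() if s == comp)
        return out

    # -- compilation ---------------------------------------------------
    def to_kinetic_scheme(self) -> KineticScheme:
        n = len(self.compartments)
        idx = {c: i for i, c in enumerate(self.compartments)}
        K = np.zeros((n, n))
        for (src, dst), rate in self.transfers.items():
            K[idx[dst], idx[src]] += rate
        for comp in self.compartments:
            K[idx[comp], idx[comp]] = -self.total_rate(comp)
        j = np.zeros(n)
        for comp, frac in self.input.items():
            j[idx[comp]] = frac
        return KineticScheme(labels=list(self.compartments), K=K, input=j)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "compartments": list(self.compartments),
            "transfers": {f"{s} -> {t}": float(v) for (s, t), v in self.transfers.items()},
            "losses": {c: float(v) for c, v in self.losses.items()},
            "input": {c: float(v) for c, v in self.input.items()},
        }
        if self.description:
            d["description"] = self.description
        if self.irf is not None:
            d["irf"] = {"center_ps": float(self.irf.mu), "sigma_ps": float(self.irf.sigma)}
        if self.provenance:
            d["provenance"] = dict(self.provenance)
        return d

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump(self.to_dict(), buf, sort_keys=False)
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_dict(cls, d: dict) -> "SchemeDef":
        transfers = {}
        for key, v in (d.get("transfers") or {}).items():
            parts = [p.strip() for p in key.split("->")]
            if len(parts) != 2:
                raise ValueError(f"bad transfer key {key!r}: expected 'from -> to'")
            transfers[(parts[0], parts[1])] = float(v)
        irf = None
        if "irf" in d and d["irf"] is not None:
            entry = d["irf"]
            if "sigma_ps" in entry:
                irf = IRFModel(mu=float(entry.get("center_ps", 0.0)), sigma=float(entry["sigma_ps"]))
            else:
                irf = IRFModel.from_fwhm_fs(float(entry["fwhm_fs"]), mu=float(entry.get("center_ps", 0.0)))
        return cls(
            name=d["name"],
            compartments=list(d["compartments"]),
            transfers=transfers,
            losses={c: float(v) for c, v in (d.get("losses") or {}).items()},
            input={c: float(v) for c, v in (d.get("input") or {}).items()},
            irf=irf,
            provenance=dict(d.get("provenance") or {}),
            description=d.get("description", ""),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SchemeDef":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "SchemeDef":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


#: alias for a shipped, provenance-annotated scheme
PaperScheme = SchemeDef

_DATA_PACKAGE = "astakin.schemes_data"


def available_schemes() -> list[str]:
    names = []
    for entry in resources.files(_DATA_PACKAGE).iterdir():
        if entry.name.endswith(".yaml"):
            names.append(entry.name[: -len(".yaml")])
    return sorted(names)


def load_scheme(name: str) -> SchemeDef:
    """Load a shipped target model by name (``fig3b_508`` or ``fig3d_690``)."""
    ref = resources.files(_DATA_PACKAGE) / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(
            f"unknown scheme {name!r}; available: {', '.join(available_schemes())}"
        )
    scheme = SchemeDef.from_yaml(ref.read_text())
    scheme.to_kinetic_scheme()  # validation
    return scheme


def unconnected_carotenoids(
    chl_per_monomer: float, chl_car_ratio: float, n_binding_sites: int
) -> int:
    """Number of carotenoids per monomer beyond the protein's binding sites.

    The total carotenoid count is the chlorophyll count divided by the
    measured Chl/Car ratio, rounded to the nearest integer (stoichiometries
    are per-complex averages); subtracting the number of carotenoid binding
    sites gives the pool that cannot be pigment-connected to the complex.
    """
    if chl_per_monomer <= 0 or n_binding_sites <= 0:
        raise ValueError("counts must be positive")
    if chl_car_ratio <= 0:
        raise ValueError("Chl/Car ratio must be positive")
    total_cars = int(round(chl_per_monomer / chl_car_ratio))
    return max(total_cars - int(n_binding_sites), 0)
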