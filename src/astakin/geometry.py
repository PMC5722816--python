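"""Carotenoid end-ring dihedral angles over coordinate ensembles.

For cyclic carotenoids the torsion between the conjugated end ring and the
polyene chain modulates the energy, spectrum and lifetime of the low-lying
dark states, so the distribution of this ring–chain dihedral over a
structural ensemble is a direct readout of the conformational freedom of
the pigment in its binding site.  This module computes signed IUPAC
torsions (cis = 0°, range (−180°, 180°]) from four atom selectors, over
multi-MODEL PDB ensembles, and summarises them with wrap-aware circular
statistics.

Which four atoms define the ring–chain dihedral of a given carotenoid is a
chemical choice, not something the code can infer; the selectors live in a
user-editable mapping (see :class:`DihedralSpec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circvar

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomSelector",
    "DihedralSpec",
    "AngleDistribution",
    "dihedral",
    "wrap_angle",
    "angle_distribution",
    "read_frames",
    "select_coordinates",
]


@dataclass(frozen=True)
class AtomSelector:
    """One atom: chain id, residue id and atom name."""

    chain: str
    res_id: int
    atom: str


@dataclass
class DihedralSpec:
    """Four atom selectors defining a ring–chain torsion.

    ``side`` labels the membrane side of the ring (stromal | lumenal),
    ``site`` the carotenoid binding site (L1 | L2 | N1).
    """

    atoms: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]
    side: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("a dihedral needs exactly four atoms")
        if len(set(self.atoms)) != 4:
            raise ValueError("the four atoms must be distinct")

    @classmethod
    def from_dict(cls, d: dict) -> "DihedralSpec":
        atoms = tuple(
            AtomSelector(a["chain"], int(a["res_id"]), a["atom"]) for a in d["atoms"]
        )
        return cls(atoms=atoms, side=d.get("side", ""), site=d.get("site", ""))


@dataclass
class AngleDistribution:
    """Wrapped per-frame angles with histogram and circular summaries."""

    angles: np.ndarray  # degrees, in (-180, 180]
    bin_edges: np.ndarray
    counts: np.ndarray
    circular_mean: float  # degrees
    circular_variance: float  # in [0, 1]
    side: str = ""
    site: str = ""

    @property
    def n_frames(self) -> int:
        return self.angles.size


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    # exact −180 maps to +180 so the interval is half-open on the left
    w = np.where(w == -180.0, 180.0, w)
    return w


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Computed with the atan2 formulation, which is numerically stable near
    ±90°: cis (syn-periplanar) arrangements give 0°, trans (anti) ±180°;
    the result lies in (−180°, 180°].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.allclose(a, b):
            raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 * np.linalg.norm(b1) * np.linalg.norm(b2):
        raise ValueError("first three points are collinear")
    if np.linalg.norm(n2) < 1e-12 * np.linalg.norm(b2) * np.linalg.norm(b3):
        raise ValueError("last three points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    # sign follows the standard convention (positive = clockwise rotation
    # of the far bond viewed from atom 1), matching biotite's dihedral
    m1 = np.cross(b2u, n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return float(wrap_angle(ang))


def read_frames(path) -> struc.AtomArrayStack:
    """Read a (possibly multi-MODEL) PDB file as a coordinate ensemble."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    return stack


def select_coordinates(stack: struc.AtomArrayStack, spec: DihedralSpec) -> np.ndarray:
    """Coordinates of the spec's four atoms, shape (n_frames, 4, 3)."""
    coords = []
    for sel in spec.atoms:
        mask = (
            (stack.chain_id == sel.chain)
            & (stack.res_id == sel.res_id)
            & (stack.atom_name == sel.atom)
        )
        idx = np.where(mask)[0]
        if idx.size == 0:
            raise ValueError(f"atom not found: {sel}")
        if idx.size > 1:
            raise ValueError(f"ambiguous atom selector: {sel}")
        coords.append(stack.coord[:, idx[0], :])
    return np.stack(coords, axis=1)


def angle_distribution(
    frames,
    spec: DihedralSpec | None = None,
    bin_width: float = 5.0,
    discard: int = 0,
) -> AngleDistribution:
    """Dihedral distribution over a coordinate ensemble.

    ``frames`` is either an (n_frames, 4, 3) coordinate array or a biotite
    ``AtomArrayStack`` (then ``spec`` selects the four atoms).  ``discard``
    drops that many leading frames (e.g. un-equilibrated trajectory heads)
    before analysis.  The histogram is binned on (−180, 180] with the
    given bin width; mean and variance are circular, so mass near −180°
    and +180° is treated as adjacent.
    """
    if bin_width <= 0 or 360.0 % bin_width > 1e-9 and abs(360.0 % bin_width - bin_width) > 1e-9:
        raise ValueError("bin width must be positive and divide 360")
    if spec is not None and not isinstance(frames, np.ndarray):
        frames = select_coordinates(frames, spec)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != (4, 3):
        raise ValueError("frames must have shape (n_frames, 4, 3)")
    frames = frames[discard:]
    if frames.shape[0] == 0:
        raise ValueError("no frames left after discarding the leading ones")

    angles = wrap_angle(np.array([dihedral(*f) for f in frames]))
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    cm = float(circmean(angles, high=180.0, low=-180.0))
    cv = float(circvar(angles, high=180.0, low=-180.0))
    return AngleDistribution(
        angles=angles,
        bin_edges=edges,
        counts=counts,
        circular_mean=wrap_angle(cm),
        circular_variance=cv,
        side=spec.side if spec is not None else "",
        site=spec.site if spec is not None else "",
    )
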