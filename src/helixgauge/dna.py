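"""Canonical B-form duplex generation and groove geometry.

The generator is a minimal-atom fiber model: each nucleotide contributes a
backbone phosphorus, the sugar C1' and the glycosidic nitrogen, placed on
helical tracks (constant radius/phase/height offset per atom type).  The two
strands are related by the per-base-pair dyad, so a generated duplex has an
exact global two-fold symmetry and its helical axis is +z through the
origin.

Groove sites are cross-strand phosphate midpoints with a fixed integer
offset along the second strand.  The default offset is frozen in
:data:`MAJOR_GROOVE_OFFSET`; :func:`discriminate_major_offset` re-derives it
from the geometry (the offset whose midpoints are recessed into a groove and
lie farthest from the sugar-side reference midpoints).  With the default
fiber constants the resulting site path has a radius of ~6.8 A and the
narrow-groove width (cross-strand P-P minus a 5.8 A phosphate van der Waals
correction) is ~5.8 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import Atom, Structure, write_structure

__all__ = [
    "FiberParams",
    "DNADuplex",
    "GrooveSites",
    "generate_bdna",
    "major_groove_sites",
    "minor_groove_midpoints",
    "discriminate_major_offset",
    "groove_width_series",
    "MAJOR_GROOVE_OFFSET",
    "PHOSPHATE_VDW_CORRECTION",
]

#: frozen default cross-strand offset for major-groove sites (see module docs)
MAJOR_GROOVE_OFFSET = 3
#: P...P van der Waals correction subtracted from raw widths (convention)
PHOSPHATE_VDW_CORRECTION = 5.8
#: a groove site must be radially recessed at least this far inside the
#: phosphate cylinder to count as lying inside a groove
GROOVE_RECESS_MARGIN = 1.5

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class FiberParams:
    """Helical track constants of the fiber generator.

    Defaults are standard B-DNA fiber values (10 bp/turn, 3.38 A rise,
    phosphorus at 8.91 A from the axis); phases are azimuths relative to the
    base-pair dyad, heights are offsets from the base-pair plane.  Strand 2
    is the dyad image of strand 1; overriding ``p_phase_strand2`` away from
    ``-p_phase_strand1`` shears the whole second strand azimuthally.
    """

    twist_per_bp: float = 36.0  # deg
    rise_per_bp: float = 3.38  # A
    p_radius: float = 8.91
    p_phase_strand1: float = 94.5  # deg
    p_phase_strand2: float = -94.5
    p_z_offset: float = 2.08
    c1_radius: float = 5.88
    c1_phase: float = 70.4
    c1_z: float = 1.54
    n_radius: float = 4.90
    n_phase: float = 63.0
    n_z: float = 1.40

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_bp < 90.0:
            raise ValueError("twist_per_bp must be in (0, 90) degrees")
        if self.rise_per_bp <= 0:
            raise ValueError("rise_per_bp must be positive")
        if min(self.p_radius, self.c1_radius, self.n_radius) <= 0:
            raise ValueError("track radii must be positive")


@dataclass(frozen=True)
class GrooveSites:
    """Ordered groove site coordinates with phosphate provenance."""

    sites: np.ndarray  # (M, 3)
    provenance: tuple[tuple[int, int], ...]  # (strand1 index, strand2 index)
    cross_offset: int

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class DNADuplex:
    """Two antiparallel minimal-atom strands in base-pair register.

    Per-strand atom arrays are indexed by base-pair position (0-based from
    the 5' end of strand 1); ``sequence2`` is strand 2 written 5'->3'.
    """

    sequence: str
    params: FiberParams
    strand1: dict[str, np.ndarray] = field(repr=False)  # {"P"|"C1'"|"N": (L, 3)}
    strand2: dict[str, np.ndarray] = field(repr=False)
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def sequence2(self) -> str:
        return "".join(_COMPLEMENT[b] for b in reversed(self.sequence))

    def dyad_transform(self) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) of the global two-fold mapping strand 1 onto strand 2."""
        beta = np.deg2rad((self.n_bp - 1) / 2.0 * self.params.twist_per_bp)
        zc = (self.n_bp - 1) / 2.0 * self.params.rise_per_bp
        u = np.array([np.cos(beta), np.sin(beta), 0.0])
        rot = 2.0 * np.outer(u, u) - np.eye(3)
        pivot = np.array([0.0, 0.0, zc])
        return rot, pivot - rot @ pivot

    def to_structure(self) -> Structure:
        """Chains A/B with P, C1' and glycosidic N per nucleotide."""
        atoms: list[Atom] = []

        def _nt_atoms(base: str, chain: str, resnum: int, p, c1, n):
            glyc = "N9" if base in _PURINES else "N1"
            for name, element, xyz in (("P", "P", p), ("C1'", "C", c1), (glyc, "N", n)):
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        res_name=f"D{base}",
                        res_number=resnum,
                        chain_id=chain,
                        coord=np.array(xyz, dtype=float),
                    )
                )

        for k, base in enumerate(self.sequence):
            _nt_atoms(base, "A", k + 1, self.strand1["P"][k], self.strand1["C1'"][k], self.strand1["N"][k])
        seq2 = self.sequence2
        for i, base in enumerate(seq2):
            k = self.n_bp - 1 - i  # base-pair register of strand-2 nucleotide i
            _nt_atoms(base, "B", i + 1, self.strand2["P"][k], self.strand2["C1'"][k], self.strand2["N"][k])
        return Structure(atoms, name="bdna")

    def write_pdb(self, path: str | Path) -> None:
        write_structure(path, self.to_structure())


def _cyl(radius: float, azimuth_deg: np.ndarray, z: np.ndarray) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    return np.column_stack([radius * np.cos(a), radius * np.sin(a), z])


def generate_bdna(sequence: str, params: FiberParams | None = None) -> DNADuplex:
    """Generate canonical fiber B-DNA coordinates for a sequence."""
    params = params or FiberParams()
    seq = sequence.upper()
    if len(seq) < 4:
        raise ValueError("sequence must be at least 4 bp")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
    k = np.arange(len(seq), dtype=float)
    twist, rise = params.twist_per_bp, params.rise_per_bp
    shear = params.p_phase_strand2 + params.p_phase_strand1  # 0 for a pure dyad
    strand1 = {
        "P": _cyl(params.p_radius, k * twist + params.p_phase_strand1, k * rise + params.p_z_offset),
        "C1'": _cyl(params.c1_radius, k * twist + params.c1_phase, k * rise + params.c1_z),
        "N": _cyl(params.n_radius, k * twist + params.n_phase, k * rise + params.n_z),
    }
    strand2 = {
        "P": _cyl(params.p_radius, k * twist + params.p_phase_strand2, k * rise - params.p_z_offset),
        "C1'": _cyl(params.c1_radius, k * twist - params.c1_phase + shear, k * rise - params.c1_z),
        "N": _cyl(params.n_radius, k * twist - params.n_phase + shear, k * rise - params.n_z),
    }
    return DNADuplex(sequence=seq, params=params, strand1=strand1, strand2=strand2)


def _midpoint_sites(p1: np.ndarray, p2: np.ndarray, offset: int) -> GrooveSites:
    n = len(p1)
    if n - abs(offset) < 1:
        raise ValueError(f"cross offset {offset} exhausts a {n}-nt strand")
    if offset >= 0:
        pairs = [(i, i + offset) for i in range(n - offset)]
    else:
        pairs = [(i, i + offset) for i in range(-offset, n)]
    sites = np.array([(p1[i] + p2[j]) / 2.0 for i, j in pairs])
    if len(sites) < 4:
        warnings.warn(f"only {len(sites)} groove sites for offset {offset}", stacklevel=3)
    return GrooveSites(sites=sites, provenance=tuple(pairs), cross_offset=int(offset))


def major_groove_sites(duplex: DNADuplex, cross_offset: int | None = None) -> GrooveSites:
    """Cross-strand phosphate midpoints tracing the recessed groove path."""
    offset = MAJOR_GROOVE_OFFSET if cross_offset is None else int(cross_offset)
    return _midpoint_sites(duplex.strand1["P"], duplex.strand2["P"], offset)


def minor_groove_midpoints(duplex: DNADuplex) -> np.ndarray:
    """Sugar-side reference midpoints (paired C1' atoms), used to tell grooves apart."""
    return (duplex.strand1["C1'"] + duplex.strand2["C1'"]) / 2.0


def discriminate_major_offset(
    duplex: DNADuplex, candidates: range = range(1, 6)
) -> int:
    """Re-derive the default groove-site offset from duplex geometry.

    Candidate offsets whose midpoints are not radially recessed inside the
    phosphate cylinder (by :data:`GROOVE_RECESS_MARGIN`) are rejected; among
    the rest, the winner maximises the mean distance of its sites from the
    nearest sugar-side (minor groove) reference midpoint.
    """
    axis_p = duplex.axis_point
    axis_d = duplex.axis_direction / np.linalg.norm(duplex.axis_direction)
    minor = minor_groove_midpoints(duplex)
    best_offset, best_score = None, -np.inf
    for offset in candidates:
        try:
            sites = major_groove_sites(duplex, cross_offset=offset).sites
        except ValueError:
            continue
        rel = sites - axis_p
        radial = np.linalg.norm(rel - np.outer(rel @ axis_d, axis_d), axis=1)
        if radial.mean() > duplex.params.p_radius - GROOVE_RECESS_MARGIN:
            continue
        dists = np.linalg.norm(sites[:, None, :] - minor[None, :, :], axis=2)
        score = float(dists.min(axis=1).mean())
        if score > best_score:
            best_offset, best_score = offset, score
    if best_offset is None:
        raise ValueError("no candidate offset produced recessed groove sites")
    return best_offset


def groove_width_series(
    duplex: DNADuplex,
    search_window: int = 6,
    vdw_correction: float = PHOSPHATE_VDW_CORRECTION,
) -> np.ndarray:
    """Per-step narrow-groove width (closest cross-strand P-P minus vdW).

    For each strand-1 phosphate the closest strand-2 phosphate within
    ``search_window`` steps downstream is found; the reported width is that
    distance minus ``vdw_correction``.  Steps whose search window would run
    off the strand are dropped so the series is shift-invariant.
    """
    if search_window < 1:
        raise ValueError("search_window must be >= 1")
    p1, p2 = duplex.strand1["P"], duplex.strand2["P"]
    n = len(p1)
    if n <= search_window:
        raise ValueError("duplex too short for the requested search window")
    widths = []
    for k in range(n - search_window):
        d = np.linalg.norm(p2[k + 1 : k + search_window + 1] - p1[k], axis=1)
        widths.append(d.min() - vdw_correction)
    return np.array(widths)
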