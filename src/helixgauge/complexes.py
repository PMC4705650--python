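"""Protein-DNA complex metrics and the docking-pose filter.

Metrics: mean anchor-to-groove-site distance, intermolecular steric clash
counts, buried (contact) surface area via Shrake-Rupley SASA differences,
and translocation distance for 1D-sliding analysis.  The pose filter applies
helical-compatibility, groove-distance and clash criteria in order and
reports per-pose verdicts with measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .dna import MAJOR_GROOVE_OFFSET, GrooveSites
from .geometry import AnchorPath, HelicalParams
from .structure_io import AnchorSpec, Structure, extract_anchors

__all__ = [
    "ComplexFrame",
    "PoseFilterCriteria",
    "Pose",
    "PoseVerdict",
    "FilterReport",
    "major_groove_distance",
    "count_clashes",
    "shrake_rupley_sasa",
    "contact_surface_area",
    "translocation_distance",
    "sliding_bp",
    "sliding_window_average",
    "filter_poses",
    "groove_sites_from_structure",
    "ELEMENT_RADII",
    "ELEMENT_MASSES",
]

# van der Waals radii (A) used for SASA; unknown elements are an error
ELEMENT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
}

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


@dataclass
class ComplexFrame:
    """Protein and DNA structures sharing one laboratory frame."""

    protein: Structure
    dna: Structure

    def __post_init__(self) -> None:
        if len(self.protein) == 0 or len(self.dna) == 0:
            raise ValueError("both molecules must be non-empty")


def major_groove_distance(anchors: AnchorPath | np.ndarray, sites: GrooveSites | np.ndarray) -> float:
    """Mean over anchors of the distance to the nearest groove site."""
    a = anchors.points if isinstance(anchors, AnchorPath) else np.asarray(anchors, dtype=float)
    s = sites.sites if isinstance(sites, GrooveSites) else np.asarray(sites, dtype=float)
    if len(a) == 0 or len(s) == 0:
        raise ValueError("anchors and sites must be non-empty")
    return float(cdist(a, s).min(axis=1).mean())


def _heavy_coords(structure: Structure) -> np.ndarray:
    idx = structure.select(exclude_hydrogens=True)
    return structure.coords[idx]


def count_clashes(frame: ComplexFrame, dist: float = 2.5) -> int:
    """Intermolecular heavy-atom pairs closer than ``dist`` (strict <).

    Uses a KD-tree; by contract the result equals the all-pairs count.
    """
    a = _heavy_coords(frame.protein)
    b = _heavy_coords(frame.dna)
    if len(a) == 0 or len(b) == 0:
        return 0
    sparse = cKDTree(a).sparse_distance_matrix(cKDTree(b), max_distance=dist, output_type="coo_matrix")
    return int(np.count_nonzero(sparse.data < dist))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley."""
    xyz = np.asarray(coords, dtype=float)
    rad = np.asarray(radii, dtype=float) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(xyz)
    out = np.empty(len(xyz))
    max_reach = 2.0 * rad.max()
    neighbor_lists = tree.query_ball_point(xyz, r=max_reach)
    for i in range(len(xyz)):
        pts = xyz[i] + rad[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > rad[j] ** 2
            if not exposed.any():
                break
        out[i] = 4.0 * np.pi * rad[i] ** 2 * exposed.sum() / n_points
    return out


def _radii_of(structure: Structure, indices: np.ndarray) -> np.ndarray:
    radii = []
    for i in indices:
        el = structure.atoms[int(i)].element.upper()
        if el not in ELEMENT_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii.append(ELEMENT_RADII[el])
    return np.array(radii)


def contact_surface_area(
    frame: ComplexFrame, probe: float = 1.4, n_points: int = 960
) -> float:
    """Buried interface area, (SASA_protein + SASA_dna - SASA_complex) / 2."""
    ip = frame.protein.select(exclude_hydrogens=True)
    idn = frame.dna.select(exclude_hydrogens=True)
    cp, cd = frame.protein.coords[ip], frame.dna.coords[idn]
    rp, rd = _radii_of(frame.protein, ip), _radii_of(frame.dna, idn)
    sasa_p = shrake_rupley_sasa(cp, rp, probe, n_points).sum()
    sasa_d = shrake_rupley_sasa(cd, rd, probe, n_points).sum()
    both = shrake_rupley_sasa(
        np.vstack([cp, cd]), np.concatenate([rp, rd]), probe, n_points
    ).sum()
    return float((sasa_p + sasa_d - both) / 2.0)


def _mass_of(structure: Structure, indices: np.ndarray) -> np.ndarray:
    masses = []
    for i in indices:
        el = structure.atoms[int(i)].element.upper()
        masses.append(ELEMENT_MASSES.get(el, 12.011))
    return np.array(masses)


def translocation_distance(frame: ComplexFrame, anchors: AnchorSpec) -> float:
    """Distance between the anchor-atom COM and the DNA heavy-atom COM."""
    path = extract_anchors(frame.protein, anchors)
    anchor_com = path.points.mean(axis=0)  # identical atoms -> plain mean
    idx = frame.dna.select(exclude_hydrogens=True)
    if len(idx) == 0:
        raise ValueError("DNA has no heavy atoms")
    masses = _mass_of(frame.dna, idx)
    dna_com = (frame.dna.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
    return float(np.linalg.norm(anchor_com - dna_com))


def sliding_bp(d_start: float, d_end: float, rise_per_bp: float = 3.0) -> float:
    """Signed base pairs traversed for a translocation-distance change."""
    if rise_per_bp <= 0:
        raise ValueError("rise_per_bp must be positive")
    return (d_end - d_start) / rise_per_bp


def sliding_window_average(series: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average; edges average over the available span."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if window_frames < 1:
        raise ValueError("window must be >= 1")
    half = (window_frames - 1) // 2
    half_hi = window_frames - 1 - half
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half_hi + 1)
        out[i] = x[lo:hi].mean()
    return out


@dataclass(frozen=True)
class PoseFilterCriteria:
    """Accept/reject thresholds for docking poses."""

    pitch_max: float = 42.0
    radius_min: float = 9.0
    radius_max: float = 16.0
    groove_dist_max: float = 11.0
    clash_dist: float = 2.5
    clash_max: int = 0

    def __post_init__(self) -> None:
        if not self.radius_min < self.radius_max:
            raise ValueError("radius_min must be below radius_max")
        if min(self.pitch_max, self.groove_dist_max, self.clash_dist) <= 0:
            raise ValueError("all distance thresholds must be positive")


@dataclass
class Pose:
    """One candidate pose: coordinates plus its apo helical parameters."""

    name: str
    frame: ComplexFrame
    helical: HelicalParams
    anchors: AnchorPath
    sites: GrooveSites


@dataclass
class PoseVerdict:
    name: str
    accepted: bool
    failures: list[str] = field(default_factory=list)
    measured: dict[str, float] = field(default_factory=dict)


@dataclass
class FilterReport:
    verdicts: list[PoseVerdict]
    criteria: PoseFilterCriteria

    @property
    def accepted(self) -> list[PoseVerdict]:
        return [v for v in self.verdicts if v.accepted]

    def to_rows(self) -> list[dict]:
        rows = []
        for v in self.verdicts:
            rows.append(
                {
                    "pose": v.name,
                    "accepted": int(v.accepted),
                    "failures": ",".join(v.failures) or "-",
                    **{k: round(val, 4) for k, val in v.measured.items()},
                }
            )
        return rows


def filter_poses(poses: Sequence[Pose], criteria: PoseFilterCriteria | None = None) -> FilterReport:
    """Apply pitch/radius, groove-distance and clash criteria, in order.

    Every criterion is evaluated for every pose so the report carries all
    measured values; a pose is accepted iff no criterion fails.
    """
    criteria = criteria or PoseFilterCriteria()
    verdicts = []
    for pose in poses:
        failures: list[str] = []
        measured: dict[str, float] = {}
        measured["pitch"] = pose.helical.pitch_kappa
        measured["radius"] = pose.helical.radius
        if not pose.helical.pitch_kappa < criteria.pitch_max:
            failures.append("pitch")
        if not criteria.radius_min <= pose.helical.radius <= criteria.radius_max:
            failures.append("radius")
        groove = major_groove_distance(pose.anchors, pose.sites)
        measured["groove_distance"] = groove
        if not groove <= criteria.groove_dist_max:
            failures.append("groove_distance")
        clashes = count_clashes(pose.frame, criteria.clash_dist)
        measured["clashes"] = float(clashes)
        if clashes > criteria.clash_max:
            failures.append("clashes")
        verdicts.append(
            PoseVerdict(name=pose.name, accepted=not failures, failures=failures, measured=measured)
        )
    return FilterReport(verdicts=verdicts, criteria=criteria)


def groove_sites_from_structure(
    structure: Structure,
    chains: tuple[str, str] = ("B", "C"),
    cross_offset: int = MAJOR_GROOVE_OFFSET,
) -> GrooveSites:
    """Groove sites for deposited (non-generated) DNA coordinates.

    Phosphorus atoms are collected per chain in residue order; the second
    chain is reversed into base-pair register (antiparallel convention)
    before applying the same cross-strand midpoint rule as the fiber model.
    """
    def _p_atoms(chain: str) -> np.ndarray:
        atoms = [
            a for a in structure.atoms if a.chain_id == chain and a.name == "P"
        ]
        atoms.sort(key=lambda a: (a.res_number, a.insertion_code))
        if not atoms:
            raise ValueError(f"no phosphorus atoms on chain {chain!r}")
        return np.array([a.coord for a in atoms])

    p1 = _p_atoms(chains[0])
    p2 = _p_atoms(chains[1])[::-1]
    n = min(len(p1), len(p2))
    if len(p1) != len(p2):
        warnings.warn(
            f"DNA chains differ in length ({len(p1)} vs {len(p2)}); truncating to {n}",
            stacklevel=2,
        )
    from .dna import _midpoint_sites

    return _midpoint_sites(p1[:n], p2[:n], cross_offset)
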