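"""Structure and ensemble I/O, anchor extraction, superposition and RMSD.

Reading uses Biopython's permissive PDB parser; writing emits the plain
ATOM/HETATM/MODEL dialect so fixtures and outputs stay text-only.  All
coordinates are Angstrom; residue numbering follows the author numbering of
the source file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .geometry import AnchorPath

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "AnchorSpec",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "extract_anchors",
    "parse_selection",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsd_series",
]

_ELEMENT_FROM_NAME_HINTS = {"CL": "CL", "BR": "BR", "NA": "NA", "MG": "MG", "ZN": "ZN", "FE": "FE", "MN": "MN", "CA": "CA", "K": "K"}


@dataclass
class Atom:
    name: str
    element: str
    res_name: str
    res_number: int
    chain_id: str
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    insertion_code: str = ""
    is_hetero: bool = False

    def key(self) -> tuple:
        return (self.chain_id, self.res_number, self.insertion_code, self.name)


class Structure:
    """A flat, ordered atom list with array views and simple selections."""

    def __init__(self, atoms: Sequence[Atom], name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.name = name
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom key {dup!r} in structure")
        coords = np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, value):
            atom.coord = np.array(xyz, dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.atoms], dtype=float)

    def find(self, chain_id: str, res_number: int, atom_name: str) -> Optional[int]:
        return self._index.get((chain_id, int(res_number), "", atom_name))

    def select(
        self,
        names: Optional[Iterable[str]] = None,
        chains: Optional[Iterable[str]] = None,
        elements: Optional[Iterable[str]] = None,
        exclude_hydrogens: bool = False,
    ) -> np.ndarray:
        """Return indices of atoms matching all given filters."""
        names = set(names) if names is not None else None
        chains = set(chains) if chains is not None else None
        elements = {e.upper() for e in elements} if elements is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if names is not None and a.name not in names:
                continue
            if chains is not None and a.chain_id not in chains:
                continue
            if elements is not None and a.element.upper() not in elements:
                continue
            if exclude_hydrogens and a.element.upper() in ("H", "D"):
                continue
            out.append(i)
        return np.array(out, dtype=int)

    def subset(self, indices: np.ndarray) -> "Structure":
        """A new structure with deep-copied atoms at the given indices."""
        picked = []
        for i in indices:
            a = self.atoms[int(i)]
            picked.append(Atom(**{**a.__dict__, "coord": np.array(a.coord, dtype=float)}))
        return Structure(picked, name=self.name)

    def copy(self) -> "Structure":
        return self.subset(np.arange(len(self.atoms)))


@dataclass
class Ensemble:
    """A topology plus congruent per-frame coordinate arrays."""

    topology: Structure
    frames: np.ndarray  # (F, N, 3)
    frame_times: Optional[np.ndarray] = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("every frame must match the topology atom count")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.frames):
                raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def parse_selection(expr: str, structure: Structure) -> np.ndarray:
    """Tiny selection language: clauses joined by ``and``.

    Supported clauses: ``all``, ``name N1 N2 ...``, ``chain A B``,
    ``element C N``, ``heavy`` (exclude hydrogens).
    """
    names = chains = elements = None
    exclude_h = False
    for clause in expr.split(" and "):
        toks = clause.split()
        if not toks:
            continue
        kind = toks[0].lower()
        if kind == "all":
            continue
        elif kind == "name":
            names = toks[1:]
        elif kind == "chain":
            chains = toks[1:]
        elif kind == "element":
            elements = toks[1:]
        elif kind == "heavy":
            exclude_h = True
        else:
            raise ValueError(f"unknown selection clause {clause!r}")
    idx = structure.select(names=names, chains=chains, elements=elements, exclude_hydrogens=exclude_h)
    if len(idx) == 0:
        raise ValueError(f"selection {expr!r} matched no atoms")
    return idx


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _ELEMENT_FROM_NAME_HINTS and len(name.strip()) <= 2:
        return _ELEMENT_FROM_NAME_HINTS[two]
    return stripped[0].upper()


def _atoms_from_model(model, structure_name: str) -> list[Atom]:
    atoms: list[Atom] = []
    missing_b = False
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            by_name: dict[str, list] = {}
            for atom in residue.get_unpacked_list():
                by_name.setdefault(atom.get_name(), []).append(atom)
            for name, variants in by_name.items():
                if len(variants) > 1:
                    # altloc: highest occupancy wins, ties to smallest altloc id
                    variants.sort(
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() or "A")
                    )
                chosen = variants[0]
                element = (chosen.element or "").strip() or _guess_element(name)
                bfac = chosen.get_bfactor()
                if bfac is None:
                    bfac = 0.0
                    missing_b = True
                occ = chosen.get_occupancy()
                atoms.append(
                    Atom(
                        name=name,
                        element=element.upper(),
                        res_name=residue.get_resname().strip(),
                        res_number=int(resseq),
                        chain_id=str(chain.id),
                        coord=np.array(chosen.get_coord(), dtype=float),
                        b_factor=float(bfac),
                        occupancy=1.0 if occ is None else float(occ),
                        insertion_code=icode.strip(),
                        is_hetero=bool(hetflag.strip()),
                    )
                )
    if missing_b:
        warnings.warn(f"{structure_name}: missing B-factors set to 0", stacklevel=3)
    return atoms


def _parse_pdb(path: str | Path):
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    parser = PDBParser(QUIET=True)
    return parser.get_structure(path.stem, str(path))


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a flat :class:`Structure`."""
    pdb = _parse_pdb(path)
    models = list(pdb)
    if not 0 <= model_index < len(models):
        raise IndexError(f"model index {model_index} out of range (file has {len(models)})")
    return Structure(_atoms_from_model(models[model_index], Path(path).stem), name=Path(path).stem)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB as an :class:`Ensemble` (topology = model 0)."""
    pdb = _parse_pdb(path)
    models = list(pdb)
    if not models:
        raise ValueError(f"no models in {path}")
    topology = Structure(_atoms_from_model(models[0], Path(path).stem), name=Path(path).stem)
    frames = [topology.coords]
    ref_keys = [a.key() for a in topology.atoms]
    for model in models[1:]:
        atoms = _atoms_from_model(model, Path(path).stem)
        if [a.key() for a in atoms] != ref_keys:
            raise ValueError("all models must share the same atoms for an ensemble")
        frames.append(np.array([a.coord for a in atoms]))
    return Ensemble(topology=topology, frames=np.array(frames))


def _format_atom_line(serial: int, atom: Atom) -> str:
    name = atom.name
    if len(name) < 4:
        name = f" {name:<3s}" if len(atom.element) == 1 else f"{name:<4s}"
    record = "HETATM" if atom.is_hetero else "ATOM  "
    x, y, z = atom.coord
    icode = atom.insertion_code[:1] if atom.insertion_code else " "
    return (
        f"{record}{serial % 100000:>5d} {name:<4s} {atom.res_name:>3s} "
        f"{atom.chain_id[:1]:1s}{atom.res_number:>4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element[:2]:>2s}"
    )


def write_structure(path: str | Path, structure: Structure) -> None:
    lines = [_format_atom_line(i + 1, a) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(path: str | Path, ensemble: Ensemble) -> None:
    lines: list[str] = []
    top = ensemble.topology
    for f, frame in enumerate(ensemble.frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        for i, (atom, xyz) in enumerate(zip(top.atoms, frame)):
            shadow = Atom(**{**atom.__dict__, "coord": np.asarray(xyz, dtype=float)})
            lines.append(_format_atom_line(i + 1, shadow))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class AnchorSpec:
    """Ordered (chain, residue number, atom name) triples defining a path."""

    entries: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        entries = tuple((str(c), int(r), str(a)) for c, r, a in self.entries)
        if len(entries) < 4:
            raise ValueError("an anchor spec needs at least 4 entries")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnchorSpec":
        data = yaml.safe_load(Path(path).read_text())
        if isinstance(data, dict):
            data = data["anchors"]
        entries = []
        for item in data:
            if isinstance(item, str):
                chain, res, atom = item.split()
            else:
                chain, res, atom = item["chain"], item["residue"], item["atom"]
            entries.append((chain, int(res), atom))
        return cls(entries=tuple(entries))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "anchors": [
                {"chain": c, "residue": r, "atom": a} for c, r, a in self.entries
            ]
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_mterf1_anchor_spec() -> AnchorSpec:
    """The shipped MTERF1 anchor list (example defaults, see packaged YAML)."""
    from importlib.resources import files

    path = files("helixgauge.data").joinpath("mterf1_anchors.yaml")
    data = yaml.safe_load(path.read_text())
    return AnchorSpec(
        entries=tuple((d["chain"], int(d["residue"]), d["atom"]) for d in data["anchors"])
    )


def extract_anchors(structure: Structure, spec: AnchorSpec) -> AnchorPath:
    """Resolve an :class:`AnchorSpec` against a structure, in spec order."""
    points, labels = [], []
    for chain, res, atom_name in spec.entries:
        idx = structure.find(chain, res, atom_name)
        if idx is None:
            raise KeyError(f"anchor not found in structure: chain {chain} residue {res} atom {atom_name}")
        points.append(structure.atoms[idx].coord)
        labels.append(f"{chain}:{res}:{atom_name}")
    return AnchorPath(points=np.array(points), labels=tuple(labels))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R @ p + t ~= q."""
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("superposition needs two equal (N>=3, 3) coordinate sets")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    return rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RMSD needs equal-shape coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    The fit uses ``fit_indices`` (default: all atoms); the whole mobile set is
    transformed and the returned RMSD is post-fit over the fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    rot, trans = kabsch(mobile[fit_indices], reference[fit_indices])
    moved = mobile @ rot.T + trans
    return moved, rmsd(moved[fit_indices], reference[fit_indices])


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_indices: np.ndarray,
    measure_indices: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD with independent fit and measurement selections.

    Each frame is superposed onto ``reference`` using ``fit_indices`` and the
    RMSD is then measured over ``measure_indices`` (default: the fit
    selection), reproducing e.g. fit-on-protein / measure-complex analyses.
    """
    reference = np.asarray(reference, dtype=float)
    fit_indices = np.asarray(fit_indices, dtype=int)
    if len(fit_indices) == 0:
        raise ValueError("empty fit selection")
    if measure_indices is None:
        measure_indices = fit_indices
    measure_indices = np.asarray(measure_indices, dtype=int)
    if len(measure_indices) == 0:
        raise ValueError("empty measurement selection")
    out = np.empty(ensemble.n_frames)
    for f, frame in enumerate(ensemble.frames):
        moved, _ = superpose(frame, reference, fit_indices)
        out[f] = rmsd(moved[measure_indices], reference[measure_indices])
    return out
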