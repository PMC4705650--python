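"""Deterministic synthetic fixtures: helices, planted-mode ensembles, sliders.

Every generator is a pure function of its spec and an explicit seed, so
tests and the CLI can produce byte-identical PDB/TSV fixtures with no
downloads.  Fixture structures use chain ``P`` for pseudo-Calpha anchor
beads and chains ``A``/``B`` for generated DNA so the real parsers are
exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .complexes import ELEMENT_MASSES, ComplexFrame
from .dna import DNADuplex, GrooveSites, generate_bdna, major_groove_sites
from .geometry import AnchorPath, HelicalParams, PlaneOrientation, rotation_matrix
from .structure_io import AnchorSpec, Atom, Ensemble, Structure

__all__ = [
    "HelixSpec",
    "SlidingTrajectory",
    "make_ideal_helix",
    "pseudo_ca_structure",
    "orthogonalize_to_rigid",
    "make_toy_ensemble",
    "make_toy_sliding_trajectory",
]


@dataclass(frozen=True)
class HelixSpec:
    """Specification of an ideal (optionally noisy) anchor helix."""

    n_points: int = 9
    radius: float = 9.4
    pitch: float = 34.0
    sweep_per_step: float = 36.0  # signed, deg
    start_phase: float = 0.0
    orientation: PlaneOrientation = PlaneOrientation(0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("need at least 4 anchor points")
        if self.radius < 0 or self.pitch < 0 or self.noise_sigma < 0:
            raise ValueError("radius, pitch and noise must be non-negative")
        if self.sweep_per_step == 0:
            raise ValueError("sweep_per_step must be nonzero")


def make_ideal_helix(spec: HelixSpec) -> tuple[AnchorPath, HelicalParams]:
    """Generate an anchor path with known ground-truth helical parameters.

    Point ``k`` sits at angle ``start_phase + k * sweep_per_step`` and height
    ``k * pitch * |sweep_per_step| / 360`` on a z-axis helix, which is then
    rigidly rotated so that analysing it at ``spec.orientation`` brings the
    axis back to z.  Isotropic Gaussian noise is added per coordinate.
    """
    k = np.arange(spec.n_points, dtype=float)
    ang = np.deg2rad(spec.start_phase + k * spec.sweep_per_step)
    rise_per_step = spec.pitch * abs(spec.sweep_per_step) / 360.0
    pts = np.column_stack(
        [spec.radius * np.cos(ang), spec.radius * np.sin(ang), k * rise_per_step]
    )
    # analysis applies R(orientation); generate in the inverse frame
    pts = pts @ rotation_matrix(spec.orientation)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    truth = HelicalParams(
        radius=spec.radius,
        sweep_phi=(spec.n_points - 1) * spec.sweep_per_step,
        delta_z=(spec.n_points - 1) * rise_per_step,
        pitch_kappa=spec.pitch,
        orientation=spec.orientation,
        rms_residual=0.0,
        degenerate=spec.pitch == 0.0,
    )
    return AnchorPath(points=pts), truth


def pseudo_ca_structure(coords: np.ndarray, chain_id: str = "P") -> Structure:
    """A chain of pseudo-Calpha beads (one GLY CA per residue)."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        Atom(
            name="CA",
            element="C",
            res_name="GLY",
            res_number=i + 1,
            chain_id=chain_id,
            coord=np.array(xyz),
        )
        for i, xyz in enumerate(coords)
    ]
    return Structure(atoms, name="pseudo_ca")


def orthogonalize_to_rigid(base_coords: np.ndarray, mode: np.ndarray) -> np.ndarray:
    """Remove rigid-body (translation/rotation) components from a mode.

    Useful for planting modes that survive superposition-based analyses
    unchanged.  Returns a unit vector.
    """
    xyz = np.asarray(base_coords, dtype=float)
    n = len(xyz)
    centered = xyz - xyz.mean(axis=0)
    basis = []
    for axis in np.eye(3):
        basis.append(np.tile(axis, n))  # translations
    for axis in np.eye(3):
        basis.append(np.cross(np.tile(axis, (n, 1)), centered).ravel())  # rotations
    q, _ = np.linalg.qr(np.array(basis).T)
    v = np.asarray(mode, dtype=float).ravel().copy()
    v -= q @ (q.T @ v)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("mode is entirely rigid-body motion")
    return v / norm


def make_toy_ensemble(
    base: Structure | np.ndarray,
    planted_mode: np.ndarray,
    amplitudes: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Ensemble:
    """Frames = base + a_t * mode + noise; the planted mode is the true PC."""
    if isinstance(base, Structure):
        topology, coords = base, base.coords
    else:
        coords = np.asarray(base, dtype=float)
        topology = pseudo_ca_structure(coords)
    mode = np.asarray(planted_mode, dtype=float).ravel()
    if mode.size != coords.size:
        raise ValueError("planted mode length must equal 3 * n_atoms")
    amps = np.asarray(list(amplitudes), dtype=float)
    rng = np.random.default_rng(seed)
    frames = coords[None, :, :] + amps[:, None, None] * mode.reshape(1, *coords.shape)
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    return Ensemble(topology=topology, frames=frames)


@dataclass
class SlidingTrajectory:
    """A toy search-mode trajectory with construction-time ground truth."""

    frames: list[ComplexFrame]
    anchor_paths: list[AnchorPath]
    anchor_spec: AnchorSpec
    duplex: DNADuplex
    sites: GrooveSites
    translocation_truth: np.ndarray  # (F,) A, noiseless
    bp_per_frame: float
    rise_per_bp: float


def _dna_com(dna: Structure) -> np.ndarray:
    idx = dna.select(exclude_hydrogens=True)
    masses = np.array(
        [ELEMENT_MASSES.get(dna.atoms[int(i)].element.upper(), 12.011) for i in idx]
    )
    return (dna.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()


def make_toy_sliding_trajectory(
    n_frames: int = 10,
    bp_per_frame: float = 1.0,
    duplex_length: int = 22,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_anchors: int = 9,
    start_bp: float = 0.0,
    sequence: Optional[str] = None,
) -> SlidingTrajectory:
    """A rigid anchor path sliding along the major-groove site helix.

    The 9-bead pseudo-protein starts on the generated groove-site path and
    advances by ``bp_per_frame`` helical steps per frame (screw motion about
    the duplex axis); the DNA stays fixed.  Frames whose leading anchor
    would run off the duplex are truncated with a warning.
    """
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list("ACGT"), size=duplex_length))
    duplex = generate_bdna(sequence)
    sites = major_groove_sites(duplex)
    # continuous helical parametrisation of the site path
    s0 = sites.sites[0]
    site_radius = float(np.hypot(s0[0], s0[1]))
    site_phase = float(np.degrees(np.arctan2(s0[1], s0[0])))
    site_z0 = float(s0[2])
    twist, rise = duplex.params.twist_per_bp, duplex.params.rise_per_bp

    def site_at(t: np.ndarray) -> np.ndarray:
        a = np.deg2rad(site_phase + t * twist)
        return np.column_stack(
            [site_radius * np.cos(a), site_radius * np.sin(a), site_z0 + t * rise]
        )

    max_t = len(sites) - 1
    if start_bp < 0 or start_bp + n_anchors - 1 > max_t:
        raise ValueError("start_bp places anchors off the duplex")
    if bp_per_frame > 0:
        usable = int(np.floor((max_t - start_bp - (n_anchors - 1)) / bp_per_frame)) + 1
        if n_frames > usable:
            warnings.warn(
                f"truncating sliding trajectory to {usable} frames "
                f"(anchors reach the duplex end)",
                stacklevel=2,
            )
            n_frames = usable
    if n_frames < 1:
        raise ValueError("duplex too short for even one frame")

    dna_structure = duplex.to_structure()
    dna_com = _dna_com(dna_structure)
    anchor_spec = AnchorSpec(entries=tuple(("P", i + 1, "CA") for i in range(n_anchors)))

    frames, paths, truth = [], [], []
    k = np.arange(n_anchors, dtype=float)
    for f in range(n_frames):
        t = start_bp + k + f * bp_per_frame
        clean = site_at(t)
        truth.append(float(np.linalg.norm(clean.mean(axis=0) - dna_com)))
        noisy = clean + (
            rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma > 0 else 0.0
        )
        protein = pseudo_ca_structure(noisy, chain_id="P")
        frames.append(ComplexFrame(protein=protein, dna=dna_structure))
        paths.append(AnchorPath(points=noisy))
    return SlidingTrajectory(
        frames=frames,
        anchor_paths=paths,
        anchor_spec=anchor_spec,
        duplex=duplex,
        sites=sites,
        translocation_truth=np.array(truth),
        bp_per_frame=bp_per_frame,
        rise_per_bp=rise,
    )
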