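"""Global helical gauge for ordered anchor-point paths.

The gauge treats an ordered set of 3D anchor points (e.g. one residue per
repeat motif of a superhelical protein) as samples of a single global helix.
A candidate helical axis is parameterised by a plane orientation ``(phi,
theta)``; the points are rotated so the candidate fitting plane becomes the
xy-plane, a circle is fitted to the projection by linear least squares, and
pitch/radius/sweep/rise are read off the fit.  The best orientation is found
by a coarse grid search over the orientation sphere followed by local
simplex refinement of the circle-fit residual.

Conventions
-----------
* ``phi`` is a rotation about the laboratory y-axis, ``theta`` about the
  laboratory z-axis; the z-rotation is applied first (``R = Ry(phi) @
  Rz(theta)``).  ``phi`` lives in ``[0, 180)`` and ``theta`` in ``[0, 360)``.
* The signed sweep carries the handedness of the path; ``delta_z`` is signed
  in the rotated frame; the pitch is reported from absolute values.
* Lengths are Angstrom, angles degrees, throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DegenerateFitError",
    "PlaneOrientation",
    "CircleFit",
    "AnchorPath",
    "HelicalParams",
    "GridSearchResult",
    "rotation_matrix",
    "rotate_to_plane",
    "fit_circle",
    "sweep_angles",
    "helical_params_at",
    "residual_surface",
    "grid_search_orientation",
    "refine_orientation",
]

#: absolute tolerance (Angstrom) below which an axial rise is treated as zero
DEGENERATE_DZ_TOL = 1e-6
#: absolute tolerance (degrees) below which a total sweep is treated as zero
DEGENERATE_SWEEP_TOL = 1e-7


class DegenerateFitError(ValueError):
    """Raised when a circle fit is degenerate (e.g. collinear points)."""


def _canonicalize_angles(phi: float, theta: float) -> tuple[float, float]:
    phi = float(phi) % 360.0
    theta = float(theta) % 360.0
    if phi >= 180.0:
        if phi == 180.0:
            # xy-plane with flipped normal; identify with phi = 0
            phi = 0.0
        else:
            # (phi, theta) and (360 - phi, theta + 180) share the same normal
            phi = 360.0 - phi
            theta = (theta + 180.0) % 360.0
    return phi, theta


@dataclass(frozen=True)
class PlaneOrientation:
    """Orientation of the candidate fitting plane, stored canonically.

    ``phi`` in ``[0, 180)``, ``theta`` in ``[0, 360)``; orientations
    differing by full turns (or by the normal-preserving identification
    ``(phi, theta) ~ (360 - phi, theta + 180)``) compare equal.
    """

    phi: float
    theta: float

    def __post_init__(self) -> None:
        phi, theta = _canonicalize_angles(self.phi, self.theta)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "theta", theta)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle in the fitting plane."""

    center: np.ndarray  # (2,) in-plane coordinates, Angstrom
    radius: float
    rms_residual: float  # rms radial deviation of the points from the circle


@dataclass(frozen=True)
class AnchorPath:
    """Ordered 3D anchor coordinates tracing a putative helix."""

    points: np.ndarray  # (N, 3)
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if len(pts) < 4:
            raise ValueError("an anchor path needs at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("anchor coordinates must be finite")
        step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(step <= 0.0):
            raise ValueError("consecutive anchor points must not coincide")
        object.__setattr__(self, "points", pts)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != len(pts):
                raise ValueError("labels must match the number of points")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class HelicalParams:
    """Global helical parameters of an anchor path at a given orientation."""

    radius: float
    sweep_phi: float  # signed total swept angle, degrees
    delta_z: float  # signed axial first-to-last rise, Angstrom
    pitch_kappa: float  # axial rise per full turn, Angstrom
    orientation: PlaneOrientation
    rms_residual: float
    degenerate: bool = False


def rotation_matrix(orientation: PlaneOrientation) -> np.ndarray:
    """Rotation bringing the candidate plane into the xy-plane (Ry(phi)Rz(theta))."""
    phi = np.deg2rad(orientation.phi)
    theta = np.deg2rad(orientation.theta)
    cp, sp = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rz = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
    return ry @ rz


def rotate_to_plane(points: np.ndarray, orientation: PlaneOrientation) -> np.ndarray:
    """Rigidly rotate ``points`` so the candidate fitting plane is z = const."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3 or len(pts) < 1:
        raise ValueError("points must have shape (N, 3) with N >= 1")
    return pts @ rotation_matrix(orientation).T


def fit_circle(points2d: np.ndarray) -> CircleFit:
    """Algebraic (Kasa-form) least-squares circle through 2D points.

    Minimises ``sum (x^2 + y^2 + a x + b y + c)^2`` via an SVD-backed linear
    solve; the centre is ``(-a/2, -b/2)`` and the radius
    ``sqrt(a^2/4 + b^2/4 - c)``.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points2d must have shape (N, 2)")
    if len(pts) < 3:
        raise ValueError("a circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    design = np.column_stack([x, y, np.ones_like(x)])
    rhs = -(x * x + y * y)
    sol, _, rank, sv = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 3 or sv[-1] <= 1e-9 * sv[0]:
        raise DegenerateFitError("points are (nearly) collinear; circle radius diverges")
    a, b, c = sol
    center = np.array([-a / 2.0, -b / 2.0])
    r2 = center[0] ** 2 + center[1] ** 2 - c
    if r2 <= 0.0:
        raise DegenerateFitError("degenerate circle fit (non-positive squared radius)")
    radius = float(np.sqrt(r2))
    dist = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return CircleFit(center=center, radius=radius, rms_residual=rms)


def sweep_angles(points2d: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Signed minimal-magnitude step angles (degrees) about ``center``.

    Each of the N-1 angles is the rotation in ``(-180, 180]`` carrying point
    ``i`` to point ``i+1``; their sum is the helical sweep.
    """
    pts = np.asarray(points2d, dtype=float)
    ctr = np.asarray(center, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("points2d must have shape (N, 2) with N >= 2")
    vec = pts - ctr
    if np.any(np.linalg.norm(vec, axis=1) < 1e-9):
        raise DegenerateFitError("a point coincides with the circle centre")
    ang = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
    diff = np.diff(ang)
    step = (diff + 180.0) % 360.0 - 180.0
    step[step == -180.0] = 180.0
    return step


def helical_params_at(
    path: AnchorPath | np.ndarray,
    orientation: PlaneOrientation,
    literal_pitch: bool = False,
) -> HelicalParams:
    """Evaluate the gauge at a fixed plane orientation.

    Rotates the path, fits the in-plane circle, accumulates the signed sweep
    and reads the axial rise ``delta_z`` (last minus first rotated z).  The
    pitch is the axial rise per full turn, ``|delta_z| * 360 / |sweep|``.
    Setting ``literal_pitch`` instead multiplies (rather than divides) by the
    fractional number of turns, ``|delta_z| * |sweep| / 360`` — retained only
    for comparison, as it shrinks with growing sweep.

    Coplanar paths are reported with ``pitch_kappa = 0`` and
    ``degenerate=True`` instead of raising.
    """
    pts = path.points if isinstance(path, AnchorPath) else np.asarray(path, dtype=float)
    rot = rotate_to_plane(pts, orientation)
    fit = fit_circle(rot[:, :2])
    steps = sweep_angles(rot[:, :2], fit.center)
    sweep = float(np.sum(steps))
    dz = float(rot[-1, 2] - rot[0, 2])
    degenerate = abs(dz) < DEGENERATE_DZ_TOL or abs(sweep) < DEGENERATE_SWEEP_TOL
    if abs(dz) < DEGENERATE_DZ_TOL:
        pitch = 0.0  # coplanar path
    elif abs(sweep) < DEGENERATE_SWEEP_TOL:
        pitch = float("nan")
    elif literal_pitch:
        pitch = abs(dz) * abs(sweep) / 360.0
    else:
        pitch = abs(dz) * 360.0 / abs(sweep)
    return HelicalParams(
        radius=fit.radius,
        sweep_phi=sweep,
        delta_z=dz,
        pitch_kappa=pitch,
        orientation=orientation,
        rms_residual=fit.rms_residual,
        degenerate=degenerate,
    )


def _batched_rotations(phis_deg: np.ndarray, thetas_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices for the (phi x theta) grid, shape (P, T, 3, 3)."""
    phi = np.deg2rad(phis_deg)[:, None]
    theta = np.deg2rad(thetas_deg)[None, :]
    cp, sp = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    shape = np.broadcast(cp, ct).shape
    rot = np.empty(shape + (3, 3))
    # Ry(phi) @ Rz(theta) written out
    rot[..., 0, 0] = cp * ct
    rot[..., 0, 1] = -cp * st
    rot[..., 0, 2] = sp + np.zeros_like(ct)
    rot[..., 1, 0] = st + np.zeros_like(cp)
    rot[..., 1, 1] = ct + np.zeros_like(cp)
    rot[..., 1, 2] = np.zeros(shape)
    rot[..., 2, 0] = -sp * ct
    rot[..., 2, 1] = sp * st
    rot[..., 2, 2] = cp + np.zeros_like(ct)
    return rot


def residual_surface(
    points: np.ndarray, phis_deg: np.ndarray, thetas_deg: np.ndarray
) -> np.ndarray:
    """Circle-fit rms residual over an orientation grid, shape (P, T).

    Vectorised fast path used by the grid search; it solves the Kasa normal
    equations per orientation, which agrees with :func:`fit_circle` to
    rounding on non-degenerate input.  Degenerate cells evaluate to +inf.
    """
    pts = np.asarray(points, dtype=float)
    phis = np.asarray(phis_deg, dtype=float)
    thetas = np.asarray(thetas_deg, dtype=float)
    rot = _batched_rotations(phis, thetas)  # (P, T, 3, 3)
    # rotated in-plane coordinates, (P, T, N)
    x = np.einsum("ptj,nj->ptn", rot[..., 0, :], pts)
    y = np.einsum("ptj,nj->ptn", rot[..., 1, :], pts)
    n = pts.shape[0]
    one = np.ones(n)
    s = x * x + y * y
    # normal equations M @ [a, b, c] = v for the Kasa system
    m = np.empty(x.shape[:2] + (3, 3))
    m[..., 0, 0] = np.einsum("ptn,ptn->pt", x, x)
    m[..., 0, 1] = np.einsum("ptn,ptn->pt", x, y)
    m[..., 0, 2] = x.sum(axis=-1)
    m[..., 1, 0] = m[..., 0, 1]
    m[..., 1, 1] = np.einsum("ptn,ptn->pt", y, y)
    m[..., 1, 2] = y.sum(axis=-1)
    m[..., 2, 0] = m[..., 0, 2]
    m[..., 2, 1] = m[..., 1, 2]
    m[..., 2, 2] = float(n)
    v = np.empty(x.shape[:2] + (3,))
    v[..., 0] = -np.einsum("ptn,ptn->pt", x, s)
    v[..., 1] = -np.einsum("ptn,ptn->pt", y, s)
    v[..., 2] = -s.sum(axis=-1)
    # regularise near-singular (collinear projection) cells, flag them after
    eye = np.eye(3)
    dets = np.abs(np.linalg.det(m))
    bad = dets < 1e-10 * (np.abs(m).max(axis=(-2, -1)) ** 3 + 1e-30)
    m_safe = m + 1e-9 * eye * bad[..., None, None]
    sol = np.linalg.solve(m_safe, v[..., None])[..., 0]
    cx, cy = -sol[..., 0] / 2.0, -sol[..., 1] / 2.0
    r2 = cx * cx + cy * cy - sol[..., 2]
    good = (r2 > 0.0) & ~bad
    radius = np.sqrt(np.where(good, r2, 1.0))
    dist = np.sqrt((x - cx[..., None]) ** 2 + (y - cy[..., None]) ** 2)
    res = np.sqrt(np.mean((dist - radius[..., None]) ** 2, axis=-1))
    res[~good] = np.inf
    return res


@dataclass(frozen=True)
class GridSearchResult:
    orientation: PlaneOrientation
    params: HelicalParams
    phi_grid: np.ndarray
    theta_grid: np.ndarray
    residuals: np.ndarray  # (len(phi_grid), len(theta_grid))
    flat_surface: bool  # True when the residual surface carries no signal


def _residual_objective(pts: np.ndarray):
    def objective(angles: np.ndarray) -> float:
        try:
            fit = fit_circle(rotate_to_plane(pts, PlaneOrientation(*angles))[:, :2])
        except DegenerateFitError:
            return np.inf
        return fit.rms_residual

    return objective


def refine_orientation(
    path: AnchorPath | np.ndarray,
    start: PlaneOrientation,
    literal_pitch: bool = False,
) -> HelicalParams:
    """Polish the plane orientation locally from a known starting point.

    This is the per-structure step of the aligned-ensemble workflow: once the
    ensemble is aligned (or the generating axis is known), each structure's
    orientation is refined from the common region rather than re-searched
    globally, which keeps noisy few-anchor paths from tilting onto spurious
    large-circle planes.
    """
    pts = path.points if isinstance(path, AnchorPath) else np.asarray(path, dtype=float)
    objective = _residual_objective(pts)
    opt = minimize(
        objective,
        np.array([start.phi, start.theta]),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 3000, "maxfev": 3000},
    )
    best = opt.x if np.isfinite(opt.fun) else np.array([start.phi, start.theta])
    return helical_params_at(pts, PlaneOrientation(*best), literal_pitch=literal_pitch)


def grid_search_orientation(
    path: AnchorPath | np.ndarray,
    coarse_step: float = 2.0,
    refine: bool = True,
    literal_pitch: bool = False,
    phi_range: tuple[float, float] = (0.0, 180.0),
    theta_range: tuple[float, float] = (0.0, 360.0),
) -> GridSearchResult:
    """Find the plane orientation minimising the circle-fit residual.

    A coarse grid (by default ``phi`` in [0, 180), ``theta`` in [0, 360),
    step ``coarse_step`` degrees) is scanned with the vectorised residual
    surface; ties break to the lexicographically smallest ``(phi, theta)``.
    The best cell is optionally polished with Nelder--Mead on the exact
    objective.  ``phi_range``/``theta_range`` restrict the scan, mirroring
    workflows where a low-residual region is known for an aligned ensemble.
    """
    pts = path.points if isinstance(path, AnchorPath) else np.asarray(path, dtype=float)
    if coarse_step <= 0:
        raise ValueError("coarse_step must be positive")
    phis = np.arange(phi_range[0], phi_range[1], coarse_step)
    thetas = np.arange(theta_range[0], theta_range[1], coarse_step)
    surface = residual_surface(pts, phis, thetas)
    finite = surface[np.isfinite(surface)]
    flat = finite.size == 0 or float(finite.max() - finite.min()) < 1e-12
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    best = np.array([phis[i], thetas[j]])
    objective = _residual_objective(pts)
    if refine:
        opt = minimize(
            objective,
            best,
            method="Nelder-Mead",
            options={
                "xatol": 1e-9,
                "fatol": 1e-14,
                "maxiter": 4000,
                "maxfev": 4000,
                "initial_simplex": np.array(
                    [best, best + [coarse_step, 0.0], best + [0.0, coarse_step]]
                ),
            },
        )
        if np.isfinite(opt.fun) and opt.fun <= objective(best):
            best = opt.x
    orientation = PlaneOrientation(*best)
    params = helical_params_at(pts, orientation, literal_pitch=literal_pitch)
    if flat:
        params = dataclasses.replace(params, degenerate=True)
    return GridSearchResult(
        orientation=orientation,
        params=params,
        phi_grid=phis,
        theta_grid=thetas,
        residuals=surface,
        flat_surface=flat,
    )
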