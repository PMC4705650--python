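"""Independent oracle implementations used only by the test suite.

Each oracle deliberately takes a different computational route from the
library code it checks (nonlinear vs algebraic fits, quaternions vs SVD,
brute force vs spatial indexing, closed forms vs quadrature).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist


def geometric_circle_fit(points2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonlinear geometric least-squares circle (minimises radial distances)."""
    pts = np.asarray(points2d, dtype=float)
    x0 = np.concatenate([pts.mean(axis=0), [np.std(pts)]])

    def resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    sol = least_squares(resid, x0, method="lm")
    return sol.x[:2], float(sol.x[2])


def quaternion_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD via the Kearsley quaternion eigenvalue method."""
    p = np.asarray(p, dtype=float) - np.mean(p, axis=0)
    q = np.asarray(q, dtype=float) - np.mean(q, axis=0)
    m = p - q
    s = p + q
    xm, ym, zm = m[:, 0], m[:, 1], m[:, 2]
    xp, yp, zp = s[:, 0], s[:, 1], s[:, 2]
    key = np.empty((4, 4))
    key[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    key[0, 1] = key[1, 0] = np.sum(yp * zm - ym * zp)
    key[0, 2] = key[2, 0] = np.sum(xm * zp - xp * zm)
    key[0, 3] = key[3, 0] = np.sum(xp * ym - xm * yp)
    key[1, 1] = np.sum(yp**2 + zp**2 + xm**2)
    key[1, 2] = key[2, 1] = np.sum(xm * ym - xp * yp)
    key[1, 3] = key[3, 1] = np.sum(xm * zm - xp * zp)
    key[2, 2] = np.sum(xp**2 + zp**2 + ym**2)
    key[2, 3] = key[3, 2] = np.sum(ym * zm - yp * zp)
    key[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    lam = np.linalg.eigvalsh(key)[0]
    return float(np.sqrt(max(lam, 0.0) / len(p)))


def brute_clash_count(a: np.ndarray, b: np.ndarray, dist: float) -> int:
    """All-pairs intermolecular contact count (strict <)."""
    return int(np.count_nonzero(cdist(a, b) < dist))


def two_sphere_contact_area(r1: float, r2: float, d: float, probe: float) -> float:
    """Closed-form buried area of two probe-inflated hard spheres.

    Returns (buried_1 + buried_2) / 2, the analytic analogue of the
    SASA-difference contact area for a two-atom system.
    """
    a, b = r1 + probe, r2 + probe
    if d >= a + b:
        return 0.0
    ca = (d**2 + a**2 - b**2) / (2.0 * d)
    cb = (d**2 + b**2 - a**2) / (2.0 * d)
    buried1 = 2.0 * np.pi * a * (a - ca)
    buried2 = 2.0 * np.pi * b * (b - cb)
    return float((buried1 + buried2) / 2.0)


def pseudoinverse_msf(hessian: np.ndarray) -> np.ndarray:
    """Per-node fluctuations from the Hessian pseudoinverse trace blocks."""
    hinv = np.linalg.pinv(hessian, hermitian=True, rcond=1e-10)
    n = hessian.shape[0] // 3
    diag = np.diag(hinv)
    return diag.reshape(n, 3).sum(axis=1)
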