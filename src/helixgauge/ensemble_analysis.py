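"""PCA of coordinate ensembles and RMSIP subspace overlap."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .enm import ModeSet
from .structure_io import Ensemble, superpose

__all__ = ["PCAResult", "pca", "rmsip"]


@dataclass(frozen=True)
class PCAResult:
    """Principal components of selected-atom coordinate fluctuations.

    Components are orthonormal 3N displacement vectors; variances are sorted
    descending and normalised by the number of frames (population
    covariance).
    """

    mean_coords: np.ndarray  # (N, 3) of the selection
    components: np.ndarray  # (K, 3N)
    variances: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        if len(self.components) != len(self.variances):
            raise ValueError("component/variance count mismatch")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be sorted descending")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for k, comp in enumerate(out):
        i = np.argmax(np.abs(comp))
        if comp[i] < 0:
            out[k] = -comp
    return out


def pca(
    ensemble: Ensemble,
    selection: Optional[np.ndarray] = None,
    n_components: int = 10,
) -> PCAResult:
    """PCA of an ensemble over a selection, after iterative mean alignment.

    Frames are superposed (two passes) onto the evolving mean of the
    selection, then the covariance of the flattened selected coordinates is
    eigendecomposed via SVD.  Requesting more components than ``frames - 1``
    truncates with a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = (
        np.arange(ensemble.frames.shape[1])
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if len(sel) == 0:
        raise ValueError("empty selection")
    frames = ensemble.frames[:, sel, :].copy()
    mean = frames[0].copy()
    for _ in range(2):
        for f in range(len(frames)):
            frames[f], _ = superpose(frames[f], mean)
        mean = frames.mean(axis=0)
    max_k = min(3 * len(sel), ensemble.n_frames - 1)
    if n_components > max_k:
        warnings.warn(
            f"truncating to {max_k} components ({ensemble.n_frames} frames)",
            stacklevel=2,
        )
        n_components = max_k
    x = (frames - mean).reshape(len(frames), -1)
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    variances = svals**2 / len(frames)
    components = _fix_signs(vt[:n_components])
    return PCAResult(
        mean_coords=mean, components=components, variances=variances[:n_components]
    )


def _vectors_of(obj: Union[ModeSet, PCAResult, np.ndarray]) -> np.ndarray:
    if isinstance(obj, ModeSet):
        return obj.eigenvectors
    if isinstance(obj, PCAResult):
        return obj.components
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("mode vectors must form a 2D (K, 3N) array")
    return arr


def rmsip(
    a: Union[ModeSet, PCAResult, np.ndarray],
    b: Union[ModeSet, PCAResult, np.ndarray],
    n: int = 10,
) -> float:
    """Root mean square inner product between the first ``n`` vectors of each set.

    ``RMSIP = sqrt( (1/n) * sum_{i<=n} sum_{j<=n} (a_i . b_j)^2 )``; 1 for
    identical subspaces, 0 for orthogonal ones.
    """
    va, vb = _vectors_of(a), _vectors_of(b)
    if va.shape[1] != vb.shape[1]:
        raise ValueError("mode sets live in different dimensions")
    if len(va) < n or len(vb) < n:
        raise ValueError(f"both sets must provide at least n={n} vectors")
    dots = va[:n] @ vb[:n].T
    return float(np.sqrt(np.sum(dots**2) / n))
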