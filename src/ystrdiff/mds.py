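"""Multidimensional scaling of population distance matrices.

Classical (Torgerson) MDS double-centers the squared dissimilarity matrix,

    B = -1/2 * J D2 J,   J = I - (1/P) 1 1',

and takes the top eigenpairs: coordinates are eigenvectors scaled by the
square root of their (non-negative) eigenvalues.  It reproduces Euclidean
input exactly.  An optional SMACOF pass (iterative majorization via the
Guttman transform) refines the configuration toward minimum raw stress; its
stress sequence is non-increasing by construction.  Misfit is summarized
with Kruskal stress-1:

    stress1 = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 )

Phi_st matrices can carry small negative entries (variance-component
estimates); a dissimilarity cannot, so negatives are clamped to zero at MDS
input by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .gendist import PairwiseDistanceMatrix


@dataclass
class MdsEmbedding:
    """2-D (by default) coordinates per population plus a stress diagnostic."""

    populations: list
    coords: np.ndarray
    stress: float
    method: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding coordinates must be finite")
        if self.stress < 0:
            raise ValidationError("stress must be >= 0")

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.coords, columns=[f"dim{k + 1}" for k in range(self.coords.shape[1])])
        df.insert(0, "population", self.populations)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _as_dissimilarity(dm: PairwiseDistanceMatrix | np.ndarray, clamp_negative: bool) -> np.ndarray:
    d = dm.d if isinstance(dm, PairwiseDistanceMatrix) else np.asarray(dm, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("dissimilarity matrix must be symmetric")
    d = (d + d.T) / 2.0
    if clamp_negative:
        d = np.maximum(d, 0.0)
    elif np.any(d < 0):
        raise ValidationError("negative dissimilarities; pass clamp_negative=True to zero them")
    np.fill_diagonal(d, 0.0)
    return d


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero coordinate of each axis positive."""
    coords = coords.copy()
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


def stress1(coords: np.ndarray, dm: PairwiseDistanceMatrix | np.ndarray,
            clamp_negative: bool = True) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Zero iff the embedding reproduces the dissimilarities exactly; defined
    as 0 for an all-zero matrix.
    """
    d = _as_dissimilarity(dm, clamp_negative)
    coords = np.asarray(coords, float)
    if coords.shape[0] != d.shape[0]:
        raise ValidationError("coordinate and matrix sizes disagree")
    target = squareform(d, checks=False)
    denom = float(np.dot(target, target))
    if denom == 0.0:
        return 0.0
    dhat = pdist(coords)
    resid = dhat - target
    return float(np.sqrt(np.dot(resid, resid) / denom))


def classical_mds(
    dm: PairwiseDistanceMatrix | np.ndarray,
    dims: int = 2,
    clamp_negative: bool = True,
) -> MdsEmbedding:
    """Torgerson classical scaling of a population distance matrix.

    Axes are ordered by decreasing eigenvalue; negative eigenvalues
    (non-Euclidean input) contribute zero coordinates.  The embedding is
    centered at the origin with a fixed sign convention, so output is
    bit-for-bit reproducible.
    """
    d = _as_dissimilarity(dm, clamp_negative)
    p = d.shape[0]
    if dims < 1:
        raise ValidationError("dims must be >= 1")
    j = np.eye(p) - np.full((p, p), 1.0 / p)
    b = -0.5 * j @ (d * d) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    coords = _fix_signs(coords - coords.mean(axis=0))
    pops = dm.populations if isinstance(dm, PairwiseDistanceMatrix) else list(range(p))
    return MdsEmbedding(list(pops), coords, stress1(coords, d), method="classical")


def smacof_refine(
    embedding: MdsEmbedding,
    dm: PairwiseDistanceMatrix | np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-9,
    clamp_negative: bool = True,
) -> MdsEmbedding:
    """Refine an embedding by SMACOF majorization (Guttman transform).

    Raw stress is non-increasing across iterations; stops when the relative
    stress decrease falls below ``tol`` or at ``max_iter``.  Useful when the
    input is far from Euclidean and classical scaling leaves residual
    stress.
    """
    d = _as_dissimilarity(dm, clamp_negative)
    p = d.shape[0]
    x = np.asarray(embedding.coords, float).copy()
    if x.shape[0] != p:
        raise ValidationError("embedding size does not match matrix")
    prev = _raw_stress(x, d)
    for _ in range(max_iter):
        dhat = squareform(pdist(x))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dhat > 0, d / dhat, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / p
        cur = _raw_stress(x, d)
        if prev - cur <= tol * max(prev, 1e-30):
            prev = min(prev, cur)
            break
        prev = cur
    x = _fix_signs(x - x.mean(axis=0))
    return MdsEmbedding(list(embedding.populations), x, stress1(x, d), method="smacof")


def _raw_stress(coords: np.ndarray, d: np.ndarray) -> float:
    resid = pdist(coords) - squareform(d, checks=False)
    return float(np.dot(resid, resid))
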