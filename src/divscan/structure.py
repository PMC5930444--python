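"""Population structure: IBS genomic distance and classical MDS (PCoA).

The genomic distance between two individuals is 1 minus the proportion of
alleles identical by state, averaged over the SNPs where both genotypes are
called: a shared-genotype SNP contributes similarity 1 (IBS2), a
het-vs-hom or hom-vs-het SNP contributes 0.5 (IBS1), opposite homozygotes
contribute 0 (IBS0). Ordination is Torgerson's classical MDS: square the
distances, double-center, eigendecompose, scale eigenvectors by the square
root of their (positive) eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeMatrix

__all__ = ["DistanceMatrix", "MdsResult", "ibs_distance_matrix", "classical_mds"]


@dataclass
class DistanceMatrix:
    samples: list
    values: np.ndarray  # n x n symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.samples):
            raise ValueError("distance matrix shape mismatch")
        self.values = v


@dataclass
class MdsResult:
    coordinates: np.ndarray        # n x k
    eigenvalues: np.ndarray        # all eigenvalues, descending
    explained: np.ndarray          # fraction per retained axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def ibs_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - mean IBS proportion over jointly called SNPs."""
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = G.dosages
    M = (d != MISSING)
    # indicator decomposition: |di - dj| = 1 for {0,1}/{1,2}, 2 for {0,2}
    I0 = ((d == 0)).astype(np.float64)
    I1 = ((d == 1)).astype(np.float64)
    I2 = ((d == 2)).astype(np.float64)
    Mf = M.astype(np.float64)
    n_shared = Mf @ Mf.T
    diff1 = I1 @ (I0 + I2).T + (I0 + I2) @ I1.T
    diff2 = I0 @ I2.T + I2 @ I0.T
    bad = n_shared == 0
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"samples {G.samples[i]!r} and {G.samples[j]!r} share no called SNP")
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (diff1 + 2.0 * diff2) / (2.0 * n_shared)
    dist = np.where(n_shared > 0, dist, 0.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(list(G.samples), dist)


def classical_mds(D: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson/Gower principal-coordinates analysis.

    Retains the top ``k`` axes with strictly positive eigenvalues
    (coordinates = eigenvector * sqrt(eigenvalue)); explained-variance
    fractions are eigenvalue over the sum of positive eigenvalues. The sign
    of each axis is fixed so its first nonzero loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = D.values
    n = dm.shape[0]
    B = dm**2
    B = B - B.mean(axis=0)[None, :] - B.mean(axis=1)[:, None] + B.mean()
    B *= -0.5
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(vals[0]), 1.0) if n else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes instead of {k}")
    k_eff = min(k, n_pos)
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for a in range(k_eff):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, a] = -col
    denom = vals[pos].sum()
    explained = vals[:k_eff] / denom if denom > 0 else np.zeros(k_eff)
    return MdsResult(coordinates=coords, eigenvalues=vals, explained=explained)
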