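"""Community summaries, Bray-Curtis dissimilarity and PCoA.

Per-site richness and total standardized abundance are the scalar
responses; species composition enters downstream regressions through the
first axis of a principal coordinates analysis (metric multidimensional
scaling) of the pairwise Bray-Curtis dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effort import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "richness",
    "total_abundance",
    "bray_curtis",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    site_ids: list
    values: np.ndarray
    #: index pairs (i, j) where both sites were empty and d := 0 by convention
    flagged_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)


@dataclass
class Ordination:
    """PCoA embedding: site coordinates and the eigenvalue spectrum."""

    site_ids: list
    coordinates: np.ndarray  # sites x axes
    eigenvalues: np.ndarray  # per axis, descending
    negative_eigenvalue_mass: float

    def axis(self, k: int = 1) -> pd.Series:
        """Per-site scores on axis ``k`` (1-based)."""
        return pd.Series(self.coordinates[:, k - 1], index=self.site_ids,
                         name=f"pcoa{k}")


def richness(matrix: CommunityMatrix) -> pd.Series:
    """Observed species count (cells > 0) per site."""
    return (matrix.data > 0).sum(axis=1).rename("richness")


def total_abundance(matrix: CommunityMatrix, log_transform: bool = False) -> pd.Series:
    """Per-site summed standardized abundance, optionally log10.

    With ``log_transform``, empty sites (total 0) come back NaN —
    flagged undefined rather than -inf.
    """
    totals = matrix.data.sum(axis=1)
    if not log_transform:
        return totals.rename("abundance")
    with np.errstate(divide="ignore"):
        out = np.where(totals > 0, np.log10(np.where(totals > 0, totals, 1.0)), np.nan)
    return pd.Series(out, index=totals.index, name="log10_abundance")


def bray_curtis(matrix: CommunityMatrix) -> DistanceMatrix:
    """Quantitative Bray-Curtis dissimilarity between all site pairs.

    d_jk = sum_s |a_sj - a_sk| / sum_s (a_sj + a_sk), in [0, 1].
    A pair of two empty sites has an undefined ratio; it is returned as
    0 and listed in ``flagged_pairs``.
    """
    a = matrix.data.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    diff = np.abs(a[:, None, :] - a[None, :, :]).sum(axis=2)
    tot = (a[:, None, :] + a[None, :, :]).sum(axis=2)
    flagged = []
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    empty = a.sum(axis=1) == 0
    for i in np.flatnonzero(empty):
        for j in np.flatnonzero(empty):
            if i < j:
                flagged.append((int(i), int(j)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(site_ids=list(matrix.data.index), values=d,
                          flagged_pairs=flagged)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J with J = I - 11'/n; symmetric eigendecomposition;
    coordinates = eigenvector * sqrt(max(eigenvalue, 0)). Axes are
    ordered by descending eigenvalue and at most n - 1 are kept. No
    negative-eigenvalue correction is applied; the summed magnitude of
    negative eigenvalues is reported instead so metric distortion of the
    input dissimilarity is visible.

    Sign convention: each eigenvector is oriented so that its
    largest-magnitude loading is positive (first such index on ties),
    which makes the output deterministic across platforms. Downstream
    regression coefficients on PCoA axes depend on this orientation.
    """
    D = np.asarray(d.values, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two sites")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic orientation
    for k in range(n):
        i = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[i, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    n_axes = n - 1
    coords = eigvec[:, :n_axes] * np.sqrt(np.maximum(eigval[:n_axes], 0.0))
    neg_mass = float(np.abs(eigval[eigval < 0]).sum())
    return Ordination(site_ids=list(d.site_ids), coordinates=coords,
                      eigenvalues=eigval[:n_axes],
                      negative_eigenvalue_mass=neg_mass)
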