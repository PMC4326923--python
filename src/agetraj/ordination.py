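"""Classical (Torgerson) multidimensional scaling of samples.

Sample-to-sample distances (Euclidean on log-scale expression by
convention) are doubly centered, B = -1/2 * J D^2 J, and the top
eigenpairs of B give the embedding. Axes are ordered by eigenvalue and
sign-fixed so the first nonzero coordinate of each axis is positive. Per-age
centroids and a confidence radius (a quantile of within-group distances to
the centroid) summarize group separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import NormalizedMatrix, SampleSheet

__all__ = ["MDSEmbedding", "classical_mds", "mds_of_samples", "group_centroids"]


@dataclass
class MDSEmbedding:
    coordinates: pd.DataFrame  # samples x dims
    eigenvalues: np.ndarray  # all eigenvalues of B, descending


def classical_mds(distances, dims: int = 2, sample_ids=None) -> MDSEmbedding:
    """Torgerson scaling of a symmetric zero-diagonal distance matrix."""
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    if dims < 1 or dims > n - 1:
        raise ValueError("dims must be in [1, n-1]")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    for i in range(dims):
        lam = vals[i]
        if lam > 0:
            axis = vecs[:, i] * np.sqrt(lam)
            nz = np.nonzero(np.abs(axis) > 1e-12)[0]
            if nz.size and axis[nz[0]] < 0:
                axis = -axis
            coords[:, i] = axis
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(coords, index=list(sample_ids), columns=[f"dim{i+1}" for i in range(dims)])
    return MDSEmbedding(coordinates=df, eigenvalues=vals)


def mds_of_samples(matrix: NormalizedMatrix, dims: int = 2) -> MDSEmbedding:
    """Classical MDS of samples with Euclidean distances over all genes."""
    x = matrix.values.to_numpy(float).T  # samples x genes
    d = squareform(pdist(x, metric="euclidean"))
    return classical_mds(d, dims=dims, sample_ids=matrix.sample_ids)


def group_centroids(
    embedding: MDSEmbedding, sheet: SampleSheet, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-age centroid coordinates and confidence radius.

    The radius is the ``confidence`` quantile of within-group distances to
    the centroid; it is NaN (flagged) for singleton groups.
    """
    coords = embedding.coordinates
    rows = []
    for age in sheet.ages:
        ids = [s for s in sheet.samples_at(age) if s in coords.index]
        pts = coords.loc[ids].to_numpy()
        centroid = pts.mean(axis=0)
        if len(ids) >= 2:
            dist = np.linalg.norm(pts - centroid, axis=1)
            radius = float(np.quantile(dist, confidence))
        else:
            radius = float("nan")
        row = {"age_weeks": age, "n_samples": len(ids), "radius": radius}
        for i, c in enumerate(coords.columns):
            row[c] = centroid[i]
        rows.append(row)
    return pd.DataFrame(rows).set_index("age_weeks")
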