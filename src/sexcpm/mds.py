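"""Sample-level multidimensional scaling on leading log-fold-change distances.

The distance between two samples is the root-mean-square of the ``top``
largest absolute log2 expression differences across genes, with the gene
subset chosen independently for every pair ("pairwise" leading logFC).
Log expression is log2(CPM + pseudocount) with a library-size-scaled
pseudocount, so low-count genes do not dominate the ratios.  The embedding
is classical (Torgerson) MDS: double-center the squared distances,
eigendecompose, scale eigenvectors by the square roots of the eigenvalues.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import ConsistencyError, CpmMatrix, DistanceMatrix, Embedding


def log_expression(cpm: CpmMatrix, prior: float = 2.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), pseudocount = prior / library_size × 1e6 per sample.

    When the matrix carries no library sizes (pre-computed CPM input), the
    pseudocount falls back to ``prior`` CPM, i.e. a nominal million-read
    library.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    if cpm.library_sizes is not None:
        pseudo = prior / cpm.library_sizes.to_numpy(dtype=float) * 1e6
    else:
        pseudo = np.full(cpm.cpm.shape[1], float(prior))
    return np.log2(cpm.cpm + pseudo[np.newaxis, :])


def leading_logfc_distance(cpm: CpmMatrix, top: int = 500, prior: float = 2.0) -> DistanceMatrix:
    """Pairwise leading-logFC distances between samples.

    For each sample pair: RMS of the ``top`` largest |log2FC| over genes
    (all genes if fewer than ``top`` exist).
    """
    n = cpm.cpm.shape[1]
    if n < 2:
        raise ConsistencyError("need at least 2 samples for a distance matrix")
    if top < 1:
        raise ValueError("top must be >= 1")
    logx = log_expression(cpm, prior).to_numpy(dtype=float)
    k = min(top, logx.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(logx[:, i] - logx[:, j])
            if k < diff.size:
                leading = np.partition(diff, diff.size - k)[-k:]
            else:
                leading = diff
            d[i, j] = d[j, i] = np.sqrt(np.mean(leading**2))
    ids = cpm.cpm.columns
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


def classical_mds(dist: DistanceMatrix, k: int = 2) -> Embedding:
    """Torgerson scaling of a distance matrix into ``k`` dimensions.

    Negative eigenvalues (non-Euclidean input) are clamped to zero with a
    warning.  Axis signs are arbitrary; coordinates are mean-centered by
    construction.
    """
    d = dist.d.to_numpy(dtype=float)
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1][:k]
    lam = eigvals[order]
    if (eigvals < -1e-9 * max(1.0, float(np.abs(eigvals).max()))).any():
        warnings.warn(
            "distance matrix is not Euclidean; clamping negative eigenvalues to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    lam_clamped = np.clip(lam, 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam_clamped)[np.newaxis, :]
    frame = pd.DataFrame(
        coords,
        index=dist.d.index,
        columns=[f"dim{i + 1}" for i in range(k)],
    )
    return Embedding(coordinates=frame, eigenvalues=lam_clamped)


def write_embedding(embedding: Embedding, path: str) -> None:
    """Write coordinates TSV with eigenvalues in '#'-prefixed header comments."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.6g}" for v in embedding.eigenvalues) + "\n")
        fh.write("sample_id\t" + "\t".join(embedding.coordinates.columns) + "\n")
        for sid, row in embedding.coordinates.iterrows():
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
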