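"""Dimension-reduction methods for sparse single-cell epigenomic counts.

The methods compared here are the classical linear family used for
scATAC-seq and scHPTM analysis:

* CPM-PCA — log1p counts-per-million followed by PCA (baseline);
* LSI — TF-IDF transform followed by truncated SVD, either weighting
  components by their singular values ("eigen", ChromSCape-style) or
  whitening them to unit variance (Signac-style);
* Jaccard kernel PCA — kernel PCA on the (optionally observed-over-expected
  normalised) cell-cell Jaccard similarity of binarised profiles
  (SnapATAC-style);
* NMF on raw or TF-IDF-transformed counts.

A deterministic reference-modality embedding (depth-normalised, log1p, HVG,
scaled PCA) turns paired RNA counts into the reference representation that
the neighbor score compares against.

All scHPTM presets drop the first principal component (it typically tracks
per-cell coverage rather than cell identity); the reference embedding keeps
it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .binning import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "TfidfParams",
    "SvdParams",
    "cpm_lognorm",
    "tfidf",
    "svd_embed",
    "embed_cpm_pca",
    "embed_lsi_eigen",
    "embed_lsi_whitened",
    "jaccard_kpca",
    "nmf_embed",
    "reference_embed",
]


@dataclass
class Embedding:
    """Dense cells x dims representation with aligned barcodes."""

    coords: np.ndarray
    barcodes: np.ndarray
    method_name: str
    params_used: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if len(self.barcodes) != self.coords.shape[0]:
            raise ValueError("barcodes do not match coords rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class TfidfParams:
    scale_factor: float = 1e4
    log_transform: bool = True

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


@dataclass(frozen=True)
class SvdParams:
    n_components: int = 10
    weighting: str = "eigen"  # "eigen" | "whitened"
    drop_first: bool = True

    def __post_init__(self):
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.weighting not in ("eigen", "whitened"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


def _as_csr(matrix) -> sp.csr_matrix:
    if isinstance(matrix, CountMatrix):
        return matrix.counts.tocsr()
    return sp.csr_matrix(matrix)


def cpm_lognorm(matrix) -> sp.csr_matrix:
    """log(1 + CPM): y_ij = log(1 + 1e6 * x_ij / sum_j x_ij).

    Zero entries map to zero, so sparsity is preserved.  Zero-coverage rows
    are an error — they should have been removed at matrix load.
    """
    X = _as_csr(matrix).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty matrix")
    if np.any(totals == 0):
        raise ValueError("zero-coverage cells present; remove them before normalisation")
    Y = X.multiply(1e6 / totals[:, None]).tocsr()
    Y.data = np.log1p(Y.data)
    return Y


def tfidf(matrix, params: TfidfParams = TfidfParams()) -> sp.csr_matrix:
    """TF-IDF transform of a cell x region count matrix.

    TF_ij = x_ij / sum_j x_ij, IDF_j = n_cells / df_j with df_j the number of
    cells where region j is nonzero; output log(1 + scale * TF * IDF) (or the
    linear form when ``log_transform`` is off).  Regions observed in no cell
    (df = 0) are dropped with a log message.
    """
    X = _as_csr(matrix).astype(np.float64)
    if X.shape[0] == 0 or X.shape[1] == 0 or X.nnz == 0:
        raise ValueError("empty matrix")
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-coverage cells present; remove them before TF-IDF")
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    if np.any(df == 0):
        logger.info("tfidf: dropping %d all-zero regions", int((df == 0).sum()))
        keep = np.flatnonzero(df > 0)
        X = X[:, keep]
        df = df[keep]
    tf = X.multiply(1.0 / totals[:, None]).tocsr()
    out = tf.multiply(params.scale_factor * X.shape[0] / df[None, :]).tocsr()
    if params.log_transform:
        out.data = np.log1p(out.data)
    return out


def _stable_sign_flip(U: np.ndarray) -> np.ndarray:
    """Fix component signs: the largest-|value| entry of each column is made
    positive (first index on ties), for run-to-run determinism."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs[None, :]


def _centered_svd(X, k: int):
    """Top-k singular triplets of the column-centered matrix.

    The centering is implicit (LinearOperator) so sparse inputs stay sparse;
    small problems fall back to a dense exact SVD.
    """
    n, p = X.shape
    mu = np.asarray(X.mean(axis=0)).ravel()
    if min(n, p) <= 300 or k >= min(n, p) - 1:
        Xc = (X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)) - mu[None, :]
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        return U[:, :k], s[:k], Vt[:k]

    def matvec(v):
        v = np.ravel(v)
        return np.asarray(X @ v).ravel() - float(mu @ v)

    def rmatvec(u):
        u = np.ravel(u)
        return np.asarray(X.T @ u).ravel() - mu * float(u.sum())

    op = sp.linalg.LinearOperator((n, p), matvec=matvec, rmatvec=rmatvec, dtype=np.float64)
    v0 = np.full(min(n, p), 1.0 / np.sqrt(min(n, p)))
    U, s, Vt = sp.linalg.svds(op, k=k, v0=v0)
    order = np.argsort(-s)
    return U[:, order], s[order], Vt[order]


def svd_embed(matrix, params: SvdParams, barcodes=None, method_name: str = "svd",
              strict_rank: bool = True) -> Embedding:
    """Truncated SVD of the column-centered matrix.

    ``eigen`` weighting returns U*S (PCA scores, components weighted by their
    singular values); ``whitened`` returns U*sqrt(n-1), so every component
    has unit sample variance.  With ``drop_first`` the first component is
    computed and discarded, leaving ``n_components`` columns from components
    2..n_components+1.
    """
    X = _as_csr(matrix) if not isinstance(matrix, np.ndarray) else matrix
    if isinstance(matrix, CountMatrix):
        if barcodes is None:
            barcodes = matrix.barcodes
        X = matrix.counts
    n, p = X.shape
    if barcodes is None:
        barcodes = np.array([f"cell_{i}" for i in range(n)], dtype=object)
    k = params.n_components + (1 if params.drop_first else 0)
    if k + 1 > min(n, p):
        raise ValueError(
            f"n_components={params.n_components} (+drop_first) needs min(n_cells, n_regions) "
            f">= {k + 1}, got {min(n, p)}"
        )
    U, s, _ = _centered_svd(X, k)
    tol = max(n, p) * np.finfo(np.float64).eps * (s[0] if len(s) else 0.0)
    rank = int((s > tol).sum())
    if rank < k:
        if strict_rank:
            raise ValueError(f"requested {k} components but achievable rank is {rank}")
        k = rank
        U, s = U[:, :k], s[:k]
    U = _stable_sign_flip(U)
    if params.weighting == "eigen":
        coords = U * s[None, :]
    else:
        coords = U * np.sqrt(n - 1)
    if params.drop_first and coords.shape[1] > 0:
        coords = coords[:, 1:]
    return Embedding(
        coords,
        barcodes,
        method_name,
        {"n_components": params.n_components, "weighting": params.weighting,
         "drop_first": params.drop_first},
    )


def embed_cpm_pca(matrix: CountMatrix, dim: int = 10) -> Embedding:
    """CPM-PCA baseline: log1p CPM, PCA, first component dropped."""
    Y = cpm_lognorm(matrix)
    return svd_embed(Y, SvdParams(dim, "eigen", drop_first=True), matrix.barcodes, "cpm_pca")


def embed_lsi_eigen(matrix: CountMatrix, dim: int = 10,
                    tfidf_params: TfidfParams = TfidfParams()) -> Embedding:
    """Eigenvalue-weighted LSI: TF-IDF, PCA scores U*S, first component dropped."""
    Y = tfidf(matrix, tfidf_params)
    return svd_embed(Y, SvdParams(dim, "eigen", drop_first=True), matrix.barcodes, "lsi_eigen")


def embed_lsi_whitened(matrix: CountMatrix, dim: int = 50,
                       tfidf_params: TfidfParams = TfidfParams()) -> Embedding:
    """Whitened LSI: TF-IDF, unit-variance components, first dropped."""
    Y = tfidf(matrix, tfidf_params)
    return svd_embed(Y, SvdParams(dim, "whitened", drop_first=True), matrix.barcodes, "lsi_whitened")


def jaccard_kpca(matrix: CountMatrix, dim: int = 10, normalize_ove: bool = True) -> Embedding:
    """Kernel PCA on the cell-cell Jaccard similarity of binarised profiles.

    With ``normalize_ove`` the similarity is divided by its expectation under
    independent per-cell detection rates, E_ab = p_a p_b / (p_a + p_b -
    p_a p_b); the kernel is then double-centered and eigendecomposed, and the
    embedding is the top-``dim`` eigenvectors scaled by sqrt of the
    (nonnegative-clipped) eigenvalues.
    """
    X = matrix.counts
    n, p = X.shape
    if n < dim + 1:
        raise ValueError("need at least dim + 1 cells")
    B = (X > 0).astype(np.float64)
    sizes = np.asarray(B.sum(axis=1)).ravel()
    if np.any(sizes == 0):
        raise ValueError("cells with empty binary profile; remove zero-coverage cells first")
    inter = np.asarray((B @ B.T).todense())
    union = sizes[:, None] + sizes[None, :] - inter
    J = inter / union
    if normalize_ove:
        pr = sizes / p
        expected = pr[:, None] * pr[None, :] / (pr[:, None] + pr[None, :] - pr[:, None] * pr[None, :])
        J = J / expected
    # double-center the kernel
    rowm = J.mean(axis=1, keepdims=True)
    K = J - rowm - rowm.T + J.mean()
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > max(n * np.finfo(np.float64).eps * abs(vals[0]), 0.0)).sum())
    if dim > n_pos:
        raise ValueError(f"requested dim {dim} exceeds {n_pos} positive kernel eigenvalues")
    vecs = _stable_sign_flip(vecs[:, :dim])
    coords = vecs * np.sqrt(np.clip(vals[:dim], 0.0, None))[None, :]
    return Embedding(coords, matrix.barcodes, "jaccard_kpca",
                     {"dim": dim, "normalize_ove": normalize_ove})


def nmf_embed(matrix: CountMatrix, dim: int = 10, tfidf_first: bool = False,
              seed: int = 0, max_iter: int = 200, tol: float = 1e-4) -> Embedding:
    """Nonnegative matrix factorisation X ~ W.H (Frobenius loss).

    Coordinate descent from a nonnegative-double-SVD initialisation whose
    zeros are filled with small seeded noise; the embedding is the rows of W.
    A run that has not converged within ``max_iter`` returns the best iterate
    with ``converged: False`` recorded in the params.
    """
    X = tfidf(matrix) if tfidf_first else matrix.counts.astype(np.float64)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        model = NMF(n_components=dim, init="nndsvdar", solver="cd", max_iter=max_iter,
                    tol=tol, random_state=seed)
        try:
            W = model.fit_transform(X)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = NMF(n_components=dim, init="nndsvdar", solver="cd", max_iter=max_iter,
                            tol=tol, random_state=seed)
                W = model.fit_transform(X)
    name = "tfidf_nmf" if tfidf_first else "nmf"
    return Embedding(W, matrix.barcodes, name,
                     {"dim": dim, "tfidf_first": tfidf_first, "seed": seed,
                      "n_iter": int(model.n_iter_), "converged": converged,
                      "frobenius_error": float(model.reconstruction_err_)})


def reference_embed(rna_counts, barcodes, dim: int = 50, n_hvg: int = 2000) -> Embedding:
    """Deterministic reference embedding of the co-assay modality.

    Standard scRNA-seq-style pipeline: depth-normalise each cell to 1e4
    counts, log1p, keep the ``n_hvg`` most variable genes (variance
    standardised against the mean-variance trend), center and unit-scale
    genes with values clipped at 10, then PCA scores (no component dropped).
    The output dimension is min(dim, achievable rank).
    """
    from .qc import hvg_scores  # late import: qc depends on this module's sibling types

    X = sp.csr_matrix(rna_counts).astype(np.float64)
    n, g = X.shape
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-depth cells in the reference modality")
    Y = X.multiply(1e4 / totals[:, None]).tocsr()
    Y.data = np.log1p(Y.data)
    if n_hvg < g:
        scores = hvg_scores(X)
        order = np.argsort(-scores, kind="stable")
        keep = np.sort(order[:n_hvg])
        Y = Y[:, keep]
    D = Y.toarray()
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.minimum((D - mean) / sd, 10.0)
    dim_eff = min(dim, min(Z.shape) - 2)
    emb = svd_embed(Z, SvdParams(dim_eff, "eigen", drop_first=False),
                    np.asarray(barcodes, dtype=object), "reference", strict_rank=False)
    emb.params_used.update({"n_hvg": min(n_hvg, g), "requested_dim": dim})
    return emb
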