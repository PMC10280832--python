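"""In-silico experimental-condition perturbations of a count matrix.

The benchmark probes how common QC choices change embedding quality by
modifying a real (or simulated) matrix: keeping only the best-covered cells,
selecting features by variability or coverage, and randomly downsampling the
number of cells.  Every perturbation returns the modified matrix together
with a :class:`PerturbationRecord` for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import CountMatrix

__all__ = [
    "PerturbationRecord",
    "filter_cells_by_coverage",
    "select_features_hvg",
    "select_features_top",
    "downsample_cells",
    "hvg_scores",
    "DEFAULT_COVERAGE_FRACTIONS",
    "DEFAULT_FEATURE_FRACTIONS",
]

# default sweep grids: 7 coverage conditions and 7 feature-selection conditions
DEFAULT_COVERAGE_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4)
DEFAULT_FEATURE_FRACTIONS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05)


@dataclass(frozen=True)
class PerturbationRecord:
    kind: str  # cell_coverage | feature_hvg | feature_top | downsample
    parameter: float
    n_before: int
    n_after: int
    seed: int | None = None

    def __post_init__(self):
        if self.n_after > self.n_before:
            raise ValueError("n_after cannot exceed n_before")


def filter_cells_by_coverage(matrix: CountMatrix, keep_fraction: float):
    """Keep the ``ceil(keep_fraction * n_cells)`` best-covered cells.

    Cells are ranked by total count; ties are broken by lexicographic
    barcode order.  Retained rows keep their original matrix order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    n_keep = math.ceil(keep_fraction * matrix.n_cells)
    totals = matrix.row_sums()
    # sort by (-total, barcode); lexsort keys are last-key-major
    order = np.lexsort((matrix.barcodes.astype(str), -totals))
    keep = np.sort(order[:n_keep])
    rec = PerturbationRecord("cell_coverage", keep_fraction, matrix.n_cells, n_keep)
    return matrix.subset_cells(keep), rec


def hvg_scores(X) -> np.ndarray:
    """Variance-stabilised variability score per feature (column).

    Per feature: raw mean m_j and sample variance v_j; a lowess fit (span
    0.3) of log10 v on log10 m over features with v_j > 0 gives the expected
    standard deviation s_hat_j = sqrt(10^fit); entries are standardised as
    z_ij = min((x_ij - m_j) / s_hat_j, sqrt(n_cells)) and the score is the
    sample variance of the z column.  Constant features score 0.  With fewer
    than 20 distinct means the trend fit degenerates to the global mean of
    log10 v (degree-0 fallback).
    """
    X = sp.csr_matrix(X).astype(np.float64)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 cells")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    var = np.clip(var, 0.0, None)
    variable = var > 0
    if not variable.any():
        raise ValueError("no variable features")
    lm = np.log10(mean[variable])
    lv = np.log10(var[variable])
    if len(np.unique(lm)) < 20:
        fit = np.full(variable.sum(), lv.mean())
    else:
        fit = lowess(lv, lm, frac=0.3, return_sorted=False)
    expected_sd = np.ones(p)
    expected_sd[variable] = np.sqrt(10.0**fit)
    clip = np.sqrt(n)

    scores = np.zeros(p)
    Xc = X.tocsc()
    block = 4096
    for lo in range(0, p, block):
        hi = min(lo + block, p)
        dense = Xc[:, lo:hi].toarray()
        z = np.minimum((dense - mean[lo:hi][None, :]) / expected_sd[lo:hi][None, :], clip)
        scores[lo:hi] = z.var(axis=0, ddof=1)
    scores[~variable] = 0.0
    return scores


def select_features_hvg(matrix: CountMatrix, n_keep: int):
    """Keep the ``n_keep`` most variable regions (variance-stabilised rank).

    Ties rank the lower region index first; the surviving columns keep their
    original order.
    """
    if not 1 <= n_keep <= matrix.n_regions:
        raise ValueError("n_keep must be in [1, n_regions]")
    scores = hvg_scores(matrix.counts)
    order = np.argsort(-scores, kind="stable")  # stable: lower index wins ties
    keep = np.sort(order[:n_keep])
    rec = PerturbationRecord("feature_hvg", n_keep, matrix.n_regions, n_keep)
    return matrix.subset_regions(keep, _subscheme(matrix, keep)), rec


def select_features_top(matrix: CountMatrix, n_keep: int):
    """Keep the ``n_keep`` highest-coverage regions (column-sum rank)."""
    if not 1 <= n_keep <= matrix.n_regions:
        raise ValueError("n_keep must be in [1, n_regions]")
    totals = matrix.col_sums()
    order = np.argsort(-totals, kind="stable")
    keep = np.sort(order[:n_keep])
    rec = PerturbationRecord("feature_top", n_keep, matrix.n_regions, n_keep)
    return matrix.subset_regions(keep, _subscheme(matrix, keep)), rec


def downsample_cells(matrix: CountMatrix, n: int, seed: int):
    """Uniform sample of ``n`` distinct cells, deterministic given ``seed``.

    Retained rows keep the original matrix order.
    """
    if not 1 <= n <= matrix.n_cells:
        raise ValueError("n must be in [1, n_cells]")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(matrix.n_cells, size=n, replace=False))
    rec = PerturbationRecord("downsample", n, matrix.n_cells, n, seed=seed)
    return matrix.subset_cells(keep), rec


def _subscheme(matrix: CountMatrix, keep: np.ndarray):
    """Column subset of a bin scheme; a proper subset is no longer a tiling,
    so the result is of annotation kind."""
    from .binning import BinScheme

    s = matrix.scheme
    if len(keep) == s.n_regions:
        return s
    return BinScheme(s.chroms[keep], s.starts[keep], s.ends[keep],
                     s.region_ids[keep], "annotation", s.layout)
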