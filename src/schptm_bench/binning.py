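"""Genome binning and cell x region count-matrix construction.

Single-cell histone-PTM assays (scCUT&Tag, scChIP-seq) produce per-cell
fragment records rather than a feature matrix.  The first analysis step is to
summarise fragments into a cell x region count matrix, where the regions are
either fixed-size genomic tiles or intervals taken from an annotation (gene /
TSS sets, pseudobulk peak calls).  This module provides the genome layout and
bin-scheme containers, fragment counting, and re-binning of a fine matrix to
coarser resolutions.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Fixed-size bins tile each chromosome from position 0; the
last bin of a chromosome is truncated at the chromosome end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "BinScheme",
    "FragmentSet",
    "CountMatrix",
    "make_fixed_bins",
    "load_annotation_bins",
    "count_fragments",
    "merge_bins",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with their lengths in base pairs."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        names = tuple(str(n) for n in self.chrom_names)
        lengths = tuple(int(l) for l in self.chrom_lengths)
        if len(names) == 0:
            raise ValueError("empty genome layout")
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in lengths):
            raise ValueError("every chromosome length must be > 0")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @classmethod
    def from_dict(cls, lengths: dict) -> "GenomeLayout":
        return cls(tuple(lengths.keys()), tuple(lengths.values()))

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class BinScheme:
    """Ordered genomic intervals defining the columns of a count matrix.

    ``kind`` is ``"fixed"`` (genome tiling at ``bin_size_bp``) or
    ``"annotation"`` (intervals from a BED source, kept as given, possibly
    overlapping).  Regions are sorted by (chromosome in layout order, start).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    region_ids: np.ndarray
    kind: str
    layout: GenomeLayout
    bin_size_bp: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        object.__setattr__(self, "region_ids", np.asarray(self.region_ids, dtype=object))
        if self.kind not in ("fixed", "annotation"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.n_regions == 0:
            raise ValueError("no regions")
        if np.any(self.starts < 0) or np.any(self.starts >= self.ends):
            raise ValueError("regions must satisfy 0 <= start < end")
        if len(set(self.region_ids)) != self.n_regions:
            raise ValueError("region_ids must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "region_id": self.region_ids,
            }
        )

    def _chrom_slices(self) -> dict:
        """Contiguous index slice per chromosome (regions are chrom-sorted)."""
        out = {}
        chroms = self.chroms
        i = 0
        n = len(chroms)
        while i < n:
            j = i
            while j < n and chroms[j] == chroms[i]:
                j += 1
            out[chroms[i]] = (i, j)
            i = j
        return out

    def assign(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Map genomic positions to region indices (-1 when uncovered).

        A position falling in several overlapping annotation regions is
        assigned to the first containing region in scheme order.
        """
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), -1, dtype=np.int64)
        slices = self._chrom_slices()
        if self.kind == "fixed":
            B = int(self.bin_size_bp)
            lengths = self.layout.lengths
            for chrom, (lo, hi) in slices.items():
                mask = chroms == chrom
                if not mask.any():
                    continue
                pos = positions[mask]
                idx = lo + pos // B
                valid = (pos >= 0) & (pos < lengths[chrom]) & (idx < hi)
                res = np.where(valid, idx, -1)
                out[mask] = res
            return out
        for chrom, (lo, hi) in slices.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            pos = positions[mask]
            starts = self.starts[lo:hi]
            ends = self.ends[lo:hi]
            # last region with start <= pos
            cand = np.searchsorted(starts, pos, side="right") - 1
            # first region with end > pos: binary search on the running max
            # of ends, which is non-decreasing
            prefix_max_end = np.maximum.accumulate(ends)
            first = np.searchsorted(prefix_max_end, pos, side="right")
            hit = (cand >= 0) & (first <= cand)
            out[mask] = np.where(hit, lo + first, -1)
        return out


@dataclass(frozen=True)
class FragmentSet:
    """Per-cell sequenced fragment records (10x-style fragments file)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    barcodes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        object.__setattr__(self, "barcodes", np.asarray(self.barcodes, dtype=object))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        n = len(self.chroms)
        for arr in (self.starts, self.ends, self.barcodes, self.counts):
            if len(arr) != n:
                raise ValueError("fragment columns differ in length")
        if n and np.any(self.starts >= self.ends):
            raise ValueError("fragments must satisfy start < end")
        if n and np.any(self.counts < 1):
            raise ValueError("fragment counts must be >= 1")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FragmentSet":
        counts = df["count"].to_numpy() if "count" in df else np.ones(len(df), dtype=np.int64)
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            df["barcode"].to_numpy(dtype=object),
            counts,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "barcode": self.barcodes,
                "count": self.counts,
            }
        )


@dataclass
class CountMatrix:
    """Sparse nonnegative cell x region integer count matrix.

    The central exchange object of the pipeline: rows are cells (identified
    by unique barcodes), columns are the regions of a :class:`BinScheme`, in
    scheme order.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    scheme: BinScheme

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape[0] != len(self.barcodes):
            raise ValueError("row count does not match number of barcodes")
        if self.counts.shape[1] != self.scheme.n_regions:
            raise ValueError("column count does not match scheme")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def col_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, indices: np.ndarray) -> "CountMatrix":
        indices = np.asarray(indices)
        return CountMatrix(self.counts[indices], self.barcodes[indices], self.scheme)

    def subset_regions(self, indices: np.ndarray, scheme: BinScheme | None = None) -> "CountMatrix":
        indices = np.asarray(indices)
        if scheme is None:
            scheme = BinScheme(
                self.scheme.chroms[indices],
                self.scheme.starts[indices],
                self.scheme.ends[indices],
                self.scheme.region_ids[indices],
                "annotation",
                self.scheme.layout,
            )
        return CountMatrix(self.counts[:, indices], self.barcodes, scheme)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.barcodes.copy(), self.scheme)


def make_fixed_bins(layout: GenomeLayout, bin_size_bp: int) -> BinScheme:
    """Tile every chromosome with fixed-size bins of ``bin_size_bp``.

    Per chromosome of length L, emits ``ceil(L / B)`` half-open tiles
    ``[i*B, min((i+1)*B, L))``; the last tile is truncated at the chromosome
    end.
    """
    bin_size_bp = int(bin_size_bp)
    if bin_size_bp < 1:
        raise ValueError("bin_size_bp must be >= 1")
    chroms, starts, ends, ids = [], [], [], []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_bins = -(-length // bin_size_bp)
        s = np.arange(n_bins, dtype=np.int64) * bin_size_bp
        e = np.minimum(s + bin_size_bp, length)
        chroms.extend([chrom] * n_bins)
        starts.append(s)
        ends.append(e)
        ids.extend(f"{chrom}:{a}-{b}" for a, b in zip(s, e))
    return BinScheme(
        np.array(chroms, dtype=object),
        np.concatenate(starts),
        np.concatenate(ends),
        np.array(ids, dtype=object),
        "fixed",
        layout,
        bin_size_bp,
    )


# default fixed-size sweep grid, kbp, spanning the 5 kbp - 1 Mbp log range
DEFAULT_BIN_SIZES_BP = (5_000, 10_000, 20_000, 50_000, 100_000, 200_000, 500_000, 1_000_000)


def load_annotation_bins(bed_source, layout: GenomeLayout) -> BinScheme:
    """Build an annotation bin scheme from a BED3+ source (path or stream).

    Intervals are kept as given (overlaps are not merged) and sorted by
    (chromosome in layout order, start, end).  An interval extending beyond
    its chromosome end is an error naming the offending record.
    """
    try:
        df = pd.read_csv(bed_source, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError("no regions in BED source") from None
    if df.empty:
        raise ValueError("no regions in BED source")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["chrom"] = df["chrom"].astype(str)
    lengths = layout.lengths
    for rec in df.itertuples(index=False):
        if rec.chrom not in lengths:
            raise ValueError(f"BED record on unknown chromosome: {rec.chrom}:{rec.start}-{rec.end}")
        if rec.start < 0 or rec.start >= rec.end:
            raise ValueError(f"invalid BED interval: {rec.chrom}:{rec.start}-{rec.end}")
        if rec.end > lengths[rec.chrom]:
            raise ValueError(
                f"BED record beyond chromosome end: {rec.chrom}:{rec.start}-{rec.end} "
                f"(length {lengths[rec.chrom]})"
            )
    chrom_rank = {c: i for i, c in enumerate(layout.chrom_names)}
    df = df.sort_values(
        by=["chrom", "start", "end"],
        key=lambda col: col.map(chrom_rank) if col.name == "chrom" else col,
        kind="stable",
    ).reset_index(drop=True)
    ids = [f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    # identical intervals repeated in the BED get a disambiguating suffix
    seen: dict = {}
    for i, rid in enumerate(ids):
        if rid in seen:
            seen[rid] += 1
            ids[i] = f"{rid}.{seen[rid]}"
        else:
            seen[rid] = 0
    return BinScheme(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        np.array(ids, dtype=object),
        "annotation",
        layout,
    )


def count_fragments(
    fragments: FragmentSet,
    scheme: BinScheme,
    barcodes: Sequence | None = None,
) -> CountMatrix:
    """Count fragments into the regions of ``scheme``.

    Each fragment is assigned to exactly one region by its midpoint
    ``floor((start + end) / 2)``; fragments whose midpoint is covered by no
    region are dropped (tallied in the log).  Rows are cells: either the
    sorted unique fragment barcodes, or the explicit ``barcodes`` order when
    given (which may include zero-fragment cells).
    """
    if barcodes is None:
        barcode_index = pd.Index(np.unique(fragments.barcodes))
    else:
        barcode_index = pd.Index(np.asarray(barcodes, dtype=object))
        if barcode_index.has_duplicates:
            raise ValueError("explicit barcode list contains duplicates")
    n_cells = len(barcode_index)
    if len(fragments) == 0:
        mat = sp.csr_matrix((n_cells, scheme.n_regions), dtype=np.int64)
        return CountMatrix(mat, barcode_index.to_numpy(dtype=object), scheme)

    region_idx = scheme.assign(fragments.chroms, fragments.midpoints)
    kept = region_idx >= 0
    n_dropped = int(fragments.counts[~kept].sum())
    if n_dropped:
        logger.info("count_fragments: dropped %d fragment units outside the bin scheme", n_dropped)
    cell_idx = barcode_index.get_indexer(fragments.barcodes[kept])
    if np.any(cell_idx < 0):
        missing = sorted(set(fragments.barcodes[kept][cell_idx < 0]))[:5]
        raise ValueError(f"fragment barcodes absent from explicit barcode list: {missing}")
    mat = sp.coo_matrix(
        (fragments.counts[kept], (cell_idx, region_idx[kept])),
        shape=(n_cells, scheme.n_regions),
        dtype=np.int64,
    ).tocsr()
    mat.sum_duplicates()
    return CountMatrix(mat, barcode_index.to_numpy(dtype=object), scheme)


def merge_bins(fine: CountMatrix, target_scheme: BinScheme) -> CountMatrix:
    """Re-bin a fine fixed-size matrix to a coarser or annotation scheme.

    Each coarse entry is the sum of the fine-bin entries whose bin midpoint
    lies in the target region; fine bins mapping nowhere are dropped (logged).
    When the target is fixed-size with a bin size that is a multiple of the
    fine size, the total count is conserved exactly.
    """
    if fine.scheme.kind != "fixed":
        raise ValueError("merge_bins requires a fixed-size source scheme")
    if target_scheme.kind == "fixed" and target_scheme.bin_size_bp < fine.scheme.bin_size_bp:
        raise ValueError(
            f"target bin size {target_scheme.bin_size_bp} is finer than source "
            f"{fine.scheme.bin_size_bp}"
        )
    mids = (fine.scheme.starts + fine.scheme.ends) // 2
    tgt = target_scheme.assign(fine.scheme.chroms, mids)
    kept = tgt >= 0
    if not kept.all():
        logger.info("merge_bins: %d fine bins map to no target region", int((~kept).sum()))
    proj = sp.coo_matrix(
        (np.ones(kept.sum(), dtype=np.int64), (np.flatnonzero(kept), tgt[kept])),
        shape=(fine.n_regions, target_scheme.n_regions),
    ).tocsr()
    coarse = (fine.counts @ proj).tocsr()
    coarse.sum_duplicates()
    return CountMatrix(coarse.astype(np.int64), fine.barcodes, target_scheme)
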