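"""Readers and writers for the on-disk formats the pipeline exchanges.

Formats: 10x-style fragments TSV (optionally gzipped), chrom.sizes tables,
BED annotations (consumed by :func:`schptm_bench.binning.load_annotation_bins`),
Matrix Market triplets with barcode/feature sidecars for count matrices, and
plain TSV for labels and embeddings.

Count matrices are stored features x cells on disk (the common single-cell
convention) and cells x regions in memory; the round trip is bit-exact for
integer counts.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .binning import BinScheme, CountMatrix, FragmentSet, GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fragments",
    "write_fragments",
    "write_count_matrix",
    "read_count_matrix",
    "read_labels",
    "write_labels",
    "read_embedding_tsv",
    "write_embedding_tsv",
]


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a 2-column (chrom, length) TSV into a :class:`GenomeLayout`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    pd.DataFrame({"chrom": layout.chrom_names, "length": layout.chrom_lengths}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments(path) -> FragmentSet:
    """Read a fragments TSV: chrom, start, end, barcode[, count].

    The count column is optional and defaults to 1.  Gzipped files are
    handled transparently by the ``.gz`` suffix.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("fragments file needs at least 4 columns (chrom, start, end, barcode)")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df
    df.columns = ["chrom", "start", "end", "barcode", "count"][: df.shape[1]]
    if "count" not in df:
        df["count"] = 1
    df["chrom"] = df["chrom"].astype(str)
    df["barcode"] = df["barcode"].astype(str)
    return FragmentSet.from_frame(df)


def write_fragments(fragments: FragmentSet, path) -> None:
    fragments.to_frame().to_csv(path, sep="\t", header=False, index=False)


def write_count_matrix(cm: CountMatrix, outdir) -> None:
    """Write a count matrix as matrix.mtx + barcodes.tsv + features.tsv.

    The Matrix Market file holds integer triplets in features x cells
    orientation; ``scheme.json`` records the bin-scheme kind and size.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", cm.counts.T.tocoo(), field="integer")
    pd.Series(cm.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    cm.scheme.to_frame().to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    meta = {"kind": cm.scheme.kind, "bin_size_bp": cm.scheme.bin_size_bp,
            "layout": {"chrom_names": list(cm.scheme.layout.chrom_names),
                       "chrom_lengths": list(cm.scheme.layout.chrom_lengths)}}
    (outdir / "scheme.json").write_text(json.dumps(meta, indent=1))


def read_count_matrix(indir, drop_empty_cells: bool = True) -> CountMatrix:
    """Read a matrix directory written by :func:`write_count_matrix`.

    Cells with zero total coverage break the normalisations downstream
    (CPM, TF-IDF), so by default they are removed here, with a warning.
    """
    indir = Path(indir)
    mat = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx").T).astype(np.int64)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy(dtype=object)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                        names=["chrom", "start", "end", "region_id"])
    meta = json.loads((indir / "scheme.json").read_text())
    layout = GenomeLayout(tuple(meta["layout"]["chrom_names"]), tuple(meta["layout"]["chrom_lengths"]))
    scheme = BinScheme(
        feats["chrom"].astype(str).to_numpy(dtype=object),
        feats["start"].to_numpy(),
        feats["end"].to_numpy(),
        feats["region_id"].astype(str).to_numpy(dtype=object),
        meta["kind"],
        layout,
        meta["bin_size_bp"],
    )
    cm = CountMatrix(mat, barcodes, scheme)
    if drop_empty_cells:
        totals = cm.row_sums()
        if (totals == 0).any():
            n0 = int((totals == 0).sum())
            warnings.warn(f"removing {n0} zero-coverage cells at matrix load")
            logger.warning("read_count_matrix: removed %d zero-coverage cells", n0)
            cm = cm.subset_cells(np.flatnonzero(totals > 0))
    return cm


def read_labels(path) -> pd.Series:
    """Read a 2-column (barcode, label) TSV into a barcode-indexed Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"])
    return pd.Series(df["label"].to_numpy(), index=df["barcode"].astype(str))


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("barcode").rename("label").reset_index().to_csv(
        path, sep="\t", header=False, index=False
    )


def write_embedding_tsv(embedding, path) -> None:
    """Write an embedding as TSV (barcode + one column per dimension), with a
    sidecar ``<path>.params.json`` echoing the method name and parameters."""
    path = Path(path)
    df = pd.DataFrame(embedding.coords, index=embedding.barcodes)
    df.columns = [f"dim_{i + 1}" for i in range(df.shape[1])]
    df.rename_axis("barcode").to_csv(path, sep="\t")
    sidecar = {"method_name": embedding.method_name, "params_used": embedding.params_used}
    Path(str(path) + ".params.json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_embedding_tsv(path):
    from .embeddings import Embedding

    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = Path(str(path) + ".params.json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return Embedding(
        coords=df.to_numpy(dtype=float),
        barcodes=df.index.astype(str).to_numpy(dtype=object),
        method_name=meta.get("method_name", "external"),
        params_used=meta.get("params_used", {}),
    )
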