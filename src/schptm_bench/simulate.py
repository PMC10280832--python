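"""Synthetic paired-modality single-cell datasets.

Real benchmarks of scHPTM embeddings rely on multi-omic co-assays: a histone
mark measured by scCUT&Tag together with an RNA readout in the same cells.
This module generates datasets with the same statistical skeleton, so every
downstream stage can be exercised and tested without downloads:

* discrete cell types with configurable proportions;
* a per-type scHPTM rate profile over fine genomic bins — flat background
  plus enrichment domains whose widths emulate a mark's regime (kbp-scale
  "narrow" promoter/enhancer marks up to Mbp-scale "broad" repressive
  domains), a fraction of domains being shared by all types;
* per-cell fragment counts drawn lognormally (hundreds to thousands of
  fragments per cell, the regime of current protocols), each fragment placed
  uniformly at random with probability ``background_fraction`` (noise) and
  from the type profile otherwise;
* an RNA-like reference modality generated from the same latent cell types —
  the benchmark's premise that cells with similar epigenomes display locally
  similar expression is built into the generator, not claimed of real data.

All randomness derives from a single seed through named
``numpy.random.SeedSequence`` child streams (labels, domains, coverage,
fragments, rna, barcodes), so every sub-draw is independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import CountMatrix, FragmentSet, GenomeLayout, count_fragments, make_fixed_bins

__all__ = [
    "MarkProfileSpec",
    "SimulationConfig",
    "PairedDataset",
    "MARK_PRESETS",
    "simulate_paired_dataset",
    "shuffle_pairing",
    "write_dataset",
]

DEFAULT_LAYOUT = GenomeLayout(("chr1",), (50_000_000,))


@dataclass(frozen=True)
class MarkProfileSpec:
    """Enrichment-domain geometry of a histone mark.

    ``domain_width_bp`` is the (low, high) sampling range of domain widths;
    ``enrichment_fold`` multiplies the per-bp background rate inside a
    domain; ``shared_fraction`` of each type's domains are common to all
    types (housekeeping-like signal that carries no type information).
    """

    domain_width_bp: tuple = (50_000, 2_000_000)
    n_domains_per_type: int = 10
    enrichment_fold: float = 10.0
    shared_fraction: float = 0.3

    def __post_init__(self):
        lo, hi = self.domain_width_bp
        if not (0 < lo <= hi):
            raise ValueError("invalid domain width range")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")


# named presets spanning the two width regimes of real marks: promoter /
# enhancer-like peaks (kbp, sharply enriched) vs broad repressive domains
# (up to Mbp, only a few-fold enriched over background)
MARK_PRESETS = {
    "narrow": MarkProfileSpec(domain_width_bp=(2_000, 10_000), n_domains_per_type=100,
                              enrichment_fold=10.0),
    "broad": MarkProfileSpec(domain_width_bp=(50_000, 2_000_000), n_domains_per_type=10,
                             enrichment_fold=3.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 2000
    n_types: int = 3
    type_proportions: tuple | None = None  # uniform when None
    layout: GenomeLayout = DEFAULT_LAYOUT
    fine_bin_bp: int = 5_000
    mark: MarkProfileSpec = MARK_PRESETS["broad"]
    background_fraction: float = 0.2
    coverage_log_mean: float = math.log(1000.0)
    coverage_log_sd: float = 1.0
    fragment_length_bp: int = 200
    rna_n_genes: int = 3000
    rna_mean_depth: float = 5000.0
    rna_effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.type_proportions is not None:
            props = tuple(float(p) for p in self.type_proportions)
            if len(props) != self.n_types:
                raise ValueError("type_proportions length must equal n_types")
            if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
                raise ValueError("type_proportions must be nonnegative and sum to 1")
            object.__setattr__(self, "type_proportions", props)
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        for name in ("n_cells", "n_types", "fine_bin_bp", "fragment_length_bp", "rna_n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def proportions(self) -> np.ndarray:
        if self.type_proportions is None:
            return np.full(self.n_types, 1.0 / self.n_types)
        return np.asarray(self.type_proportions)


@dataclass
class PairedDataset:
    """Synthetic bundle: scHPTM fragments + fine count matrix + RNA counts +
    ground-truth labels, all sharing one barcode set."""

    fragments: FragmentSet
    hptm_counts: CountMatrix
    rna_counts: sp.csr_matrix
    barcodes: np.ndarray
    labels: np.ndarray
    truth: np.ndarray  # n_types x n_fine_bins realized rate profiles
    config: SimulationConfig

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def validate(self) -> None:
        if not (len(self.labels) == self.n_cells == self.hptm_counts.n_cells
                == self.rna_counts.shape[0]):
            raise ValueError("component sizes disagree")
        if np.any(self.hptm_counts.barcodes != self.barcodes):
            raise ValueError("barcode sets differ between components")


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 16) -> np.ndarray:
    """Unique 10x-style ACGT barcodes."""
    bases = np.array(list("ACGT"))
    out: set = set()
    codes = []
    while len(codes) < n:
        draw = rng.integers(0, 4, size=(n - len(codes), length))
        for row in draw:
            bc = "".join(bases[row])
            if bc not in out:
                out.add(bc)
                codes.append(bc)
    return np.array(codes, dtype=object)


def _place_domains(config: SimulationConfig, rng: np.random.Generator):
    """Domain sets: one shared list plus one type-specific list per type."""
    mark = config.mark
    lengths = np.array(config.layout.chrom_lengths)
    lo, hi = mark.domain_width_bp
    if lo > lengths.max():
        raise ValueError("domain width exceeds every chromosome length")
    n_shared = int(round(mark.shared_fraction * mark.n_domains_per_type))
    n_specific = mark.n_domains_per_type - n_shared

    def draw(n):
        doms = []
        for _ in range(n):
            width = int(rng.integers(lo, hi + 1))
            feasible = np.flatnonzero(lengths >= width)
            if feasible.size == 0:
                raise ValueError(f"domain of width {width} does not fit any chromosome")
            ci = int(rng.choice(feasible, p=lengths[feasible] / lengths[feasible].sum()))
            start = int(rng.integers(0, lengths[ci] - width + 1))
            doms.append((config.layout.chrom_names[ci], start, start + width))
        return doms

    shared = draw(n_shared)
    per_type = [shared + draw(n_specific) for _ in range(config.n_types)]
    return per_type


def _type_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Per-type fragment-placement probability over fine bins.

    The per-bp rate is 1 outside domains and ``enrichment_fold`` inside
    (bin membership by bin midpoint); bin probability is rate x bin width,
    normalised.
    """
    scheme = make_fixed_bins(config.layout, config.fine_bin_bp)
    widths = (scheme.ends - scheme.starts).astype(float)
    mids = (scheme.starts + scheme.ends) // 2
    per_type_domains = _place_domains(config, rng)
    rates = np.ones((config.n_types, scheme.n_regions))
    for t, domains in enumerate(per_type_domains):
        for chrom, start, end in domains:
            inside = (scheme.chroms == chrom) & (mids >= start) & (mids < end)
            rates[t, inside] = config.mark.enrichment_fold
    probs = rates * widths[None, :]
    probs /= probs.sum(axis=1, keepdims=True)
    return scheme, rates, probs, widths


def simulate_paired_dataset(config: SimulationConfig = SimulationConfig()) -> PairedDataset:
    """Draw one paired dataset; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(("labels", "domains", "coverage", "fragments", "rna", "barcodes"),
                   ss.spawn(6))}

    labels = streams["labels"].choice(config.n_types, size=config.n_cells, p=config.proportions)
    barcodes = np.sort(_random_barcodes(config.n_cells, streams["barcodes"]))

    scheme, rates, probs, widths = _type_profiles(config, streams["domains"])
    bg_prob = widths / widths.sum()

    cov = streams["coverage"].lognormal(config.coverage_log_mean, config.coverage_log_sd,
                                        size=config.n_cells)
    n_frags = np.maximum(1, np.rint(cov)).astype(np.int64)

    rng_f = streams["fragments"]
    n_bg = rng_f.binomial(n_frags, config.background_fraction)
    n_sig = n_frags - n_bg

    # pooled draws per type keep the generation vectorised; fragments are
    # handed back to cells in barcode order within each type
    frag_cell = np.repeat(np.arange(config.n_cells), n_frags)
    frag_bin = np.empty(int(n_frags.sum()), dtype=np.int64)
    # background placement: uniform over the genome (bin prob ~ width)
    is_bg = np.zeros(len(frag_cell), dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(n_frags)])
    for c in range(config.n_cells):
        is_bg[offsets[c]: offsets[c] + n_bg[c]] = True
    total_bg = int(n_bg.sum())
    if total_bg:
        frag_bin[is_bg] = rng_f.choice(scheme.n_regions, size=total_bg, p=bg_prob)
    for t in range(config.n_types):
        mask = (~is_bg) & (labels[frag_cell] == t)
        m = int(mask.sum())
        if m:
            frag_bin[mask] = rng_f.choice(scheme.n_regions, size=m, p=probs[t])

    # fragment geometry: fixed length centered in the chosen bin with uniform
    # jitter of the midpoint, kept inside the chromosome
    half = config.fragment_length_bp // 2
    bstart = scheme.starts[frag_bin]
    bwidth = (scheme.ends - scheme.starts)[frag_bin]
    mid = bstart + rng_f.integers(0, bwidth)
    chrom_len = np.array([config.layout.lengths[c] for c in scheme.chroms[frag_bin]])
    mid = np.clip(mid, half, chrom_len - (config.fragment_length_bp - half))
    starts = mid - half
    ends = starts + config.fragment_length_bp

    frag_chroms = scheme.chroms[frag_bin]
    frag_barcodes = barcodes[frag_cell]
    order = np.lexsort((starts, np.array([str(c) for c in frag_chroms])))
    fragments = FragmentSet(frag_chroms[order], starts[order], ends[order],
                            frag_barcodes[order], np.ones(len(order), dtype=np.int64))

    hptm = count_fragments(fragments, scheme, barcodes=barcodes)

    rna = _simulate_rna(config, labels, streams["rna"])

    ds = PairedDataset(fragments, hptm, rna, barcodes, labels, rates, config)
    ds.validate()
    return ds


def _simulate_rna(config: SimulationConfig, labels: np.ndarray,
                  rng: np.random.Generator) -> sp.csr_matrix:
    """Type-structured RNA counts: common lognormal baseline, per-type
    lognormal fold-changes of scale ``rna_effect_size``, multinomial sampling
    to a Poisson per-cell depth."""
    base = rng.lognormal(0.0, 1.0, size=config.rna_n_genes)
    folds = rng.lognormal(0.0, config.rna_effect_size,
                          size=(config.n_types, config.rna_n_genes))
    profiles = base[None, :] * folds
    profiles /= profiles.sum(axis=1, keepdims=True)
    depths = np.maximum(1, rng.poisson(config.rna_mean_depth, size=config.n_cells))
    rows = []
    for c in range(config.n_cells):
        rows.append(rng.multinomial(depths[c], profiles[labels[c]]))
    return sp.csr_matrix(np.stack(rows), dtype=np.int64)


def shuffle_pairing(dataset: PairedDataset, seed: int) -> PairedDataset:
    """Negative control: permute the RNA rows against the scHPTM rows.

    Labels stay with the scHPTM rows; the barcode multiset is unchanged.
    """
    if dataset.n_cells < 2:
        raise ValueError("need at least 2 cells to shuffle")
    perm = np.random.default_rng(seed).permutation(dataset.n_cells)
    return PairedDataset(
        fragments=dataset.fragments,
        hptm_counts=dataset.hptm_counts,
        rna_counts=dataset.rna_counts[perm],
        barcodes=dataset.barcodes,
        labels=dataset.labels,
        truth=dataset.truth,
        config=dataset.config,
    )


def write_dataset(dataset: PairedDataset, outdir) -> None:
    """Write fragments TSV, both matrices (MTX + sidecars), labels TSV and a
    config echo."""
    from . import io as _io
    from .binning import BinScheme

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fragments(dataset.fragments, outdir / "fragments.tsv")
    _io.write_count_matrix(dataset.hptm_counts, outdir / "hptm")
    rna_dir = outdir / "rna"
    rna_dir.mkdir(exist_ok=True)
    import scipy.io as sio

    sio.mmwrite(rna_dir / "matrix.mtx", dataset.rna_counts.T.tocoo(), field="integer")
    pd.Series(dataset.barcodes).to_csv(rna_dir / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.Series([f"gene_{i}" for i in range(dataset.rna_counts.shape[1])]).to_csv(
        rna_dir / "features.tsv", sep="\t", header=False, index=False)
    _io.write_labels(pd.Series([f"type_{t}" for t in dataset.labels], index=dataset.barcodes),
                     outdir / "labels.tsv")
    cfg = asdict(dataset.config)
    cfg["layout"] = {"chrom_names": list(dataset.config.layout.chrom_names),
                     "chrom_lengths": list(dataset.config.layout.chrom_lengths)}
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
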