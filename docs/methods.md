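# Methods

## Pipeline model

The package treats scHPTM analysis as a chain
fragments → cell×region count matrix → (optional QC perturbation) →
embedding → evaluation, with every stage exchangeable:

* **Matrix construction.** Coordinates are BED-convention 0-based half-open
  everywhere. Fixed-size bins tile each chromosome from position 0; the last
  bin is truncated at the chromosome end. Each fragment is assigned to
  exactly **one** region by its midpoint `floor((start+end)/2)`; fragments
  covered by no region are dropped and tallied in the log. The midpoint rule
  is this package's choice: it never double-counts a boundary-spanning
  fragment, so re-binning conserves totals. Duplicate
  (chrom, start, end, barcode) records are summed, not deduplicated — the
  fragments format carries a count column and upstream deduplication is
  assumed done. Re-binning a fine fixed-size matrix (`merge_bins`) assigns
  each fine bin to the target region containing the fine bin's midpoint;
  when the target size is a multiple of the source size the total count is
  conserved exactly, and rebinning fragments directly at the coarse size is
  identical to merging the fine matrix. The default sweep grid is
  {5, 10, 20, 50, 100, 200, 500, 1000} kbp. On disk, matrices are Matrix
  Market triplets in features×cells orientation with barcode/feature TSV
  sidecars; the in-memory orientation is cells×regions and the round trip is
  bit-exact. Zero-coverage cells are removed at matrix load (with a warning)
  because they break the normalisations downstream.

* **QC perturbations.** Coverage filtering keeps the top `ceil(f·n)` cells
  by total count (ties broken by barcode). Feature selection is either
  highest column sum ("top") or a variance-stabilised ranking ("HVG"): per
  region, a lowess fit (span 0.3) of log10 variance on log10 mean gives an
  expected standard deviation; entries are standardised and clipped above at
  √n_cells, and regions are ranked by the variance of the standardised
  column. With fewer than 20 distinct means the trend fit is ill-posed and
  degenerates to the global mean of log variance (degree-0 fallback) — this
  makes toy fixtures reproducible by hand. Downsampling draws cells uniformly
  without replacement, deterministically given a seed. Default grids:
  coverage fractions {1.0 … 0.4} and feature fractions {1.0 … 0.05}, seven
  conditions each.

* **Embeddings.** The TF-IDF convention is
  `log(1 + scale · TF_ij · IDF_j)` with `TF_ij = x_ij / Σ_j x_ij`,
  `IDF_j = n_cells / df_j` and scale 10⁴; packages in the field differ in
  their exact TF-IDF variant, so one canonical form is fixed here (behind
  `TfidfParams`) and no concordance with any particular implementation is
  claimed. CPM normalisation applies log1p after counts-per-million — raw
  CPM PCA would be scale-dominated. SVD embeddings are computed on the
  column-centered matrix (implicit centering through a linear operator keeps
  the input sparse; small problems use a dense exact SVD); "eigen" weighting
  returns the PCA scores U·S, "whitened" returns U·√(n−1) so each component
  has unit sample variance. All scHPTM presets compute one extra component
  and drop the first — on real data the leading component tracks per-cell
  coverage rather than identity, and the synthetic generator reproduces this
  (see below) — while the RNA reference embedding keeps it. Component signs
  are fixed (largest-magnitude loading positive) for run-to-run determinism.
  Jaccard kernel PCA binarises the matrix, computes pairwise Jaccard
  similarity, by default divides by the expected similarity under
  independent per-cell detection rates `E_ab = p_a p_b / (p_a + p_b −
  p_a p_b)`, double-centers, and eigendecomposes; negative eigenvalues
  (possible after the observed-over-expected normalisation) are clipped to
  zero before the √-eigenvalue scaling. NMF minimises Frobenius loss by
  coordinate descent from a nonnegative-double-SVD init with seeded noise
  (max 200 iterations, tol 1e-4); a non-converged run returns the best
  iterate and flags `converged: False`. Because the seeded init noise is not
  row-permuted with the data, NMF is only approximately equivariant to cell
  permutation; the SVD- and kernel-based methods are exactly equivariant.

* **Reference embedding.** The co-assay (RNA) representation is a
  deterministic simplified standard pipeline: depth-normalise each cell to
  10⁴, log1p, keep the 2,000 most variable genes by the HVG ranking above,
  center and unit-scale genes with values clipped at 10, PCA to
  min(50, rank) dimensions, no component dropped.

## Neighbor score

For each k in the grid given by fractions {0.001, 0.003, 0.005, 0.01, 0.03,
0.05, 0.10} of the cell count (`k = max(1, round-half-up(f·n))`, capped,
deduplicated), the k-nearest-neighbor graph is built in both embeddings
(Euclidean metric; ties broken by ascending cell index, so the graph is
fully deterministic). The score is the mean over cells of the shared-neighbor
fraction, then the unweighted mean over k.

Neighborhoods **include the query cell** by default. With self-inclusive
neighborhoods the expectation for two unrelated embeddings is
`mean_k[(1 + (k−1)²/(n−1)) / k]`, ≈0.052 at n = 10⁴ on the default grid —
the familiar ≈0.05 baseline; with self excluded it would be ≈0.028. The
convention is exposed in `NeighborScoreConfig`. Note that the baseline grows
as n shrinks (at n = 2,000 it is ≈0.15, and the k=1 term alone contributes
1/|grid|), so absolute scores are only comparable at a fixed cell count.

Clustering evaluation uses seeded k-means (10 restarts, best inertia) or
Ward agglomerative clustering, scored by ARI (pair counting, hypergeometric
chance model) and AMI (arithmetic-mean normaliser) — the fixed conventions
matter for exact tests.

## Synthetic paired-modality generator

The generator stands in for real multi-omic co-assay datasets. Defaults are
desk-scale and chosen once:

* **Genome**: 1 chromosome × 50 Mbp, fine bins of 5 kbp (10⁴ bins).
* **Cell types**: 3 types, uniform proportions, 2,000 cells.
* **scHPTM profile**: per-bp rate 1 outside domains, ×`enrichment_fold`
  inside. Domains are placed uniformly with widths drawn from the mark
  preset: `narrow` = 2–10 kbp, 100 domains/type, fold 10 (sharp
  promoter/enhancer-like peaks); `broad` = 50–2,000 kbp, 10 domains/type,
  fold 3 (Mbp-scale repressive domains are only a few-fold enriched over
  background). 30% of domains are shared by all types and carry no type
  information. The default preset is `broad`.
* **Coverage**: per-cell fragment count ~ lognormal(log 1000, 1.0), i.e.
  median 1,000 fragments with an order-of-magnitude spread, the regime of
  current protocols. The wide spread matters: it makes the leading component
  of TF-IDF/SVD a technical depth axis, as observed on real data, so the
  drop-first convention of the presets behaves as intended. Each fragment is
  placed uniformly over the genome with probability `background_fraction`
  (default 0.2) and from the cell's type profile otherwise; fragments are
  200 bp, centered in the chosen bin with uniform jitter.
* **RNA modality**: 3,000 genes; a common lognormal baseline with per-type
  lognormal fold-changes (scale 1.0); per-cell depth ~ Poisson(5,000),
  multinomial sampling. The RNA is generated from the same latent types as
  the scHPTM profiles — the core assumption of co-assay-based evaluation
  (epigenomically similar cells are transcriptomically similar) is a
  simulation premise here, not a claim about real data.
* **Seeding**: one global seed feeds named `SeedSequence` child streams
  (labels, domains, coverage, fragments, rna, barcodes), so every sub-draw
  is reproducible and components can be regenerated independently.

What the generator does **not** emulate: batch effects, doublets,
continuous trajectories, GC/mappability bias, protein (CITE-seq-like)
readouts, chromatin contact structure, or realistic genome size (the toy
genome is ~50× smaller than mammalian, so per-bin coverage at a given bin
size is correspondingly higher than in real data). Tests passing on this
generator therefore validate the machinery and the qualitative logic of the
benchmark, not quantitative performance on any real dataset.

## Test and acceptance problem sizes

The test suite exercises the worked-example and perfect-agreement values of
the score exactly; the random baseline at 10,000 cells over 10 seeds;
brute-force/dense oracles for kNN, PCA, ARI and fragment counting;
conservation and invariance laws; and, on fixed-seed synthetic data,
parameter recovery (k-means ARI of the LSI embedding vs ground truth > 0.8
at 200 kbp bins; neighbor score strictly decreasing in background noise and
reaching the random floor at pure noise) plus two qualitative trends:
TF-IDF+SVD scoring at least as high as CPM-PCA on low-coverage data, and the
score-maximizing bin size being larger for the broad preset than for the
narrow one. The trend checks run at median coverage 150 — the low-coverage
regime where matrix construction matters most; at higher coverage the broad
mark's score is nearly flat across bin sizes and the argmax is not
informative. Sweep sizes (2,000 cells, 8 bin sizes, 2 seeds) are the
package's default desk-scale protocol.

## Known limitations

* The neighbor-score baseline depends on n; compare scores only within a
  dataset/perturbation of fixed size (the harness recomputes the reference
  embedding on the retained cells after any cell-reducing perturbation).
* The HVG trend fit falls back to degree 0 below 20 distinct means; toy
  matrices are ranked by the fallback formula, not by lowess.
* `jaccard_kpca` requires every cell to have a nonempty binary profile and
  densifies the cell×cell kernel (quadratic memory in cells).
* NMF determinism is per (data, seed); it is not exactly equivariant to row
  permutation (seeded init noise), and non-convergence within 200 iterations
  is flagged rather than raised.
* Latent Dirichlet allocation and variational autoencoder methods are out of
  scope; externally computed embeddings can be scored by writing them as the
  embedding TSV format.
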