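# Methods

## Scoring model

A spot's measured expression is the pooled signal of the cells its capture
area overlaps. `spottype` labels spots by marker-set enrichment rather
than deconvolution, so the only inputs are the spot count matrix and a
marker database of positive and (optionally) negative genes per cell type.

**Normalization.** Counts restricted to the tissue's marker genes are
log1p-transformed, then each gene row is centered and scaled across spots
(sample standard deviation, n−1 denominator). Z-scoring is what makes
positive and negative marker contributions symmetric around the tissue
average: a marker merely at its tissue-wide mean contributes nothing.
Rows with zero variance carry no information and are dropped (logged).
If *no* marker gene is present in the matrix at all, normalization raises
a hard `NoMarkerGenesError` rather than returning an empty matrix — on
targeted panels with a few hundred probes this is a real, common failure
and silently producing arbitrary labels would be worse than stopping.

**Specificity weights.** With `N` cell types in the selected tissue and a
gene appearing in the marker lists (positive or negative, counted once per
cell type) of `n_g` of them, the weight is `w_g = 1 − (n_g − 1)/(N − 1)`
(`1` when `N = 1`). This is the simplest form with the right endpoints —
weight 1 for a gene marking a single cell type, weight 0 for a gene
marking all of them — and is strictly decreasing in `n_g`. Weighting is
tissue-scoped: occurrences of the gene in other tissues' marker lists are
irrelevant once a tissue is selected.

**Enrichment and integration.** For cell type `k` with detected positive
set `P_k` and negative set `N_k`,

    ES(k, s) = ( Σ_{g∈P_k} w_g z_gs − Σ_{g∈N_k} w_g z_gs ) / √(|P_k|+|N_k|).

The positive and negative sums are the two marker-set enrichment matrices;
subtracting them and dividing by the square root of the total marker count
integrates them into one score comparable across cell types with different
marker-set sizes (the √ denominator is the variance-stabilizing choice for
a sum of standardized terms). Cell types with no detected marker are
excluded from the score matrix and recorded with counts (0, 0).

**Assignment.** Per spot: argmax over cell types; exact ties go to the
lexicographically smallest label so results are platform-independent. With
`unknown_if_nonpositive`, a top score ≤ 0 — no marker set enriched above
the tissue average — yields `Unknown`. Per cluster: scores are summed over
member spots and the cluster is labeled `Unknown` when the top summed
score is below `min_score_fraction × cluster size` (default 0.25, exposed
as a parameter); member spots inherit the cluster label. Both modes are
provided because practice varies between per-spot and cluster-aggregated
annotation; per-spot is the default in the CLI.

## Marker derivation from reference profiles

`derive_markers_from_reference` ranks genes per label by the gap between
the label's log1p-mean expression and the best competing label's
log1p-mean, keeping the `top_n` genes with strictly positive gap (ties
broken by gene symbol). This one-vs-best-other gap is deliberately a
deterministic screening rule, not a statistical test: a gene can only
score positively for one label, so derived positive sets are disjoint by
construction, and on noiseless profiles it provably recovers planted
marker blocks. When a label has fewer than `top_n` positively scoring
genes the available ones are kept and a warning is logged; a label with no
positively scoring genes gets an empty set (the returned database permits
this, unlike databases ingested from files, where an entry without
positive markers is rejected).

## Simulator

The generator emulates a spatially organized tissue probed by a
fixed-diameter spot array:

1. **Placement.** `n_cells` positions uniform in a `width × height` µm
   rectangle. Types by layout: `random` (iid uniform), `stripes` (K equal
   vertical bands), `blobs` (K Gaussian-jittered centers on a grid, type =
   nearest center). `blobs` is the default because real tissue is
   spatially organized into contiguous domains; `random` exists as a
   worst case in which many spots straddle type boundaries.
2. **Expression.** Counts per (gene, cell) are negative binomial — the
   standard overdispersed count model for transcriptomics — with mean
   `mu_high` (default 10) for a cell's own marker genes and `mu_low`
   (default 0.2) otherwise, shared dispersion `theta` (default 2, variance
   µ + µ²/θ). Each type owns a disjoint planted block of
   `markers_per_type` (default 5) marker genes; `n_background_genes`
   (default 20) genes mark nothing and exist so that marker genes are a
   minority of the panel, as in real assays.
3. **Capture.** Spots of diameter 10 µm (default) sit on a square lattice
   with pitch 20 µm (default). A cell is captured iff its center lies in
   the closed disk around the nearest spot center, so every cell lands in
   at most one spot and gene-wise counts are conserved between captured
   cells and the spot matrix — an invariant the tests assert. Ground
   truth per spot is the modal captured type (lexicographic tie-break),
   `Empty` for spots capturing nothing; majority truth mirrors
   "most abundant cell type per spot" semantics.

The default configuration (4 types, 2000 cells on 500×500 µm) is the
benchmark condition used by the test suite and the acceptance script; at
20 µm pitch it yields 625 spots of which roughly 250–320 capture at least
one cell (mean occupancy ≈ 0.6 cells/spot), so most occupied spots hold a
single cell and multi-cell spots concentrate at blob boundaries.

**Seed schedule.** The master seed spawns independent `SeedSequence`
substreams for placement (positions, typing) and expression, so each stage
is reproducible in isolation and full runs are byte-identical given a
seed.

**What it does not model.** Capture efficiency and dropout gradients,
segmentation noise, doublet chemistry, platform-specific probe panels
(restricting the output genes stands in for a targeted panel), and any
transcriptome-scale correlation structure. Passing the recovery tests
therefore shows the scoring machinery is correct and well-conditioned at
realistic signal strengths — not that real-tissue accuracy will match the
simulated numbers.

## Benchmarking

Correctness is taxonomy-aware: a prediction is correct iff it equals the
truth or the truth is a proper ancestor of it ("same or deeper level").
Before computing metrics, predictions are unified to the truth label set:
each is replaced by its nearest ancestor (or itself) in that set, `Other`
when none exists; `Unknown` predictions always unify to `Other`, i.e.
abstention is penalized. Spots whose truth is `Empty` or `Unknown` are
excluded. Per truth class, one-vs-rest TP/FP/FN give precision (0 when
TP+FP = 0), recall, and F1 (0 when both are 0); the summary is the median
F1 across classes, with the even-count median taken as the mean of the two
central values.

## Numerical and interface choices

- Tolerances: score agreement with the brute-force oracle is asserted at
  1e−10 (pure float64 arithmetic); z-score row statistics at 1e−8.
- Sparse spot matrices are accepted anywhere and densified only on the
  marker-gene rows actually used, since marker panels are small relative
  to the transcriptome.
- Gene symbols are canonicalized (trimmed, uppercased) on every ingest
  path; duplicate features in an MTX bundle are summed.
- Geometry is micron-space, origin top-left, y downward, 0-based,
  matching full-resolution pixel conventions of Visium position files.
- CLI exit codes: 0 success, 1 unexpected, 2 lookup/validation/format,
  3 no marker genes detected.

## Problem sizes

The test suite and acceptance script run the full benchmark condition
(2000 cells, 625 spots) across 5 seeds, a 15-run difficulty ladder at
1500 cells, 50 random oracle instances and 20 random conservation
configurations; the whole suite completes in a few seconds since every
stage is vectorized over genes × spots.

## Known limitations

- The specificity-weight formula and the √-count integration are the
  simplest forms satisfying the documented endpoint behavior; other
  monotone rescalings would also be defensible.
- Cluster-mode `Unknown` thresholding is a heuristic confidence cutoff;
  its default (0.25) is exposed rather than claimed optimal.
- `derive_markers_from_reference` is a screening rule, not a DE test, and
  derives no negative markers.
- The benchmark excludes `Empty`/`Unknown` truths; tools that abstain are
  penalized on recall but not rewarded for calibrated abstention.
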