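# Methods

## The problem

A chimeric sample — human cells developing inside a mouse tissue —
sequenced with droplet scRNA-seq against a pooled human+mouse
reference yields, for every read, a best alignment (gene and score)
per species. Three artefacts must be handled before any cross-species
biology can be read off: reads whose cross-species alignment
spuriously wins (misassignment), droplets that captured one cell of
each species (interspecies doublets), and the fact that the two
species' gene namespaces differ. This package deconvolves the species,
eliminates cross-species barcodes, maps genes through a strict 1:1
ortholog table, and then compares the two species' expression on the
shared namespace.

## Species deconvolution

**Read assignment.** The species with the strictly greater alignment
score wins; exact ties are ambiguous (never broken randomly, for
determinism); a read aligned in only one species goes to that species.

**UMI collapse.** Reads sharing (barcode, UMI) are one candidate
molecule. Its species is the majority of its read calls
(human-vs-mouse ties → ambiguous); its gene is the majority gene among
the winning species' reads, ties broken lexicographically and logged.
`supporting_reads` counts the agreeing reads; molecules below
`min_reads_per_molecule` (default 1) are dropped. Classifying barcodes
at the molecule level rather than the read level prevents PCR
amplification depth from biasing the species tallies.

**Barcode elimination.** Per barcode, ambiguous molecules are set
aside and the two species tallied. With minor fraction
f = min(h, m)/(h + m), a barcode is `cross_species` when
min(h, m) ≥ `min_minor_molecules` (default 2) **and**
f ≥ τ (default 0.10); otherwise the verdict is the majority species.
A literal "any opposite-species molecule" rule would flag nearly every
barcode under realistic misassignment noise, so both thresholds are
explicit, configurable parameters rather than fidelity claims. The
reported flagged percentage is truncated (not rounded) to two
decimals, computed with exact integer arithmetic, matching the
convention in the source material (147/19,154 → 0.76%). Barcodes with
no unambiguous molecules fall back to a read-level majority when read
calls are supplied, else they are dropped with a log entry. Raising τ
can only shrink the flagged set (monotonicity is tested).

## Ortholog table

Homology-report rows (class id, species, symbol) are curated into a
strict bijection: a class is retained iff it pairs exactly one human
with exactly one mouse symbol and neither symbol is claimed by another
retained candidate. Drops are recorded with reasons (`many-to-one`,
`missing species`, `symbol collision`). The real curation behind
published tables was partly manual; this rule is the reproducible
proxy, so the table size of any given report is not treated as a
target. Symbol comparison is case-sensitive — human symbols are
upper-case and mouse symbols capitalized, so lowercasing would
manufacture collisions. A pre-curated two-column table can be supplied
directly, skipping curation.

## Quantification

Count matrices are barcodes × genes, entry = number of distinct UMIs.
Normalization is the standard droplet convention
`ln(1 + c / C · s)` with scale factor s = 10,000 (configurable); the
source material states only "log normalized counts", so the de facto
convention is adopted. Zero-total barcodes are dropped with a log
entry. Merging translates human symbols to mouse symbols and keeps the
intersection of the translated human genes with the mouse genes
(cross-species statistics are defined only on genes with unique
orthologs); barcodes are suffixed `_human`/`_mouse`; untranslatable
genes are reported, never silently dropped. The pipeline fixes the
order eliminate → count → normalize.

## Identity analysis

Clustering is deliberately plumbing: PCA (default 20 components) plus
k-means on the log-normalized matrix, deterministic under the given
seed; externally produced labels are first-class input and pass
through verbatim. The scientific outputs are cluster mean profiles and
their Pearson cross-correlation over the shared namespace (pairwise
gene exclusion; zero-variance profiles give missing, not zero). In a
chimeric brain this is the statistic that ties the xenografted human
cluster to the host's homologous cell type — on synthetic data with
shared elevated markers the human cluster's top correlation lands on
its mouse counterpart, though the numeric value is data-dependent.
Dot statistics use raw-count > 0 for "expressing" (nonzero is
preserved by the monotone normalization, so either matrix state gives
the same percentage) and mean log-normalized values for colour.
Z-scores use the n−1 denominator; zero-spread genes give all-zero rows
with a warning.

## Cross-species comparison

Per-ortholog cluster means are arithmetic means of log-normalized
values. The log2 ratio adds a pseudocount ε (default 0.01) to both
means. Concordance reports the fraction of pairs with |log₂ ratio| < 1
("within twofold", one decimal) and the squared Pearson correlation of
the two mean vectors.

Differential calls use a two-sided rank-sum test per gene on the
per-cell log-normalized values (Welch t optional), BH-FDR across all
tested genes, and the class rule: `human_enriched` iff
log₂ ratio ≥ log₂(fold cutoff) and FDR < α (defaults 2 and 0.05),
`mouse_enriched` symmetric, else `shared`. Genes that are all-zero in
both sets are excluded and logged. Swapping the two cell sets swaps
the classes and negates the ratio exactly.

**Ratio scale.** The fold ratio entering the DE class is computed on
*linearized* means — mean of expm1 of the log-normalized values — by
default, while the concordance scatter uses means of the
log-normalized values themselves. The reason is numeric: log1p
compresses large values, so a genuine twofold raw difference shows up
as roughly half that on the log scale (empirically, a planted log2
fold of 2 appears as ~0.75–1.0 in log-scale means), which would make a
twofold cutoff on log-scale means blind to true twofold genes.
Linearized means are the convention of the standard single-cell
toolkits for exactly this reason. `scale="log"` switches back where
comparability with log-scale presentations matters.

Disease-panel tallies are direction-of-means comparisons with no
significance filter (an optional FDR restriction exists); panel
symbols given in the human namespace are auto-translated. The shipped
`ms`/`ad`/`pd` panels are small illustrative subsets of
microglia-expressed disease-risk genes and are plain editable inputs —
published tallies on full panels require the corresponding full gene
lists and real data.

## Synthetic generator

The generator emulates the structure the pipeline reads, not
sequences:

- **Expression**: per-gene lognormal(0, 1) base weights shared between
  species for orthologs (independent for species-exclusive genes),
  scaled to `molecules_per_cell`; counts are NB with mean μ and
  variance μ + μ²/θ (θ = `nb_dispersion`, default 2); per-cell
  lognormal library factor (σ = 0.3). Planted log2 folds multiply the
  human-side means of chosen ortholog genes.
- **Doublets**: `round(doublet_rate · (n_h + n_m))` extra barcodes,
  each pooling the molecules of one fresh human and one fresh mouse
  cell (50/50 by construction), mimicking droplets that captured a
  cell of each species.
- **Alignment scores**: one draw near the own-species level (default
  90) and one near the cross-species level (default 60), sd 8,
  order-enforced so the own-species score strictly wins; with
  probability `misassignment_rate` the pair is swapped, making the
  parameter exactly the read-misassignment probability. Only ortholog
  genes receive a cross-species alignment. No public characterization
  of the empirical score gap exists for the pooled-reference setting,
  so these defaults are declared calibration knobs.
- **Reads per molecule**: 1 + Poisson(mean − 1).

Defaults are desk-scale (hundreds of cells, ~1,200 genes, hundreds of
molecules per cell) so that full-pipeline runs finish in seconds; the
validation suite uses up to ~5,000 barcodes × 2,000 genes and the DE
checks use 200 cells per side at ~1,100 molecules per cell — the sizes
were chosen once as adequate for the statistics tested. What the
generator does *not* model: ambient RNA ("soup"), sequence content and
error profiles, within-species doublets, cell-type heterogeneity
within a species. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
performance on any real dataset.

## Numerical and design choices

- Determinism everywhere: one `numpy` Generator seeded from the config;
  lexicographic tie-breaks; no randomized fallbacks. Reruns with the
  same config and seed are byte-identical (checked on whole output
  trees).
- The run manifest records per-stage parameters, in/out counts and
  sha256 checksums with relative paths and no timestamps, so it is
  itself reproducible; a conservation audit reconciles
  reads → UMI groups → molecules → per-species counts, attributing
  every discarded molecule to a named filter.
- Degenerate inputs reject loudly (empty cell sets, uncalled barcodes,
  double normalization, non-bijective tables) or warn and degrade
  (empty molecule set → 0×0 matrix; zero-spread Z-scores → zeros).
- Realized-fold tolerances in tests are derived from the generative
  variance (NB dispersion plus the shared library-size offset), not
  tuned.

## Known limitations

- The barcode-elimination thresholds are declared defaults; published
  flagged fractions from real pooled alignments depend on the
  unpublished rule used there and are not reproduction targets.
- The 1:1 curation rule is a proxy for manual curation; real homology
  reports contain judgment calls a rule cannot replicate.
- Clustering is intentionally minimal (PCA + k-means); graph-based
  clustering and embeddings are out of scope, and external labels are
  the recommended path for real data.
- Concordance r² and cross-correlation values on synthetic data are
  properties of the generator's shared-weight construction and are not
  comparable to values from real tissue.
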