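# chimeraseq

Species deconvolution and cross-species expression comparison for
mixed human–mouse ("barnyard") droplet scRNA-seq, as produced by
xenograft models such as human stem-cell-derived microglia engrafted
into the mouse brain.

When a chimeric tissue is sequenced against a pooled human+mouse
reference, every read can be scored against both genomes. This package
implements the computational chain that turns those pooled alignments
into clean per-species expression data and then compares the two
species' coresident cell populations:

1. **Read-level species assignment** — each read goes to the species
   with the strictly greater alignment score (ties are ambiguous).
2. **UMI collapse** — one molecule per (barcode, UMI) by majority vote
   of its read calls.
3. **Cross-species barcode elimination** — a barcode whose minor
   species contributes ≥ `min_minor_molecules` molecules *and* ≥ τ of
   its unambiguous molecules (defaults 2 and 0.10) is flagged as an
   interspecies doublet and removed; the flagged percentage is reported
   (e.g. 147 of 19,154 barcodes → 0.76%).
4. **Ortholog curation and translation** — a homology report is
   curated into a strict 1:1 human↔mouse symbol bijection; human genes
   are translated into the mouse namespace.
5. **Quantification** — per-species UMI count matrices, log
   normalization `ln(1 + c_gb / C_b · 10^4)`, and a merged matrix on
   the shared-ortholog namespace.
6. **Identity analysis** — cluster mean profiles, Pearson
   cross-correlation between clusters, dot-plot marker statistics
   (percent expressing, average expression), per-gene Z-scores.
7. **Cross-species comparison** — per-ortholog mean expression and
   log2 ratios, a concordance summary (fraction of pairs within a
   twofold range, i.e. |log₂ ratio| < 1, plus r² of the mean vectors),
   per-gene rank-sum tests with Benjamini–Hochberg FDR and a twofold /
   FDR < 0.05 enrichment call, and disease-gene-panel tallies.

A first-class synthetic generator (`simulate_chimera`) produces
barcoded two-species read tables with negative-binomial expression,
configurable interspecies-doublet and read-misassignment rates,
planted log2 fold-changes, and full ground truth, so every stage can
be validated against exact truth.

## Worked example

```python
import chimeraseq as cq

cfg = cq.SimulationConfig(
    n_cells_human=500, n_cells_mouse=500, doublet_rate=0.02,
    n_ortholog_genes=600, n_human_only_genes=50, n_mouse_only_genes=50,
    molecules_per_cell=200.0, planted_fold_changes={"GENE00007": 2.0},
    seed=1,
)
reads, truth = cq.simulate_chimera(cfg)
mols = cq.collapse_umis(reads)
calls = cq.classify_barcodes(mols)
print(cq.classification_summary(calls))
```

```
{'n_barcodes': 1020, 'n_cross_species': 20, 'percent_cross_species': 1.96}
```

All 20 constructed doublet barcodes (2% of 1,000 cells) are flagged
and none of the pure barcodes is. Continuing through quantification
and comparison:

```python
split = cq.split_by_species(mols[mols["barcode"].isin(calls["barcode"])], calls)
table = cq.build_ortholog_table(cq.make_homology_records(cfg))
merged, _ = cq.merge_species_matrices(
    cq.count_molecules(split.human, "human"),
    cq.count_molecules(split.mouse, "mouse"), table)
merged = cq.log_normalize(merged)
hc = [b for b in merged.barcodes if b.endswith("_human")]
mc = [b for b in merged.barcodes if b.endswith("_mouse")]
print(cq.concordance(cq.ortholog_pair_means(merged, hc, mc)))
det = cq.differential_orthologs(merged, hc, mc)
print(det[det["class"] == "human_enriched"].round(3))
```

```
ConcordanceSummary(n_pairs=600, n_within_twofold=597,
                   fraction_within_twofold=99.5,
                   r_squared=0.9685944294882394, p_value=0.0)
           mean_human  mean_mouse  log2_ratio  p_value  fdr           class
gene
Gene00007       3.002       1.149       1.972      0.0  0.0  human_enriched
```

The two species' mean expression is highly concordant (99.5% of
ortholog pairs within twofold, r² = 0.97), and the single gene planted
at a log2 fold of 2 is the only human-enriched call, recovered at its
planted magnitude.

The same run is available from the shell:

```bash
chimeraseq simulate --seed 1 --outdir sim
chimeraseq deconvolve sim/read_table.tsv --outdir dec
chimeraseq run-all --seed 1 --outdir run   # full pipeline + manifest
```

`run-all` writes per-stage outputs (barcode calls, MTX matrices,
cluster correlation, DE tables) plus `manifest.json` recording every
parameter, count and output checksum; reruns with the same seed are
byte-identical, and the manifest reconciles every molecule from read
to count matrix.

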