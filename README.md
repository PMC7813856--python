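# scfa-resilience

Resilience analysis of short-chain-fatty-acid (SCFA) synthesis genes in
human gut metagenomes, from stratified gene-family tables.

## The problem

The three major SCFAs — acetate, butyrate and propionate — are end products
of microbial fibre fermentation and central to gut health.  Whether a
microbiome can *keep* producing them after an ecological disturbance depends
not on total gene abundance but on how the synthesis genes are distributed
across taxa: a function encoded by many, evenly contributing, phylogenetically
diverse bacteria survives the loss of any one clade; a function dominated by
a few close relatives does not.  This package quantifies that resilience
potential from shotgun-metagenome functional profiles (HUMAnN2-style
stratified gene-family tables, where each gene's abundance is split by the
contributing taxon plus an `unclassified` remainder), and — equally important
— quantifies how much of the signal is an artefact of reference-database
bias against under-studied populations.

It is written for microbiome researchers comparing cohorts (e.g. lifestyle
groups: industrial, pastoral, rural-agricultural, hunter-gatherer) and for
methodologists studying annotation bias.

## What it computes

For each SCFA gene group (acetate = *ackA*; butyrate = *buk* + *but*;
propionate = *mmdA* + *lcdA* + *pduP*) at a chosen taxonomic level, per
sample:

- **Richness** — number of taxa with gene abundance > 0.
- **Hill numbers** ^q^D for q = 0, 1, 2: with relative contributions
  p_i, ^0^D = S (richness), ^1^D = exp(−Σ p_i ln p_i) (effective number of
  common taxa), ^2^D = 1/Σ p_i² (effective number of dominant taxa).
- **Gini-Simpson index** 1 − Σ p_i² — the probability two reads come from
  different taxa; equals 1 − 1/^2^D.
- **Faith's phylogenetic diversity** — branch length of the subtree
  subtending the observed taxa on a supplied (e.g. 16S proxy) tree; rooted
  or crown convention.
- **Bias statistics** — the fraction of gene abundance classified to a
  taxon at each rank (phylum/family/genus/species), and the genus:species
  relative mapping index (species-attributed over genus-attributed
  abundance; < 1 means species-level annotation dropout, > 1 means
  species-only annotations with a missing genus).
- **Group comparisons** — Kruskal–Wallis omnibus, Dunn's pairwise post-hoc
  (tie-corrected, two-sided), Benjamini–Hochberg FDR within a declared
  family scope.

A first-class synthetic-cohort generator (`scfa_resilience.cohort`) produces
stratified tables with population-structured taxon pools,
Dirichlet-controlled evenness, lognormal totals, a controlled unmapped
fraction and rank-specific annotation dropout — with full ground truth, so
every stage of the pipeline is testable against known parameters.

## Worked example

Simulate an evenness contrast (two populations sharing the same 20-genus
pools, Dirichlet α = 5 vs 0.2) and run the full analysis:

```python
from scfa_resilience import (preset_cohorts, generate_cohort,
                             PipelineConfig, run_pipeline)

preset = preset_cohorts()["evenness-shift"]
table, metadata, truth = generate_cohort(preset.specs, seed=42)
result = run_pipeline(PipelineConfig(table=table, metadata=metadata))

tidy = result.comparison_frame()
cols = ["metric", "gene_group", "level", "group_a", "group_b", "z", "p_adj"]
print(tidy.query("metric == 'hill_q1' and level == 'genus'")[cols].to_string(index=False))
```

```
 metric gene_group level group_a group_b        z        p_adj
hill_q1    acetate genus    even  uneven 8.617275 6.856641e-18
hill_q1   butyrate genus    even  uneven 8.617275 6.856641e-18
hill_q1 propionate genus    even  uneven 8.617275 6.856641e-18
```

The even population's median effective number of common genera is ~18.2
versus ~6.4 in the uneven one (same richness, pool size 20), and every
pairwise Dunn contrast is flagged after FDR adjustment — the generated
evenness shift is recovered as a genus-level Hill-number difference, which
is exactly how differing resilience profiles surface in real cohorts.

The same analysis runs from the shell:

```sh
scfa-resilience simulate --preset evenness-shift --seed 42 --out sim/
scfa-resilience analyze --table sim/stratified_table.tsv \
    --metadata sim/metadata.tsv --levels genus,species --out analysis/
scfa-resilience figures --table sim/stratified_table.tsv \
    --metadata sim/metadata.tsv --out figs/
```

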