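# Methods

## Stratified tables and normalization

The unit of input is a stratified gene-family table: rows are features
(`<gene_id>: <gene name>` optionally followed by `|` and a rank-prefixed
lineage such as `g__Clostridium.s__Clostridium_butyricum`, or the literal
`unclassified`), columns are samples, values are RPK (reads per kilobase)
abundances.  A single `UNMAPPED` row (also recognized in the variant
spelling `UNAMAPPED`, case-insensitively) carries reads matched to no gene.
Lineages may have gaps — a stratum can name a species without a genus — and
such gaps are preserved verbatim, never imputed; what happens to them is
decided at collapse time.

Normalization rescales each sample so its grand total equals 10⁶
("copies per million").  The denominator includes `UNMAPPED` and all
stratified gene rows; per-gene community-total rows are excluded when the
gene also has stratified rows (they duplicate the same mass) and included
otherwise.  The mapped fraction is then (total − UNMAPPED)/total.
Normalization is idempotent and preserves all within-sample ratios.

Strict validation (community total = sum of strata, relative tolerance
10⁻⁶) is on for synthetic tables and off by default for foreign files,
which can carry rounding drift.

## Gene groups and collapsing

SCFA groups are defined by exact annotation-name matching after case and
whitespace folding (acetate = acetate kinase; butyrate = butyrate kinase +
butyryl-CoA:acetate CoA transferase; propionate = methylmalonyl-CoA
decarboxylase + lactoyl-CoA dehydratase + CoA-dependent propionaldehyde
dehydrogenase).  Exact matching avoids false substring hits (e.g.
"phosphoacetate kinase homolog"); a regex escape hatch exists for keyword
workflows, since annotation databases are not consistent about name forms.

Collapsing to a rank sums every stratum that names a taxon at that rank
into that taxon, across member genes and deeper strata.  Strata lacking a
name at the rank — including per-gene `unclassified` remainders — accrue to
an `UNCLASSIFIED_AT_LEVEL` bucket.  The bucket participates in
mass-conservation checks (column sums are conserved exactly) but never
counts as a taxon in diversity metrics.  Samples whose classified group
abundance is zero at a level are flagged *missing* rather than assigned
zero diversity, and are dropped listwise per metric in the group tests —
which is why per-group n is reported with every comparison.

## Diversity metrics

Hill numbers are computed directly (natural logarithm; q = 1 as
exp(−Σ p ln p), not as a numeric limit), restricted to orders {0, 1, 2}.
Presence is strictly abundance > 0 with no minimum-abundance filter.
Gini-Simpson is 1 − Σ p² = 1 − 1/^2^D.

Faith's PD defaults to the **rooted** convention: the branch length of the
minimal subtree connecting the present leaves *to the root*, so a single
present taxon contributes its full root path.  The **crown** convention
(subtree below the MRCA of the present leaves; 0 for a single leaf) is
available via `convention="crown"`.  Taxon names are matched to tree leaves
after case folding and space/underscore normalization.  Taxa present in a
matrix but absent from the tree are excluded from PD with a logged count —
proxy 16S trees routinely miss taxa — and are never dropped from the other
metrics.

## Bias statistics

The classified fraction at rank r is the abundance of strata naming a taxon
at r divided by the sample's total gene abundance (UNMAPPED excluded,
unclassified included).  "Naming a taxon at r" ignores gaps at other ranks;
this is what allows the genus:species mapping index (species-attributed
over genus-attributed abundance) to exceed 1 when species-only strata
exist.  For per-SCFA scopes the default denominator is the group's own
abundance; a whole-metagenome denominator is available by passing the full
table as the scope.  Indices are computed per sample and their
distributions compared across groups, not pooled across samples.

## Group statistics

Kruskal–Wallis uses mid-ranks with tie correction and the chi-squared
approximation with k − 1 degrees of freedom regardless of n (group sizes in
the intended use are ≥ ~20); an exact-permutation variant (total n ≤ 12)
exists mainly to back the test oracles.  Dunn's post-hoc test is the
tie-corrected, two-sided, pooled-rank formulation:
z = (R̄_i − R̄_j) / √[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i + 1/n_j)] with
T = t³ − t per tie group.  Benjamini–Hochberg adjustment is applied within
each (gene group × level × metric) family of pairwise tests by default; a
global scope is available, and the scope identifier is recorded in every
output row because the choice of family is a genuine analysis decision with
no single right answer.

## Synthetic cohorts

The generator emulates the statistical structure of real stratified tables,
not the sequencing process.  Per population and gene group: per-sample
taxon proportions ~ symmetric Dirichlet(α) over a fixed (genus, species)
pool; per-sample group totals ~ lognormal parametrized by arithmetic mean
(CPM scale) and log-dispersion σ; the group total is split between member
genes by fixed proportions.  Annotation dropout is applied independently
per stratum × sample cell: with probability `m_genus` the whole lineage is
erased (cell becomes `unclassified`), otherwise with probability
`m_species` the species rank is erased.  Masking moves abundance between
rows without arithmetic on it, so conservation is exact.  Finally an
`UNMAPPED` row is added so the unmapped share equals `u` exactly.
Expected bias statistics follow directly: classified fraction at genus =
1 − m_genus, at species = (1 − m_genus)(1 − m_species), mapping index =
1 − m_species.

What the generator does **not** emulate: read-count noise (proportions are
continuous, so richness equals pool size when α is moderate), gene-length
effects, correlated taxon abundances across gene groups, compositional
coupling between SCFA groups, or taxonomy errors other than rank erasure.
Passing tests therefore demonstrate that the pipeline recovers known
ecological and bias parameters from correctly structured tables — not that
it is robust to profiling-software artefacts.

### Presets

- **null** — two identical populations (n = 50 each; α = 1; pools of
  15/12/10 genera for acetate/butyrate/propionate; u = 0.30;
  m_species = 0.3, m_genus = 0.2). Used for type-I-error calibration.
- **evenness-shift** — same 20-genus pools, α = 5 vs 0.2, no masking.
  The even population has higher Hill 1 and 2 at identical richness.
- **bias-shift** — identical ecology, m_species = 0.1 vs 0.6 (m_genus = 0):
  a pure database-bias contrast with no ecological difference.
- **congeneric-species** — 4 genera × 6 species vs 12 genera × 1 species,
  with a bundled newick tree placing congeners on short terminal branches
  (0.02) inside genus clades (stem 0.49) and dispersed species on long
  (0.51) branches: species richness dissociates from PD.
- **lifestyle** — five populations with the paper-style design
  (industrial EU/NA n = 114, industrial C/E-Asia n = 96, pastoral n = 50,
  rural-agricultural n = 140, hunter-gatherer n = 51; total 451).
  Industrial pools are congeneric-heavy (*Bacteroides*, *Clostridium*) with
  low genus evenness (α = 0.3), mild dropout (m_genus = 0.2,
  m_species = 0.06) and u = 0.25; non-industrial pools are dispersed
  single-species genera (*Prevotella*, *Faecalibacterium*, ...) with high
  evenness (α = 1–2.5), strong dropout (up to m_genus = 0.45,
  m_species = 0.5) and u = 0.35.  Group mean totals are set so the overall
  acetate:butyrate:propionate composition is ≈ 0.60 : 0.215 : 0.185, the
  mapped fraction ≈ 75% (industrial) vs ≈ 65% (non-industrial), and the
  species-classified fraction ≈ 75% vs ≈ 27% — the descriptive regime of
  published global gut-metagenome panels.  These are generator *inputs*;
  the acceptance script measures them back through the analysis pipeline.

Randomness: one user seed feeds a `numpy.random.SeedSequence`, spawned once
per population, so populations are independent and reproducible
module-by-module.

## Numerical choices and conventions

- All-zero abundance vectors yield NaN metrics and a missing flag, never 0.
- Mass-conservation assertions use relative tolerance 10⁻⁹; IO round trips
  write full float precision by default (significant-digit formatting is
  opt-in), so read(write(T)) is exact.
- Identical pooled data short-circuits KW/Dunn to (H = 0, p = 1) rather than
  dividing by a zero tie-correction.
- Exact-permutation p-values count permutations with H ≥ H_obs − 10⁻¹²
  to absorb floating-point ties.

## Problem sizes used in the checks

Calibration and recovery checks run at the preset sizes (50 samples per
population): 1000 replicates for the null rejection rate, 100 for the
evenness-shift detection rate (50 in the acceptance script), and single
cohorts elsewhere.  These sizes give Monte-Carlo standard errors well below
the decision margins (e.g. ±0.007 on a 5% rejection rate) while keeping the
default test run fast.

## Known limitations

- Diversity is computed on relative contributions within a gene group;
  absolute production capacity is out of scope, as are rarefaction,
  coverage-based richness estimators and beta diversity.
- The Dunn variant and the FDR family scope are analysis choices; other
  software may default differently, so both are recorded in the outputs.
- Tree construction is not provided — the phylogeny is an input, and PD
  inherits whatever bias the proxy tree carries.
- The generator's masking model is independent per cell; real annotation
  dropout is correlated by taxon and database version.
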