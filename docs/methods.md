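# Methods

## Coordinate and mapping conventions

All intervals are held 1-based inclusive (the GFF3 convention); the BED
reader converts `[chromStart, chromEnd)` to `[chromStart+1, chromEnd]` and
the writer inverts it, so lengths are preserved and the conversion is
self-inverse. The genic region is the full TSS-to-gene-end span with no
exon structure; a read is assigned to a gene when the intervals share at
least `min_overlap` bases (default 50). A read overlapping several genes
counts for each of them — per-gene read counts carry no exclusivity rule.
Raising `min_overlap` can only remove assignments (tested property).

The promoter is the fixed-length window (default 1000 bp) immediately
upstream of the TSS. The 50-base cutoff is applied to genic mapping only;
promoter mapping defaults to `min_overlap = 1` ("falling in" the window),
configurable up to 50. Promoter windows are strand-aware — upstream of the
TSS is left of `start` for `+` genes and right of `end` for `-` genes —
because "upstream of the TSS" is strand-defined; `ignore_strand=True`
reproduces a strand-naive reading. A window truncated at chromosome
position 1 is flagged; a gene starting at position 1 has a degenerate
(empty) window. Windows abut but never intersect their own gene. The
TSS-proximal sub-windows (first 1000 genic bases, first 200 upstream
bases) inherit the thresholds of their parent regions and are, by
construction, subsets of the parent assignments.

## Cluster algebra

Cluster membership is purely rule-based: E requires ≥ 1 of {genic read,
promoter read, miRNA target, chromatin-gene membership}; NE is its
complement within D; DU/DD and the leaves EU/ED/NEU/NED come from the
regulation direction. Classification is idempotent and the partition
identities are validated (not merely assumed) after every run.

Genes reported with conflicting directions by different source studies are
kept in D (and E/NE) but excluded from DU/DD and the leaves, with a logged
count; the validator accounts for them explicitly
(n(DU)+n(DD)+n_conflict = n(D)). Exclusion is conservative and visible;
the synthetic generator emits one direction per gene, so on generated data
the strict identities hold. When a gene carries several fold changes, the
maximum absolute value is used (configurable to the mean).

Published per-cluster tables are internally inconsistent about n(DD)
(3080 in the TF table vs 3238 in the Pfam table for the same clustering);
this package enforces the tree algebra, under which DD = D − DU, and both
published values are used only as fixed inputs to the arithmetic-reporting
checks.

## Background sampling and the Monte Carlo z

The eligible pool excludes TE-related genes and pseudogenes but retains
the DRGs themselves, so a random draw honestly reflects their genome-wide
prevalence (a size-5000 draw from a pool that is 15% DRGs contains ~15%
DRGs, a tested sampling-distribution property). The enrichment z for a
feature in a query set of size n is

    z = (observed − mean_B) / sd_B,

with mean and sd (B−1 denominator) over B seeded draws of size n from the
pool, B = 1000 by default, and a two-sided normal p. If the null sd is 0
(feature saturating the pool) the result is flagged degenerate rather than
given an infinite z. The closed-form binomial z,
`(obs − n·p0)/√(n·p0(1−p0))`, is computed alongside as a cross-check; it
uses with-replacement variance, so the Monte Carlo z converges to the
binomial z divided by the finite-population correction
`√((N−n)/(N−1))` — the two agree closely whenever n ≪ N.

The published analysis pairs "z-score 2.58" with "p < 0.05", which does not
match a two-sided normal (2.58 ↔ p ≈ 0.01); significance thresholds are
therefore configuration, not hard-coded constants, and tests use the
conventional 1.96 two-sided criterion.

## Term enrichment

GO (and any other term) enrichment is a one-sided Fisher exact test:
hypergeometric upper-tail probability of observing ≥ k annotated genes in
the query given the background margins. "Fisher t-test" in the source
description is read as Fisher's exact test — the test the referenced
enrichment service actually performs. Terms with fewer than `min_mapped`
(default 5) annotated genes in the *query* are removed before testing, and
Benjamini–Yekutieli adjustment runs across the surviving terms of that one
query set only (no cross-cluster pooling). BY rather than BH because GO
terms are strongly dependent; BY is valid under arbitrary dependence, at
the price of the harmonic-number inflation c(m). Annotations are used as
given, with no propagation to ancestor terms.

## G statistic

`G = 2·Σ O·ln(O/E)` with `0·ln(0) = 0`, margins-based expectations, p from
chi-square with 1 df, and no Williams or continuity correction by default
(Williams is available as a flag). The 2×2 contrast for domain analyses is
(genes with ≥ 1 Pfam domain vs without) × (in cluster vs its complement
within D). On the published counts the canonical formula gives 51.96
(E vs NE) and 13.31 (DU vs DD) where the study prints 51.4 and 13.1 — a
~1–1.5% discrepancy whose origin (possibly a correction variant or
slightly different margins) is not recoverable; the package reports the
canonical values.

## PPI degrees

Only edges with *both* endpoints inside the cluster and a combined score
passing the threshold are counted, matching the within-cluster phrasing of
the source analysis. Edges are undirected, self-loops dropped, duplicate
and reversed pairs collapsed at read time. The published "combined score
p-value < 0.04" is ambiguous (combined scores are confidences, not
p-values), so the comparison direction is an explicit configuration choice
(`score_direction: ge|le`); the pipeline default is `ge 0.4`, the
conventional medium-confidence score reading. Top-k genes are ranked by
degree with ties broken lexicographically for determinism.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 2000 genes on 4 chromosomes, 400 DRGs, 2500 reads of
75 bp). Genes are placed sequentially with exponential intergenic gaps
(mean 3 kb, minimum 1.1 kb so a promoter window never reaches the upstream
neighbour) and lognormal lengths (mean 3 kb). 30% of gene models are
TE-related and 2% pseudogenes, approximating the rice annotation's
composition; DRGs are drawn from the remainder, 44% upregulated.

Feature planting is per-gene Bernoulli on presence with counts
1 + geometric(0.6) for positive genes, so presence/absence statistics and
multiplicity histograms are both non-trivial. Base rates and DRG
enrichment factors default to `genic 0.20 × 1.3`, `promoter 0.08 × 1.6`,
`mirna 0.12 × 2.7`, `chromdb 0.02 × 1.75`. The miRNA pair matches the
published prevalence contrast (~32% of DRGs vs 12% of random genes); the
remaining factors are calibration choices — the source reports
significance but no effect sizes for them — set so the default bundle
reproduces the qualitative regime of a strong miRNA signal and modest
methylation signals at n = 400. Planted reads fall entirely inside their
target region; leftover reads up to `n_reads` are uniform positional
noise. Fold changes are lognormal with direction-dependent parameters
(mean |FC| ≈ 12 up, ≈ 3 down, matching the published leaf-cluster
averages); the single-(μ,σ) alternative cannot express the planted
up-vs-down ordering the cluster summaries are tested against. GO terms are
random gene sets (5–60 genes) plus 3 spiked terms per leaf cluster (70%
of members drawn from the cluster). PPI edges are Erdős–Rényi within the
down-regulated (density 0.02) and up-regulated (0.006) DRG sets plus a
sparse genome-wide background (5·10⁻⁴), reproducing the published
pattern of denser interaction among downregulated genes.

Each table draws from its own seed substream (`default_rng([seed, k])`
with fixed per-table k), so identical seeds give byte-identical bundles
and adding a table never perturbs earlier ones. What the generator does
*not* emulate: sequence content, spatial autocorrelation of chromatin
state, GO-term dependence structure, gene-length/feature correlations
beyond planting, and annotation noise — so passing tests demonstrate
correctness of the machinery and recoverability of planted effects, not
performance on real annotation.

## Numerical and testing choices

Every stochastic operation takes an explicit seed; there is no global
random state. Test problem sizes are chosen to keep the full suite fast
while leaving the checks sharp: oracle equivalence uses 200 random
interval instances and exhaustive hypergeometric enumeration for all
tables with N ≤ 60; null calibration uses 400 seeded rho = 1 bundles
(n = 2000 genes, B = 200 draws) against the exact binomial 99% interval
around 0.05; power checks use 20 seeds at rho_genic = 4. Degenerate cases
(empty clusters, empty partitions, zero-margin tables, saturating
features, windows at chromosome start) return explicit undefined markers
or flagged results rather than silent zeros.

## Known limitations

- Gene-level only: protein models, transcript isoforms and exon structure
  are out of scope; one protein per gene.
- No methylation-level quantification — reads are opaque intervals, there
  is no β-value or C-context calling and no peak calling.
- GO annotations are taken as given (no graph propagation), so enrichment
  p-values are not comparable to tools that propagate to ancestors.
- The Monte Carlo z relies on a normal tail for its p-value; for very
  small query sets the discrete null makes the p approximate (the z itself
  is exact given the draws).
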