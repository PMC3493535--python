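# drgepi

Integrative epigenetic and miRNA characterization of drought-responsive
gene (DRG) sets in a plant genome.

Large compendia of drought-responsive genes exist for rice, but how much of
that transcriptional response sits under epigenetic (DNA methylation) and
post-transcriptional (miRNA) control is not visible from expression data
alone. `drgepi` overlays a DRG list with genome-wide methylation-read
intervals, miRNA→target predictions and chromatin-associated-protein
annotations, partitions the DRGs into nine rule-based clusters, and asks —
with explicit, reproducible statistics — which molecular features are
enriched where.

## What it computes

1. **Feature mapping.** A methylation read is *genic* for a gene when their
   intervals share ≥ 50 bases (1-based inclusive) anywhere between the
   transcriptional start site (TSS) and the gene end, and a *promoter* read
   when it falls in the 1 kb window immediately upstream of the TSS
   (strand-aware; threshold 1 base by default). Per-gene profiles also
   count TSS-proximal reads (first 1 kb of the gene, first 200 bp of the
   promoter), miRNA targets and chromatin-gene membership.
2. **Clustering.** Every DRG is in cluster **D**; DRGs carrying ≥ 1
   epigenetic/miRNA feature form **E**, the rest **NE**; crossing with the
   regulation direction gives **DU/DD** and the four exclusive leaves
   **EU, ED, NEU, NED**. The partition algebra
   (n(DU)+n(DD) = n(E)+n(NE) = n(D), leaves summing to D) is validated on
   every run.
3. **Enrichment statistics.**
   - Monte Carlo z-score: observed feature count in the DRG set versus B
     size-matched random draws from the non-TE, non-pseudogene gene pool
     (DRGs stay in the pool), `z = (obs − mean_B)/sd_B`, with a closed-form
     binomial z as cross-check.
   - One-sided Fisher exact (hypergeometric) GO-term enrichment per
     cluster, Benjamini–Yekutieli FDR (`adj_(i) = min_{j≥i} p_(j)·m·c(m)/j`,
     `c(m) = Σ 1/k`), with a minimum-mapping-entries filter (default 5).
   - Likelihood-ratio G statistic `G = 2·Σ O·ln(O/E)` for 2×2 contrasts
     such as Pfam-bearing × cluster membership.
4. **Characterization.** TF-family / Pfam / pathway distributions across
   the nine clusters, within-cluster PPI degree summaries after combined-
   score filtering, four-set Venn region counts, and a consolidated
   leaf-cluster summary table.

A first-class synthetic-data generator (`drgepi.simulate`) emits every
input table with planted, recoverable enrichment factors and ground truth,
so the whole pipeline runs and is tested without any external download.

## Worked example

```bash
drgepi run --seed 9 --out out/ --draws 200
```

simulates a 2000-gene genome with 400 DRGs at the default study
conditions, maps 2500 reads, classifies and characterizes. Key output
`out/enrichment_z.tsv`:

```
feature   observed  target_size  bg_mean  bg_sd  z      z_binomial
genic     169       400          157.68   7.805  1.450  1.131
promoter  91        400          86.005   6.823  0.732  0.587
mirna     114       400          69.475   6.349  7.013  5.838
chromdb   12        400          8.710    2.563  1.284  1.201
```

114 of 400 DRGs are miRNA targets against a null expectation of ~69.5 —
the planted 2.7-fold miRNA-target enrichment is recovered at z ≈ 7.0
(the modest planted genic/chromdb factors sit near the detection
threshold at this sample size, as intended). `out/fold_change_summary.tsv`
shows the planted regulation asymmetry: mean |fold change| ≈ 12.5 in the
upregulated clusters (DU, EU, NEU) versus ≈ 3 in the downregulated ones.
Cluster sizes obey the partition algebra exactly (here D = 400 =
166 DU + 234 DD = 283 E + 117 NE).

Every stage is also exposed separately (`drgepi simulate`, `map-features`,
`classify`, `enrich`, `characterize`) and as library functions
(`drgepi.map_reads_to_genic`, `drgepi.mc_enrichment_z`, …).

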