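"""Synthetic input bundles with planted, recoverable enrichments.

The generator emits every table the pipeline consumes — gene models, a DRG
table, methylation-read intervals, miRNA-target / chromatin-gene / TF /
Pfam / pathway / GO annotation pairs and a scored PPI edge list — from one
seed, together with the planted ground truth.

Planting model: each epigenetic feature is per-gene Bernoulli on "carries
at least one instance", with a base rate for non-DRGs and ``min(1, rho ·
base)`` for DRGs; instance counts for positive genes are 1 + geometric, so
multiplicity histograms are non-trivial. Genes are laid out sequentially
per chromosome with exponential intergenic gaps (minimum 1.1 kb, so a
promoter window never reaches the upstream neighbour); planted reads fall
entirely inside their target region and noise reads are placed uniformly.
Each table draws from its own seed substream, so adding a table never
perturbs the ones before it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DRG_COLUMNS, GENE_COLUMNS, PAIR_COLUMNS, READ_COLUMNS

# substream indices, fixed forever (append-only)
_STREAMS = {
    "genome": 0, "drg": 1, "genic_reads": 2, "promoter_reads": 3,
    "noise_reads": 4, "mirna": 5, "chromdb": 6, "go": 7,
    "tf": 8, "pfam": 9, "pathway": 10, "ppi": 11,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Base rates and enrichment factors are per-gene presence probabilities:
    a non-DRG carries >=1 instance of a feature with probability ``base_*``
    and a DRG with probability ``min(1, rho_* · base_*)``. Defaults mirror
    a rice-like regime at desk scale: ~30% TE-related gene models, DRGs
    about a fifth of the eligible genes with ~44% upregulated, a modest
    genic-methylation enrichment, a strong miRNA-target enrichment
    (roughly 32% of DRGs vs 12% of random genes), and denser PPIs among
    downregulated genes.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    te_fraction: float = 0.30
    pseudo_fraction: float = 0.02
    n_drg: int = 400
    up_fraction: float = 0.44
    n_reads: int = 2500
    read_length: int = 75
    mean_gene_len: float = 3000.0
    gene_len_sigma: float = 0.6
    mean_gap: float = 3000.0
    rho_genic: float = 1.3
    rho_promoter: float = 1.6
    rho_mirna: float = 2.7
    rho_chromdb: float = 1.75
    base_genic: float = 0.20
    base_promoter: float = 0.08
    base_mirna: float = 0.12
    base_chromdb: float = 0.02
    multi_geom_p: float = 0.6
    fc_up_lognormal: tuple = (2.1, 0.9)    # mean |FC| ~ 12
    fc_down_lognormal: tuple = (1.0, 0.5)  # mean |FC| ~ 3
    n_mirnas: int = 300
    n_go_terms: int = 150
    go_term_size: tuple = (5, 60)
    go_spike_per_cluster: int = 3
    go_spike_size: int = 30
    go_spike_purity: float = 0.7
    n_tf_families: int = 30
    tf_fraction: float = 0.045
    rho_tf: float = 1.9
    n_pfam_families: int = 120
    pfam_fraction: float = 0.60
    rho_pfam: float = 1.3
    n_pathways: int = 60
    pathway_fraction: float = 0.15
    ppi_density_down: float = 0.020
    ppi_density_up: float = 0.006
    ppi_density_bg: float = 0.0005
    seed: int = 0

    def validate(self):
        for name in ("te_fraction", "pseudo_fraction", "up_fraction", "base_genic",
                     "base_promoter", "base_mirna", "base_chromdb", "go_spike_purity",
                     "tf_fraction", "pfam_fraction", "pathway_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rho_genic", "rho_promoter", "rho_mirna", "rho_chromdb",
                     "rho_tf", "rho_pfam", "ppi_density_down", "ppi_density_up",
                     "ppi_density_bg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_eligible = int(round(self.n_genes * (1.0 - self.te_fraction - self.pseudo_fraction)))
        if self.n_drg > n_eligible:
            raise ValueError(
                f"n_drg={self.n_drg} exceeds the ~{n_eligible} eligible "
                "(non-TE, non-pseudogene) genes implied by the fractions"
            )
        if self.n_genes < 1 or self.n_chroms < 1 or self.read_length < 1:
            raise ValueError("n_genes, n_chroms and read_length must be positive")


@dataclass
class GroundTruth:
    """Planted truth for one bundle, recomputable from the emitted tables."""

    drg_ids: list
    up_ids: list
    down_ids: list
    rho: dict
    base: dict
    planted_counts: dict          # feature -> {gene_id: instance count}
    spiked_go_terms: dict         # leaf cluster -> [term ids]
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), _STREAMS[stream]])


def _simulate_genes(cfg: SimConfig) -> pd.DataFrame:
    rng = _rng(cfg, "genome")
    mu = np.log(cfg.mean_gene_len) - cfg.gene_len_sigma**2 / 2.0
    lengths = np.maximum(200, rng.lognormal(mu, cfg.gene_len_sigma, cfg.n_genes)).astype(np.int64)
    chroms = np.sort(rng.integers(1, cfg.n_chroms + 1, cfg.n_genes))
    # min gap 1.1 kb keeps promoter windows clear of the upstream neighbour
    gaps = (1100 + rng.exponential(cfg.mean_gap, cfg.n_genes)).astype(np.int64)
    strands = rng.choice(["+", "-"], cfg.n_genes)
    roles = rng.permutation(
        np.array(
            ["te"] * int(round(cfg.n_genes * cfg.te_fraction))
            + ["pseudo"] * int(round(cfg.n_genes * cfg.pseudo_fraction))
            + ["ok"] * (cfg.n_genes
                        - int(round(cfg.n_genes * cfg.te_fraction))
                        - int(round(cfg.n_genes * cfg.pseudo_fraction)))
        )
    )
    rows, cursor, prev_chrom = [], 0, None
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        chrom = f"chr{chroms[i]}"
        if chrom != prev_chrom:
            cursor, prev_chrom = 0, chrom
        start = cursor + int(gaps[i])
        end = start + int(lengths[i]) - 1
        cursor = end
        rows.append((
            f"g{str(i).zfill(width)}", chrom, start, end, strands[i],
            roles[i] == "te", roles[i] == "pseudo",
        ))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _simulate_drgs(cfg: SimConfig, genes: pd.DataFrame):
    rng = _rng(cfg, "drg")
    eligible = genes.loc[~(genes["is_te"] | genes["is_pseudogene"]), "gene_id"].to_numpy()
    drg_ids = np.sort(rng.choice(eligible, size=cfg.n_drg, replace=False))
    is_up = rng.random(cfg.n_drg) < cfg.up_fraction
    mu_u, sg_u = cfg.fc_up_lognormal
    mu_d, sg_d = cfg.fc_down_lognormal
    fc = np.where(is_up, rng.lognormal(mu_u, sg_u, cfg.n_drg), rng.lognormal(mu_d, sg_d, cfg.n_drg))
    drgs = pd.DataFrame({
        "gene_id": drg_ids,
        "direction": np.where(is_up, "up", "down"),
        "fold_change": np.round(fc, 4),
        "source": "sim",
    })[DRG_COLUMNS]
    return drgs


def _plant_presence(rng, gene_ids, drg_set, base, rho, geom_p):
    """Per-gene planted instance counts: Bernoulli presence then 1+geometric."""
    p = np.array([min(1.0, rho * base) if g in drg_set else base for g in gene_ids])
    present = rng.random(len(gene_ids)) < p
    counts = np.where(present, rng.geometric(geom_p, len(gene_ids)), 0)
    return {g: int(c) for g, c in zip(gene_ids, counts) if c > 0}


def _place_reads(rng, genes_by_id, counts, read_len, region, prefix):
    """Place reads fully inside the target region of each positive gene."""
    rows = []
    k = 0
    for g in sorted(counts):
        row = genes_by_id[g]
        if region == "genic":
            lo, hi = row.start, row.end
        else:  # promoter window
            if row.strand == "+":
                lo, hi = max(1, row.start - 1000), row.start - 1
            else:
                lo, hi = row.end + 1, row.end + 1000
        span = hi - lo + 1
        if span < read_len:
            continue
        for _ in range(counts[g]):
            s = lo + int(rng.integers(0, span - read_len + 1))
            rows.append((f"{prefix}{k}", row.chrom, s, s + read_len - 1))
            k += 1
    return rows


def _simulate_reads(cfg: SimConfig, genes: pd.DataFrame, drg_set):
    genes_by_id = {r.gene_id: r for r in genes.itertuples(index=False)}
    gene_ids = genes["gene_id"].tolist()

    rng_g = _rng(cfg, "genic_reads")
    genic_counts = _plant_presence(rng_g, gene_ids, drg_set, cfg.base_genic,
                                   cfg.rho_genic, cfg.multi_geom_p)
    rows = _place_reads(rng_g, genes_by_id, genic_counts, cfg.read_length, "genic", "rg")

    rng_p = _rng(cfg, "promoter_reads")
    prom_counts = _plant_presence(rng_p, gene_ids, drg_set, cfg.base_promoter,
                                  cfg.rho_promoter, cfg.multi_geom_p)
    rows += _place_reads(rng_p, genes_by_id, prom_counts, cfg.read_length, "promoter", "rp")

    rng_n = _rng(cfg, "noise_reads")
    n_noise = max(0, cfg.n_reads - len(rows))
    chrom_len = genes.groupby("chrom")["end"].max().to_dict()
    chrom_names = sorted(chrom_len)
    for k in range(n_noise):
        chrom = chrom_names[int(rng_n.integers(0, len(chrom_names)))]
        s = 1 + int(rng_n.integers(0, max(1, chrom_len[chrom] - cfg.read_length)))
        rows.append((f"rn{k}", chrom, s, s + cfg.read_length - 1))
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return reads, genic_counts, prom_counts


def _pairs(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.drop_duplicates(["subject_id", "gene_id", "kind"]).sort_values(
        ["subject_id", "gene_id"]).reset_index(drop=True)


def _simulate_mirna(cfg: SimConfig, gene_ids, drg_set):
    rng = _rng(cfg, "mirna")
    counts = _plant_presence(rng, gene_ids, drg_set, cfg.base_mirna,
                             cfg.rho_mirna, cfg.multi_geom_p)
    rows = []
    for g in sorted(counts):
        picks = rng.choice(cfg.n_mirnas, size=min(counts[g], cfg.n_mirnas), replace=False)
        rows += [(f"mir{int(m):04d}", g, float("nan"), "mirna_target") for m in picks]
    return _pairs(rows), counts


def _simulate_chromdb(cfg: SimConfig, gene_ids, drg_set):
    rng = _rng(cfg, "chromdb")
    counts = _plant_presence(rng, gene_ids, drg_set, cfg.base_chromdb, cfg.rho_chromdb, 1.0)
    rows = [(f"CAP{i:04d}", g, float("nan"), "chromdb") for i, g in enumerate(sorted(counts))]
    return _pairs(rows), counts


def _leaf_of(gene, drg_dir, feature_positive):
    if gene not in drg_dir:
        return None
    has = gene in feature_positive
    if drg_dir[gene] == "up":
        return "EU" if has else "NEU"
    return "ED" if has else "NED"


def _simulate_go(cfg: SimConfig, gene_ids, leaf_members):
    rng = _rng(cfg, "go")
    rows, spiked = [], {leaf: [] for leaf in ("EU", "ED", "NEU", "NED")}
    arr = np.array(gene_ids)
    lo, hi = cfg.go_term_size
    for t in range(cfg.n_go_terms):
        size = int(rng.integers(lo, hi + 1))
        picks = rng.choice(arr, size=min(size, len(arr)), replace=False)
        rows += [(f"GO:{t:07d}", g, float("nan"), "go") for g in picks]
    t = cfg.n_go_terms
    for leaf in ("EU", "ED", "NEU", "NED"):
        members = np.array(sorted(leaf_members[leaf]))
        for _ in range(cfg.go_spike_per_cluster):
            term = f"GO:{t:07d}"
            n_in = min(int(round(cfg.go_spike_size * cfg.go_spike_purity)), len(members))
            n_out = cfg.go_spike_size - n_in
            picks = list(rng.choice(members, size=n_in, replace=False)) if n_in else []
            picks += list(rng.choice(arr, size=n_out, replace=False))
            rows += [(term, g, float("nan"), "go") for g in picks]
            spiked[leaf].append(term)
            t += 1
    return _pairs(rows), spiked


def _simulate_family(cfg: SimConfig, rng, gene_ids, drg_set, n_families, fraction, rho,
                     prefix, kind, multi_geom_p=1.0):
    counts = _plant_presence(rng, gene_ids, drg_set, fraction, rho, multi_geom_p)
    rows = []
    for g in sorted(counts):
        picks = rng.choice(n_families, size=min(counts[g], n_families), replace=False)
        rows += [(f"{prefix}{int(f):04d}", g, float("nan"), kind) for f in picks]
    return _pairs(rows), counts


def _simulate_ppi(cfg: SimConfig, gene_ids, up_ids, down_ids):
    rng = _rng(cfg, "ppi")
    rows = []

    def _er_edges(members, density, tag):
        members = sorted(members)
        m = len(members)
        n_pairs = m * (m - 1) // 2
        if n_pairs == 0 or density <= 0:
            return
        n_edges = int(rng.binomial(n_pairs, min(1.0, density)))
        seen = set()
        while len(seen) < n_edges:
            i, j = rng.integers(0, m, 2)
            if i == j:
                continue
            a, b = (members[i], members[j]) if members[i] < members[j] else (members[j], members[i])
            seen.add((a, b))
        for a, b in sorted(seen):
            rows.append((a, b, round(float(rng.uniform(0.15, 0.999)), 3), "ppi_edge"))

    _er_edges(down_ids, cfg.ppi_density_down, "down")
    _er_edges(up_ids, cfg.ppi_density_up, "up")
    _er_edges(gene_ids, cfg.ppi_density_bg, "bg")
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    df = df.sort_values("score").drop_duplicates(["subject_id", "gene_id"], keep="last")
    return df.sort_values(["subject_id", "gene_id"]).reset_index(drop=True)


def simulate_dataset(config: SimConfig):
    """Generate one complete input bundle and its ground truth.

    Returns ``(bundle, truth)`` where ``bundle`` maps table names
    (genes, drgs, reads, mirna, chromdb, go, tf, pfam, pathway, ppi) to
    canonical DataFrames and ``truth`` is a :class:`GroundTruth`.
    Identical config (including seed) gives a byte-identical bundle.
    """
    config.validate()
    genes = _simulate_genes(config)
    drgs = _simulate_drgs(config, genes)
    drg_set = set(drgs["gene_id"])
    drg_dir = dict(zip(drgs["gene_id"], drgs["direction"]))
    up_ids = sorted(drgs.loc[drgs["direction"] == "up", "gene_id"])
    down_ids = sorted(drgs.loc[drgs["direction"] == "down", "gene_id"])
    gene_ids = genes["gene_id"].tolist()

    reads, genic_counts, prom_counts = _simulate_reads(config, genes, drg_set)
    mirna, mirna_counts = _simulate_mirna(config, gene_ids, drg_set)
    chromdb, chromdb_counts = _simulate_chromdb(config, gene_ids, drg_set)

    feature_positive = (set(genic_counts) | set(prom_counts)
                        | set(mirna_counts) | set(chromdb_counts))
    leaf_members = {leaf: set() for leaf in ("EU", "ED", "NEU", "NED")}
    for g in drg_set:
        leaf_members[_leaf_of(g, drg_dir, feature_positive)].add(g)

    go, spiked = _simulate_go(config, gene_ids, leaf_members)
    tf, _ = _simulate_family(config, _rng(config, "tf"), gene_ids, drg_set,
                             config.n_tf_families, config.tf_fraction, config.rho_tf,
                             "TF", "tf_family")
    pfam, _ = _simulate_family(config, _rng(config, "pfam"), gene_ids, drg_set,
                               config.n_pfam_families, config.pfam_fraction, config.rho_pfam,
                               "PF", "pfam", multi_geom_p=config.multi_geom_p)
    pathway, _ = _simulate_family(config, _rng(config, "pathway"), gene_ids, drg_set,
                                  config.n_pathways, config.pathway_fraction, 1.0,
                                  "PWY", "pathway")
    ppi = _simulate_ppi(config, gene_ids, up_ids, down_ids)

    bundle = {
        "genes": genes, "drgs": drgs, "reads": reads, "mirna": mirna,
        "chromdb": chromdb, "go": go, "tf": tf, "pfam": pfam,
        "pathway": pathway, "ppi": ppi,
    }
    truth = GroundTruth(
        drg_ids=sorted(drg_set),
        up_ids=up_ids,
        down_ids=down_ids,
        rho={"genic": config.rho_genic, "promoter": config.rho_promoter,
             "mirna": config.rho_mirna, "chromdb": config.rho_chromdb},
        base={"genic": config.base_genic, "promoter": config.base_promoter,
              "mirna": config.base_mirna, "chromdb": config.base_chromdb},
        planted_counts={"genic": genic_counts, "promoter": prom_counts,
                        "mirna": mirna_counts, "chromdb": chromdb_counts},
        spiked_go_terms=spiked,
        config=dataclasses.asdict(config),
    )
    return bundle, truth


def realized_enrichment(bundle, truth: GroundTruth, feature: str) -> float:
    """Observed DRG vs non-DRG prevalence ratio of a planted feature.

    Prevalence is the fraction of genes with >=1 planted instance. Returns
    ``inf`` when the feature is absent outside the DRGs but present inside
    (unbounded enrichment) and ``nan`` for 0/0.
    """
    if feature not in truth.planted_counts:
        raise ValueError(f"feature {feature!r} not in the bundle's ground truth")
    positive = set(truth.planted_counts[feature])
    drg = set(truth.drg_ids)
    all_genes = set(bundle["genes"]["gene_id"])
    non_drg = all_genes - drg
    p_drg = len(drg & positive) / len(drg) if drg else float("nan")
    p_bg = len(non_drg & positive) / len(non_drg) if non_drg else float("nan")
    if p_bg == 0.0:
        return float("inf") if p_drg > 0 else float("nan")
    return p_drg / p_bg


def write_bundle(bundle, truth: GroundTruth, outdir) -> dict:
    """Write a bundle in its on-disk formats (GFF3, BED, TSV) plus
    truth.json; returns the path map."""
    from pathlib import Path
    from .io import write_gene_models_gff3, write_intervals_bed, write_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_gene_models_gff3(bundle["genes"], out / "genes.gff3")
    paths["genes"] = str(out / "genes.gff3")
    write_intervals_bed(bundle["reads"], out / "reads.bed")
    paths["reads"] = str(out / "reads.bed")
    write_tsv(bundle["drgs"], out / "drgs.tsv")
    paths["drgs"] = str(out / "drgs.tsv")
    for name in ("mirna", "chromdb", "go", "tf", "pfam", "pathway", "ppi"):
        write_tsv(bundle[name], out / f"{name}.tsv")
        paths[name] = str(out / f"{name}.tsv")
    (out / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    paths["truth"] = str(out / "truth.json")
    return paths
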