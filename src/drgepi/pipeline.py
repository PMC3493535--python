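"""End-to-end pipeline: simulate/load → map features → classify → enrich →
characterize, with a YAML-configurable entry point and a run manifest.

All stage outputs are headered TSVs; re-running with the same inputs, config
and seed reproduces them byte-for-byte. The manifest (written last) echoes
the config, records input checksums, per-stage row counts and the package
version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as aio
from .characterize import (cluster_summary_table, family_distribution,
                           four_set_overlap, overlap_counts_table,
                           ppi_degree_summary)
from .clusters import LEAF_LABELS, classify, cluster_members, fold_change_summary, validate_partition
from .mapping import (build_feature_profiles, map_reads_to_genic,
                      map_reads_to_promoters, promoter_windows)
from .simulate import SimConfig, simulate_dataset, write_bundle
from .stats import BackgroundSpec, binomial_z, fisher_term_enrichment, mc_enrichment_z

logger = logging.getLogger("drgepi")


@dataclass
class RunConfig:
    """Everything one pipeline run needs: either input paths or a SimConfig,
    plus every threshold the stages take."""

    out_dir: str = "drgepi_out"
    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # genes/reads/drgs/mirna/chromdb/go/tf/pfam/pathway/ppi
    min_overlap: int = 50
    promoter_len: int = 1000
    promoter_min_overlap: int = 1
    ignore_strand: bool = False
    bg_size: int | None = None   # default: eligible-pool size capped at 5000
    n_draws: int = 1000
    alpha: float = 0.05
    min_mapped: int = 5
    score_threshold: float = 0.4
    score_direction: str = "ge"
    fc_reduce: str = "max"

    REQUIRED_INPUTS = ("genes", "reads", "drgs", "mirna", "chromdb", "go", "tf", "pfam", "pathway", "ppi")

    def validate(self):
        if self.sim is None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ValueError(f"config missing input path(s): {missing}")
        if self.score_direction not in ("ge", "le"):
            raise ValueError("score_direction must be 'ge' or 'le'")

    @classmethod
    def from_yaml(cls, path, **overrides):
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_inputs(config: RunConfig) -> dict:
    """Load the input bundle from disk, or simulate it (writing the bundle
    under ``<out_dir>/inputs`` so the run is re-executable from files)."""
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        bundle, truth = simulate_dataset(sim)
        write_bundle(bundle, truth, Path(config.out_dir) / "inputs")
        return bundle
    paths = config.inputs
    fmt = "gff3" if str(paths["genes"]).endswith((".gff3", ".gff")) else "tsv"
    return {
        "genes": aio.read_gene_models(paths["genes"], format=fmt),
        "reads": aio.read_intervals_bed(paths["reads"]),
        "drgs": aio.read_drg_table(paths["drgs"]),
        "mirna": aio.read_pair_table(paths["mirna"], "mirna_target"),
        "chromdb": aio.read_pair_table(paths["chromdb"], "chromdb"),
        "go": aio.read_pair_table(paths["go"], "go"),
        "tf": aio.read_pair_table(paths["tf"], "tf_family"),
        "pfam": aio.read_pair_table(paths["pfam"], "pfam"),
        "pathway": aio.read_pair_table(paths["pathway"], "pathway"),
        "ppi": aio.read_pair_table(paths["ppi"], "ppi_edge"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all outputs under ``config.out_dir`` and
    return the manifest (also written as ``manifest.json``, last)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_rows: dict[str, int] = {}

    def _fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    try:
        bundle = load_inputs(config)
    except Exception as exc:
        _fail("load-inputs", exc)
    genes, reads, drgs = bundle["genes"], bundle["reads"], bundle["drgs"]
    stage_rows["genes"] = len(genes)
    stage_rows["reads"] = len(reads)
    logger.info("inputs: %d genes, %d reads, %d DRG rows", len(genes), len(reads), len(drgs))

    # --- feature mapping -------------------------------------------------
    try:
        genic = map_reads_to_genic(genes, reads, min_overlap=config.min_overlap)
        windows = promoter_windows(genes, upstream=config.promoter_len,
                                   ignore_strand=config.ignore_strand)
        prom = map_reads_to_promoters(windows, reads, min_overlap=config.promoter_min_overlap)
        profiles = build_feature_profiles(
            genes, genic, prom, bundle["mirna"], bundle["chromdb"], reads=reads,
            min_overlap_genic=config.min_overlap,
            min_overlap_promoter=config.promoter_min_overlap,
            ignore_strand=config.ignore_strand,
        )
    except Exception as exc:
        _fail("map-features", exc)
    aio.write_tsv(profiles, out / "profiles.tsv")
    stage_rows["profiles"] = len(profiles)
    logger.info("map-features: %d genic and %d promoter assignments", len(genic), len(prom))

    # --- classification --------------------------------------------------
    try:
        memberships = classify(drgs, profiles, fc_reduce=config.fc_reduce)
        report = validate_partition(memberships)
        fc_summary = fold_change_summary(memberships, drgs, fc_reduce=config.fc_reduce)
    except Exception as exc:
        _fail("classify", exc)
    aio.write_tsv(memberships, out / "clusters.tsv")
    aio.write_tsv(fc_summary, out / "fold_change_summary.tsv")
    stage_rows["clusters"] = len(memberships)
    if report["n_violations"]:
        logger.warning("partition violations: %s", report["violations"][:5])
    logger.info("classify: %d DRGs, cluster sizes %s", len(memberships), report["sizes"])

    # --- enrichment ------------------------------------------------------
    try:
        pool = frozenset(genes.loc[~(genes["is_te"] | genes["is_pseudogene"]), "gene_id"])
        bg_size = config.bg_size or min(5000, len(pool))
        spec = BackgroundSpec(pool=pool, size=bg_size, n_draws=config.n_draws, seed=config.seed)
        drg_set = set(memberships["gene_id"])
        feature_sets = {
            "genic": set(profiles.loc[profiles["genic_read_count"] >= 1, "gene_id"]),
            "promoter": set(profiles.loc[profiles["promoter_read_count"] >= 1, "gene_id"]),
            "mirna": set(profiles.loc[profiles["mirna_count"] >= 1, "gene_id"]),
            "chromdb": set(profiles.loc[profiles["is_chromdb"], "gene_id"]),
        }
        z_rows = []
        for name, positive in feature_sets.items():
            res = mc_enrichment_z(drg_set, positive, spec)
            chk = binomial_z(drg_set, positive, pool)
            z_rows.append({
                "feature": name, "observed": res.observed, "target_size": res.target_size,
                "bg_mean": round(res.bg_mean, 3), "bg_sd": round(res.bg_sd, 3),
                "z": round(res.z, 3), "p_two_sided": res.p_two_sided,
                "z_binomial": round(chk.z, 3), "degenerate": res.degenerate,
            })
        enrichment_z = pd.DataFrame(z_rows)
        go_results = {}
        for label in ("D", "DU", "DD", "E", "NE") + LEAF_LABELS:
            members = cluster_members(memberships, label)
            if not members:
                continue
            go_results[label] = fisher_term_enrichment(
                members & pool, bundle["go"], pool,
                min_mapped=config.min_mapped, alpha=config.alpha,
            )
    except Exception as exc:
        _fail("enrich", exc)
    aio.write_tsv(enrichment_z, out / "enrichment_z.tsv")
    for label, df in go_results.items():
        aio.write_tsv(df, out / f"go_enrichment_{label}.tsv")
    stage_rows["enrichment_z"] = len(enrichment_z)
    logger.info("enrich: features %s", {r['feature']: r['z'] for r in z_rows})

    # --- characterization ------------------------------------------------
    try:
        tf_dist = family_distribution(memberships, bundle["tf"])
        pfam_dist = family_distribution(memberships, bundle["pfam"])
        pwy_dist = family_distribution(memberships, bundle["pathway"])
        ppi_rows = []
        for leaf in LEAF_LABELS:
            deg = ppi_degree_summary(
                cluster_members(memberships, leaf), bundle["ppi"],
                config.score_threshold, score_direction=config.score_direction, cluster=leaf,
            )
            ppi_rows.append({
                "cluster": leaf, "n_genes": deg.n_genes,
                "n_genes_with_edge": deg.n_genes_with_edge,
                "total_edges_within": deg.total_edges_within,
                "mean_degree_all": round(deg.mean_degree_all, 3),
                "mean_degree_positive": (round(deg.mean_degree_positive, 3)
                                         if deg.n_genes_with_edge else float("nan")),
                "top_genes": ";".join(f"{g}:{d}" for g, d in deg.top_genes),
            })
        ppi_summary = pd.DataFrame(ppi_rows)
        go_sets = {leaf: set(go_results.get(leaf, pd.DataFrame(columns=["term_id", "enriched"]))
                             .query("enriched")["term_id"]) for leaf in LEAF_LABELS}
        pwy_sets = {
            leaf: {f for f, n in zip(pwy_dist["family_id"], pwy_dist[f"n_{leaf}"]) if n > 0}
            for leaf in LEAF_LABELS
        } if len(pwy_dist) else {leaf: set() for leaf in LEAF_LABELS}
        overlap = overlap_counts_table(four_set_overlap(go_sets))
        summary = cluster_summary_table(
            memberships, profiles, drgs, bundle["tf"], bundle["pfam"], bundle["ppi"],
            config.score_threshold, config.score_direction,
            go_terms_by_cluster=go_sets, pathways_by_cluster=pwy_sets,
            fc_reduce=config.fc_reduce,
        )
    except Exception as exc:
        _fail("characterize", exc)
    aio.write_tsv(tf_dist, out / "tf_distribution.tsv")
    aio.write_tsv(pfam_dist, out / "pfam_distribution.tsv")
    aio.write_tsv(pwy_dist, out / "pathway_distribution.tsv")
    aio.write_tsv(ppi_summary, out / "ppi_summary.tsv")
    aio.write_tsv(overlap, out / "overlap_counts.tsv")
    aio.write_tsv(summary, out / "cluster_summary.tsv")
    stage_rows["cluster_summary"] = len(summary)

    # --- manifest (written last) -----------------------------------------
    cfg_echo = dataclasses.asdict(config)
    manifest = {
        "tool": "drgepi",
        "version": __version__,
        "config": cfg_echo,
        "input_checksums": {
            k: _sha256(v) for k, v in (config.inputs or {}).items() if Path(str(v)).exists()
        },
        "stage_row_counts": stage_rows,
        "partition_report": {"n_violations": report["n_violations"], "sizes": report["sizes"]},
        "runtime_seconds": round(time.time() - t0, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str), encoding="utf-8")
    return manifest
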