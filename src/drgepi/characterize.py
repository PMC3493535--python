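"""Per-cluster descriptive analytics.

Distributions of TF families, Pfam domain families and metabolic pathways
across the nine clusters; within-cluster PPI degree summaries after score
filtering; four-set overlap (Venn region) counts; and the consolidated
leaf-cluster summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .clusters import CLUSTER_LABELS, LEAF_LABELS, cluster_members, resolve_drgs

logger = __import__("logging").getLogger("drgepi")


@dataclass
class DegreeSummary:
    cluster: str
    n_genes: int
    n_genes_with_edge: int
    total_edges_within: int
    mean_degree_all: float
    mean_degree_positive: float
    top_genes: list  # [(gene_id, degree)] ranked, ties by gene_id ascending
    degrees: dict    # gene_id -> within-cluster degree


def family_distribution(memberships: pd.DataFrame, pairs: pd.DataFrame,
                        genome_totals: dict | None = None) -> pd.DataFrame:
    """Count member genes of each family (TF family, Pfam family or
    pathway) in each of the nine clusters.

    Percent columns are 100·count/cluster-size rounded to 2 decimals;
    ``percent_drg_of_family`` is the D count over the family's genome-wide
    total (NaN when the total is unknown, with a logged warning).
    """
    kinds = set(pairs["kind"].unique())
    if len(kinds) > 1:
        raise ValueError(f"pairs must be of a single kind, got {sorted(kinds)}")
    kind = kinds.pop() if kinds else ""
    sets = {lab: cluster_members(memberships, lab) for lab in CLUSTER_LABELS}
    genome_totals = genome_totals or {}
    rows = []
    for family, grp in pairs.groupby("subject_id", sort=True):
        genes = set(grp["gene_id"])
        counts = {lab: len(genes & sets[lab]) for lab in CLUSTER_LABELS}
        total = genome_totals.get(family)
        if genome_totals and total is None:
            logger.warning("family %s missing from genome totals", family)
        pct_drg = round(100.0 * counts["D"] / total, 2) if total else float("nan")
        row = {"family_id": family, "kind": kind}
        for lab in CLUSTER_LABELS:
            row[f"n_{lab}"] = counts[lab]
            size = len(sets[lab])
            row[f"pct_{lab}"] = round(100.0 * counts[lab] / size, 2) if size else float("nan")
        row["total_in_genome"] = total if total is not None else pd.NA
        row["percent_drg_of_family"] = pct_drg
        rows.append(row)
    return pd.DataFrame(rows)


def ppi_degree_summary(cluster_genes, edges: pd.DataFrame, score_threshold: float,
                       k: int = 10, score_direction: str = "ge",
                       cluster: str = "") -> DegreeSummary:
    """Within-cluster PPI degree summary after score filtering.

    Only edges with BOTH endpoints in ``cluster_genes`` and a score passing
    the threshold count. ``score_direction="ge"`` keeps scores >= threshold
    (confidence-score reading); ``"le"`` keeps scores <= threshold
    (p-value reading). Top-``k`` genes are ranked by degree, ties broken by
    gene_id ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if score_direction not in ("ge", "le"):
        raise ValueError("score_direction must be 'ge' or 'le'")
    cluster_genes = set(cluster_genes)
    keep = edges["subject_id"].isin(cluster_genes) & edges["gene_id"].isin(cluster_genes)
    if score_direction == "ge":
        keep &= edges["score"] >= score_threshold
    else:
        keep &= edges["score"] <= score_threshold
    graph = nx.Graph()
    graph.add_nodes_from(cluster_genes)
    graph.add_edges_from(edges.loc[keep, ["subject_id", "gene_id"]].itertuples(index=False))
    degrees = {g: int(d) for g, d in graph.degree()}
    n = len(cluster_genes)
    positive = [d for d in degrees.values() if d > 0]
    total_edges = graph.number_of_edges()
    ranked = sorted(degrees.items(), key=lambda gd: (-gd[1], gd[0]))
    return DegreeSummary(
        cluster=cluster,
        n_genes=n,
        n_genes_with_edge=len(positive),
        total_edges_within=total_edges,
        mean_degree_all=(sum(degrees.values()) / n) if n else float("nan"),
        mean_degree_positive=(sum(positive) / len(positive)) if positive else float("nan"),
        top_genes=ranked[:k],
        degrees=degrees,
    )


def four_set_overlap(sets: dict) -> dict:
    """Counts of the 15 exclusive Venn regions of exactly four named sets.

    Returns a map from the sorted tuple of set names defining a region to
    the number of elements exclusive to that region. The region counts sum
    to the size of the union.
    """
    names = list(sets)
    if len(names) != 4 or len(set(names)) != 4:
        raise ValueError("exactly 4 distinct set names required")
    region_counts = {}
    for r in range(1, 5):
        for combo in combinations(sorted(names), r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(*(set(sets[n]) for n in names if n not in combo), set())
            region_counts[combo] = len(inside - outside)
    return region_counts


def overlap_counts_table(region_counts: dict) -> pd.DataFrame:
    rows = [("&".join(combo), n) for combo, n in sorted(region_counts.items())]
    return pd.DataFrame(rows, columns=["region", "n"])


def cluster_summary_table(
    memberships: pd.DataFrame,
    profiles: pd.DataFrame,
    drgs: pd.DataFrame,
    tf_pairs: pd.DataFrame,
    pfam_pairs: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    score_threshold: float,
    score_direction: str = "ge",
    go_terms_by_cluster: dict | None = None,
    pathways_by_cluster: dict | None = None,
    fc_reduce: str = "max",
) -> pd.DataFrame:
    """One consolidated row per leaf cluster (EU, ED, NEU, NED).

    Counts and percents of genes with promoter/genic methylation reads,
    miRNA targets and chromatin-gene membership; genes with >=1
    within-cluster PPI; TF genes; Pfam-bearing genes; mean |fold change|;
    and — when per-cluster GO-term / pathway sets are supplied — the number
    unique to the cluster among the four leaves. Percents are reported to
    1 decimal with raw counts alongside.
    """
    for name, val in [("profiles", profiles), ("memberships", memberships), ("drgs", drgs)]:
        if val is None or len(val) == 0:
            raise ValueError(f"missing upstream output: {name}")
    prof = profiles.set_index("gene_id")
    resolved = resolve_drgs(drgs, fc_reduce=fc_reduce).set_index("gene_id")
    tf_genes = set(tf_pairs["gene_id"])
    pfam_genes = set(pfam_pairs["gene_id"])
    unique_go = _unique_regions(go_terms_by_cluster) if go_terms_by_cluster else None
    unique_pwy = _unique_regions(pathways_by_cluster) if pathways_by_cluster else None

    rows = []
    for leaf in LEAF_LABELS:
        ids = sorted(cluster_members(memberships, leaf))
        n = len(ids)
        sub = prof.loc[prof.index.intersection(ids)]

        def _cp(count: int):
            return count, round(100.0 * count / n, 1) if n else float("nan")

        n_prom, p_prom = _cp(int((sub["promoter_read_count"] >= 1).sum()))
        n_genic, p_genic = _cp(int((sub["genic_read_count"] >= 1).sum()))
        n_mir, p_mir = _cp(int((sub["mirna_count"] >= 1).sum()))
        n_chrom, p_chrom = _cp(int(sub["is_chromdb"].sum()))
        deg = ppi_degree_summary(ids, ppi_edges, score_threshold,
                                 score_direction=score_direction, cluster=leaf)
        n_ppi, p_ppi = _cp(deg.n_genes_with_edge)
        n_tf, p_tf = _cp(len(tf_genes & set(ids)))
        n_pfam, p_pfam = _cp(len(pfam_genes & set(ids)))
        fcs = resolved.loc[resolved.index.intersection(ids), "fold_change"].abs()
        rows.append({
            "cluster": leaf,
            "n_genes": n,
            "mean_abs_fold_change": round(float(fcs.mean()), 2) if len(fcs) else float("nan"),
            "n_promoter_methylated": n_prom, "pct_promoter_methylated": p_prom,
            "n_genic_methylated": n_genic, "pct_genic_methylated": p_genic,
            "n_mirna_target": n_mir, "pct_mirna_target": p_mir,
            "n_chromdb": n_chrom, "pct_chromdb": p_chrom,
            "n_with_ppi": n_ppi, "pct_with_ppi": p_ppi,
            "n_tf": n_tf, "pct_tf": p_tf,
            "n_pfam": n_pfam, "pct_pfam": p_pfam,
            "n_unique_go": unique_go[leaf] if unique_go else pd.NA,
            "n_unique_pathways": unique_pwy[leaf] if unique_pwy else pd.NA,
        })
    return pd.DataFrame(rows)


def _unique_regions(sets_by_cluster: dict) -> dict:
    """Per-cluster count of items found in that leaf cluster only."""
    if set(sets_by_cluster) != set(LEAF_LABELS):
        raise ValueError(f"expected sets for the four leaf clusters {LEAF_LABELS}")
    regions = four_set_overlap({k: set(v) for k, v in sets_by_cluster.items()})
    return {leaf: regions[(leaf,)] for leaf in LEAF_LABELS}
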