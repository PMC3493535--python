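"""Rule-based classification of DRGs into the nine overlapping clusters.

Every DRG belongs to cluster D. A DRG is in E when it carries at least one
epigenetic/miRNA feature (genic methylation read, promoter methylation
read, miRNA target, or chromatin-gene membership) and in NE otherwise.
Crossing E/NE with the regulation direction yields the four mutually
exclusive leaf clusters EU, ED, NEU, NED; DU/DD partition D by direction
alone. Genes reported with conflicting directions by different source
studies keep only their direction-free labels (D and E or NE) and are
reported separately.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger("drgepi")

CLUSTER_LABELS = ("D", "DU", "DD", "E", "NE", "EU", "ED", "NEU", "NED")
LEAF_LABELS = ("EU", "ED", "NEU", "NED")


def resolve_drgs(drgs: pd.DataFrame, fc_reduce: str = "max") -> pd.DataFrame:
    """Collapse the (possibly multi-source) DRG table to one row per gene.

    Direction: kept when all sources agree, ``conflict`` otherwise.
    Fold change: maximum absolute value across sources by default
    (``fc_reduce="mean"`` for the mean).
    """
    if fc_reduce not in ("max", "mean"):
        raise ValueError("fc_reduce must be 'max' or 'mean'")
    if not drgs["direction"].isin(["up", "down"]).all():
        raise ValueError("DRG direction must be 'up' or 'down'")
    reduce_fn = {"max": "max", "mean": "mean"}[fc_reduce]
    grouped = drgs.groupby("gene_id", sort=True)
    direction = grouped["direction"].agg(lambda s: s.iloc[0] if s.nunique() == 1 else "conflict")
    fc = grouped["fold_change"].agg(reduce_fn)
    n_conflict = int((direction == "conflict").sum())
    if n_conflict:
        logger.warning("%d DRG(s) with conflicting directions excluded from DU/DD", n_conflict)
    return pd.DataFrame(
        {"gene_id": direction.index, "direction": direction.values, "fold_change": fc.values}
    ).reset_index(drop=True)


def classify(drgs: pd.DataFrame, profiles: pd.DataFrame, fc_reduce: str = "max") -> pd.DataFrame:
    """Assign cluster labels to every DRG.

    Returns one row per DRG: gene_id, direction, ``epi`` (E/NE), ``leaf``
    (EU/ED/NEU/NED, empty for direction conflicts) and ``labels`` (the full
    comma-joined label set). DRGs without a profile are treated as all-zero
    (logged); non-DRG genes receive no row.
    """
    resolved = resolve_drgs(drgs, fc_reduce=fc_reduce)
    prof = profiles.set_index("gene_id")
    missing = [g for g in resolved["gene_id"] if g not in prof.index]
    if missing:
        logger.warning("%d DRG(s) without a feature profile treated as all-zero", len(missing))
    rows = []
    for g in resolved.itertuples(index=False):
        if g.gene_id in prof.index:
            p = prof.loc[g.gene_id]
            has_feature = bool(
                p["genic_read_count"] >= 1
                or p["promoter_read_count"] >= 1
                or p["mirna_count"] >= 1
                or p["is_chromdb"]
            )
        else:
            has_feature = False
        epi = "E" if has_feature else "NE"
        labels = ["D", epi]
        leaf = ""
        if g.direction == "up":
            labels.append("DU")
            leaf = "EU" if has_feature else "NEU"
        elif g.direction == "down":
            labels.append("DD")
            leaf = "ED" if has_feature else "NED"
        if leaf:
            labels.append(leaf)
        rows.append((g.gene_id, g.direction, epi, leaf, ",".join(labels)))
    return pd.DataFrame(rows, columns=["gene_id", "direction", "epi", "leaf", "labels"])


def cluster_members(memberships: pd.DataFrame, label: str) -> set[str]:
    """Gene ids carrying ``label``; unknown labels are rejected."""
    if label not in CLUSTER_LABELS:
        raise ValueError(f"unknown cluster label: {label!r}")
    mask = memberships["labels"].str.split(",").map(lambda ls: label in ls)
    return set(memberships.loc[mask, "gene_id"])


def validate_partition(memberships: pd.DataFrame) -> dict:
    """Check the cluster tree algebra; violations are reported, not thrown.

    Identities checked (n_conflict = genes without a DU/DD label):
    n(DU)+n(DD)+n_conflict = n(D); n(E)+n(NE) = n(D);
    n(EU)+n(ED)+(E conflicts) = n(E); n(NEU)+n(NED)+(NE conflicts) = n(NE);
    pairwise disjointness of {DU,DD}, {E,NE} and the leaves.
    """
    sets = {lab: cluster_members(memberships, lab) for lab in CLUSTER_LABELS}
    conflicts = sets["D"] - sets["DU"] - sets["DD"]
    violations: list[str] = []

    def _check(name: str, lhs: int, rhs: int):
        if lhs != rhs:
            violations.append(f"{name}: {lhs} != {rhs}")

    _check("n(DU)+n(DD)+n_conflict = n(D)",
           len(sets["DU"]) + len(sets["DD"]) + len(conflicts), len(sets["D"]))
    _check("n(E)+n(NE) = n(D)", len(sets["E"]) + len(sets["NE"]), len(sets["D"]))
    _check("n(EU)+n(ED)+conflictE = n(E)",
           len(sets["EU"]) + len(sets["ED"]) + len(conflicts & sets["E"]), len(sets["E"]))
    _check("n(NEU)+n(NED)+conflictNE = n(NE)",
           len(sets["NEU"]) + len(sets["NED"]) + len(conflicts & sets["NE"]), len(sets["NE"]))
    for a, b in [("DU", "DD"), ("E", "NE"), ("EU", "ED"), ("EU", "NEU"), ("EU", "NED"),
                 ("ED", "NEU"), ("ED", "NED"), ("NEU", "NED")]:
        both = sets[a] & sets[b]
        for g in sorted(both):
            violations.append(f"gene {g} in both {a} and {b}")
    dup = memberships["gene_id"].duplicated()
    for g in memberships.loc[dup, "gene_id"]:
        violations.append(f"gene {g} has duplicate membership rows")
    return {
        "n_violations": len(violations),
        "violations": violations,
        "n_conflict_direction": len(conflicts),
        "sizes": {lab: len(s) for lab, s in sets.items()},
    }


def fold_change_summary(memberships: pd.DataFrame, drgs: pd.DataFrame, fc_reduce: str = "max") -> pd.DataFrame:
    """Per-cluster mean of the absolute fold change, with cluster sizes and
    percent-of-parent. Empty clusters carry NaN means (undefined)."""
    resolved = resolve_drgs(drgs, fc_reduce=fc_reduce).set_index("gene_id")
    parent = {"D": "D", "DU": "D", "DD": "D", "E": "D", "NE": "D",
              "EU": "E", "ED": "E", "NEU": "NE", "NED": "NE"}
    sets = {lab: cluster_members(memberships, lab) for lab in CLUSTER_LABELS}
    rows = []
    for lab in CLUSTER_LABELS:
        ids = sorted(sets[lab])
        fcs = resolved.loc[resolved.index.intersection(ids), "fold_change"].abs()
        mean_fc = float(fcs.mean()) if len(fcs) else float("nan")
        parent_n = len(sets[parent[lab]])
        pct = 100.0 * len(ids) / parent_n if parent_n else float("nan")
        rows.append((lab, len(ids), mean_fc, round(pct, 2)))
    return pd.DataFrame(rows, columns=["cluster", "n_genes", "mean_abs_fold_change", "percent_of_parent"])
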