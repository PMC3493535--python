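"""Mapping of methylation-read intervals onto genic and promoter regions.

The genic region of a gene is its full span from the transcriptional start
site (TSS) to the gene end — no exon structure. A read is assigned to a
region when their 1-based inclusive intervals share at least ``min_overlap``
bases (default 50 for genic regions, 1 for promoter windows). A read may be
assigned to several overlapping regions; there is no unique-assignment
arbitration.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("drgepi")

ASSIGNMENT_COLUMNS = ["gene_id", "read_id"]


def _overlap_assign(regions: pd.DataFrame, reads: pd.DataFrame, min_overlap: int) -> pd.DataFrame:
    """Assign reads to regions with >= min_overlap shared bases (both 1-based
    inclusive). Returns a (gene_id, read_id) table sorted for determinism."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for row in reads.itertuples(index=False):
        # store as half-open [start, end+1) for intervaltree
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1, row.read_id)
    pairs = []
    for row in regions.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None or row.end < row.start:
            continue
        for iv in tree.overlap(row.start, row.end + 1):
            r_start, r_end = iv.begin, iv.end - 1
            overlap = min(r_end, row.end) - max(r_start, row.start) + 1
            if overlap >= min_overlap:
                pairs.append((row.gene_id, iv.data))
    out = pd.DataFrame(pairs, columns=ASSIGNMENT_COLUMNS)
    return out.sort_values(ASSIGNMENT_COLUMNS).reset_index(drop=True)


def map_reads_to_genic(genes: pd.DataFrame, reads: pd.DataFrame, min_overlap: int = 50) -> pd.DataFrame:
    """Assign reads to gene spans (TSS to gene end) at ``min_overlap`` bases."""
    return _overlap_assign(genes[["gene_id", "chrom", "start", "end"]], reads, min_overlap)


def promoter_windows(genes: pd.DataFrame, upstream: int = 1000, ignore_strand: bool = False) -> pd.DataFrame:
    """Strand-aware upstream windows of ``upstream`` bases abutting the TSS.

    For a ``+`` gene the window is ``[max(1, start-upstream), start-1]``;
    for a ``-`` gene it is ``[end+1, end+upstream]``. A window truncated at
    chromosome position 1 carries ``truncated=True``; a gene starting at
    position 1 yields an empty window with ``degenerate=True``.
    ``ignore_strand`` reproduces a strand-naive reading (all genes treated
    as ``+``).
    """
    if upstream < 1:
        raise ValueError("upstream must be >= 1")
    rows = []
    for g in genes.itertuples(index=False):
        strand = "+" if ignore_strand else g.strand
        if strand == "+":
            start, end = max(1, g.start - upstream), g.start - 1
        else:
            start, end = g.end + 1, g.end + upstream
        degenerate = end < start
        truncated = (strand == "+") and (g.start - upstream < 1) and not degenerate
        rows.append((g.gene_id, g.chrom, start, end, g.strand, truncated, degenerate))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "truncated", "degenerate"]
    )


def map_reads_to_promoters(windows: pd.DataFrame, reads: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """Assign reads to promoter windows; same overlap contract as genic
    mapping but with its own threshold (default 1: a read merely *falling*
    in the window counts)."""
    usable = windows.loc[~windows["degenerate"], ["gene_id", "chrom", "start", "end"]]
    return _overlap_assign(usable, reads, min_overlap)


def _tss_proximal_window(genes: pd.DataFrame, bases: int) -> pd.DataFrame:
    """First ``bases`` genic bases from the TSS (clipped at the gene end)."""
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            start, end = g.start, min(g.end, g.start + bases - 1)
        else:
            start, end = max(g.start, g.end - bases + 1), g.end
        rows.append((g.gene_id, g.chrom, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _upstream_proximal_window(genes: pd.DataFrame, bases: int, ignore_strand: bool = False) -> pd.DataFrame:
    """The ``bases`` bases immediately upstream of the TSS."""
    win = promoter_windows(genes, upstream=bases, ignore_strand=ignore_strand)
    return win.loc[~win["degenerate"], ["gene_id", "chrom", "start", "end"]]


def build_feature_profiles(
    genes: pd.DataFrame,
    genic_assignments: pd.DataFrame,
    promoter_assignments: pd.DataFrame,
    mirna_pairs: pd.DataFrame,
    chromdb_pairs: pd.DataFrame,
    reads: pd.DataFrame | None = None,
    min_overlap_genic: int = 50,
    min_overlap_promoter: int = 1,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Assemble one FeatureProfile row per gene.

    Genes absent from an assignment or pair table get zero counts / false
    flags. Pair-table rows referencing unknown genes are skipped with a
    logged count. When ``reads`` is given, the strand-aware TSS-proximal
    counts are computed: reads overlapping the first 1000 genic bases from
    the TSS (genic threshold) and reads in the 200 bases immediately
    upstream of the TSS (promoter threshold).
    """
    gene_ids = genes["gene_id"]
    known = set(gene_ids)

    def _counts(pairs: pd.DataFrame, id_col: str, subject_col: str) -> tuple[pd.Series, pd.Series]:
        unknown = ~pairs[id_col].isin(known)
        if unknown.any():
            logger.warning("skipping %d pair row(s) with unknown gene_id", int(unknown.sum()))
            pairs = pairs[~unknown]
        grouped = pairs.groupby(id_col)[subject_col]
        ids = grouped.apply(lambda s: ",".join(sorted(s.astype(str))))
        return grouped.size(), ids

    genic_n, genic_ids = _counts(genic_assignments, "gene_id", "read_id")
    prom_n, prom_ids = _counts(promoter_assignments, "gene_id", "read_id")
    mir_n, mir_ids = _counts(mirna_pairs, "gene_id", "subject_id")
    chrom_flag = chromdb_pairs.loc[chromdb_pairs["gene_id"].isin(known), "gene_id"].unique()
    n_unknown_chrom = int((~chromdb_pairs["gene_id"].isin(known)).sum())
    if n_unknown_chrom:
        logger.warning("skipping %d chromdb row(s) with unknown gene_id", n_unknown_chrom)

    if reads is not None:
        first1kb = _overlap_assign(_tss_proximal_window(genes, 1000), reads, min_overlap_genic)
        # keep only reads that also qualified as genic
        genic_keys = set(map(tuple, genic_assignments[ASSIGNMENT_COLUMNS].itertuples(index=False)))
        mask1 = [tuple(r) in genic_keys for r in first1kb.itertuples(index=False)]
        first1kb = first1kb[pd.Series(mask1, index=first1kb.index, dtype=bool)]
        first200 = _overlap_assign(
            _upstream_proximal_window(genes, 200, ignore_strand), reads, min_overlap_promoter
        )
        prom_keys = set(map(tuple, promoter_assignments[ASSIGNMENT_COLUMNS].itertuples(index=False)))
        mask2 = [tuple(r) in prom_keys for r in first200.itertuples(index=False)]
        first200 = first200[pd.Series(mask2, index=first200.index, dtype=bool)]
        first1kb_n = first1kb.groupby("gene_id").size()
        first200_n = first200.groupby("gene_id").size()
    else:
        first1kb_n = pd.Series(dtype="int64")
        first200_n = pd.Series(dtype="int64")

    out = pd.DataFrame({"gene_id": gene_ids})
    out["genic_read_count"] = gene_ids.map(genic_n).fillna(0).astype("int64")
    out["promoter_read_count"] = gene_ids.map(prom_n).fillna(0).astype("int64")
    out["genic_read_ids"] = gene_ids.map(genic_ids).fillna("")
    out["promoter_read_ids"] = gene_ids.map(prom_ids).fillna("")
    out["mirna_count"] = gene_ids.map(mir_n).fillna(0).astype("int64")
    out["mirna_ids"] = gene_ids.map(mir_ids).fillna("")
    out["is_chromdb"] = gene_ids.isin(chrom_flag)
    out["first1kb_read_count"] = gene_ids.map(first1kb_n).fillna(0).astype("int64")
    out["first200_promoter_count"] = gene_ids.map(first200_n).fillna(0).astype("int64")
    return out.reset_index(drop=True)


FEATURES = ("genic", "promoter", "mirna", "chromdb")


def _feature_sets(profiles: pd.DataFrame, universe: set[str]) -> dict[str, set[str]]:
    sub = profiles[profiles["gene_id"].isin(universe)]
    return {
        "genic": set(sub.loc[sub["genic_read_count"] >= 1, "gene_id"]),
        "promoter": set(sub.loc[sub["promoter_read_count"] >= 1, "gene_id"]),
        "mirna": set(sub.loc[sub["mirna_count"] >= 1, "gene_id"]),
        "chromdb": set(sub.loc[sub["is_chromdb"], "gene_id"]),
    }


def feature_cooccurrence(profiles: pd.DataFrame, universe: set[str]) -> dict[str, int]:
    """Exclusive/shared feature counts over ``universe``.

    Returns counts of genes carrying ONLY one feature (``only_<f>``), every
    pairwise intersection (``<f>_and_<g>``), the genic∧promoter∧mirna
    triple, and genes with any / no feature.
    """
    missing = universe - set(profiles["gene_id"])
    if missing:
        raise ValueError(f"universe contains {len(missing)} gene(s) without a profile")
    sets = _feature_sets(profiles, universe)
    out: dict[str, int] = {}
    for f in FEATURES:
        others = set().union(*(sets[g] for g in FEATURES if g != f))
        out[f"only_{f}"] = len(sets[f] - others)
    for i, f in enumerate(FEATURES):
        for g in FEATURES[i + 1:]:
            out[f"{f}_and_{g}"] = len(sets[f] & sets[g])
    out["genic_and_promoter_and_mirna"] = len(sets["genic"] & sets["promoter"] & sets["mirna"])
    any_set = set().union(*sets.values())
    out["any_feature"] = len(any_set)
    out["no_feature"] = len(universe - any_set)
    return out


def length_summary(genes: pd.DataFrame, partitions: dict[str, set[str]]) -> dict[str, float | None]:
    """Mean gene length (end − start + 1) per named id set; ``None`` marks
    an empty partition (undefined, not zero)."""
    lengths = (genes["end"] - genes["start"] + 1).to_numpy()
    by_id = dict(zip(genes["gene_id"], lengths))
    out: dict[str, float | None] = {}
    for name, ids in partitions.items():
        vals = [by_id[i] for i in ids if i in by_id]
        out[name] = float(sum(vals)) / len(vals) if vals else None
    return out


def multiplicity_histogram(profiles: pd.DataFrame, feature: str) -> dict[int, int]:
    """Histogram count→n_genes of per-gene instance counts, over genes with
    at least one instance of ``feature`` (genic, promoter or mirna)."""
    col = {"genic": "genic_read_count", "promoter": "promoter_read_count", "mirna": "mirna_count"}
    if feature not in col:
        raise ValueError(f"unknown feature: {feature!r}")
    counts = profiles.loc[profiles[col[feature]] >= 1, col[feature]]
    return {int(k): int(v) for k, v in counts.value_counts().sort_index().items()}
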