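"""Readers and writers for the pipeline's tabular inputs and outputs.

All genomic coordinates are held internally as 1-based inclusive intervals
(the GFF3 convention); only the BED reader/writer converts from/to BED's
0-based half-open convention. Every reader validates row-level invariants
and fails loudly on malformed input unless ``skip_bad_rows`` is set, in
which case offending rows are dropped and counted in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger("drgepi")

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "is_te", "is_pseudogene"]
READ_COLUMNS = ["read_id", "chrom", "start", "end"]
DRG_COLUMNS = ["gene_id", "direction", "fold_change", "source"]
PAIR_COLUMNS = ["subject_id", "gene_id", "score", "kind"]

#: annotation-pair kinds understood by :func:`read_pair_table`
PAIR_KINDS = frozenset(
    {"mirna_target", "chromdb", "tf_family", "pfam", "pathway", "go", "ppi_edge"}
)

_TRUTHY = {"1", "true", "yes", "t"}
_FALSY = {"0", "false", "no", "f", ""}


class ParseError(ValueError):
    """Malformed input row; carries the 1-based line number where known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.line = line


def _to_bool(value, *, path=None, line=None) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ParseError(f"cannot interpret {value!r} as boolean", path=path, line=line)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, format: str = "gff3", skip_bad_rows: bool = False) -> pd.DataFrame:
    """Read gene models into the canonical gene table.

    Parameters
    ----------
    path
        GFF3 file (``format="gff3"``; only ``gene`` features are kept,
        TE/pseudogene status from the ``is_te`` / ``is_pseudogene``
        attributes) or a headered TSV with the canonical columns
        (``format="tsv"``).
    skip_bad_rows
        Drop invalid rows with a logged count instead of raising.
    """
    if format == "gff3":
        df = _read_gene_models_gff3(path, skip_bad_rows=skip_bad_rows)
    elif format == "tsv":
        df = _read_gene_models_tsv(path, skip_bad_rows=skip_bad_rows)
    else:
        raise ValueError(f"unknown gene-model format: {format!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ParseError(
            f"duplicate gene_id(s): {sorted(df.loc[dup, 'gene_id'].unique())[:5]}",
            path=path,
        )
    return df.reset_index(drop=True)


def _read_gene_models_gff3(path, skip_bad_rows: bool) -> pd.DataFrame:
    rows, n_bad = [], 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare ValueError variants
                if skip_bad_rows:
                    n_bad += 1
                    continue
                raise ParseError(f"malformed GFF3 line ({exc})", path=path, line=lineno)
            if feat.featuretype != "gene":
                continue
            try:
                row = _gene_row_from_feature(feat, path, lineno)
            except ParseError:
                if skip_bad_rows:
                    n_bad += 1
                    continue
                raise
            rows.append(row)
    if n_bad:
        logger.warning("read_gene_models: skipped %d bad row(s) in %s", n_bad, path)
    return pd.DataFrame(rows, columns=GENE_COLUMNS).astype(
        {"start": "int64", "end": "int64", "is_te": bool, "is_pseudogene": bool}
    )


def _gene_row_from_feature(feat, path, lineno) -> dict:
    if feat.strand not in ("+", "-"):
        raise ParseError(f"strand must be + or -, got {feat.strand!r}", path=path, line=lineno)
    if feat.end < feat.start:
        raise ParseError(f"end < start ({feat.end} < {feat.start})", path=path, line=lineno)
    gid = feat.attributes.get("ID", [None])[0] or feat.id
    if not gid:
        raise ParseError("gene feature without ID attribute", path=path, line=lineno)
    return {
        "gene_id": gid,
        "chrom": feat.seqid,
        "start": int(feat.start),
        "end": int(feat.end),
        "strand": feat.strand,
        "is_te": _to_bool(feat.attributes.get("is_te", ["false"])[0], path=path, line=lineno),
        "is_pseudogene": _to_bool(
            feat.attributes.get("is_pseudogene", ["false"])[0], path=path, line=lineno
        ),
    }


def _read_gene_models_tsv(path, skip_bad_rows: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s): {sorted(missing)}", path=path)
    df = df[GENE_COLUMNS].copy()
    df["is_te"] = df["is_te"].map(lambda v: _to_bool(v, path=path))
    df["is_pseudogene"] = df["is_pseudogene"].map(lambda v: _to_bool(v, path=path))
    df = df.astype({"start": "int64", "end": "int64"})
    bad = (df["end"] < df["start"]) | ~df["strand"].isin(["+", "-"])
    if bad.any():
        if not skip_bad_rows:
            first = bad.idxmax()
            raise ParseError(
                f"invalid gene row (start>end or bad strand)", path=path, line=int(first) + 2
            )
        logger.warning("read_gene_models: skipped %d bad row(s) in %s", int(bad.sum()), path)
        df = df[~bad]
    return df


def write_gene_models_gff3(genes: pd.DataFrame, path) -> None:
    """Write the canonical gene table as gene-level GFF3."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = (
                f"ID={row.gene_id};"
                f"is_te={'true' if row.is_te else 'false'};"
                f"is_pseudogene={'true' if row.is_pseudogene else 'false'}"
            )
            fh.write(
                f"{row.chrom}\tdrgepi\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# methylation-read intervals (BED)
# ---------------------------------------------------------------------------

def read_intervals_bed(path, skip_bad_rows: bool = False) -> pd.DataFrame:
    """Read a BED3/BED4 file of read intervals into the canonical read table.

    BED's 0-based half-open ``[chromStart, chromEnd)`` becomes the internal
    1-based inclusive ``[chromStart+1, chromEnd]``, so interval lengths are
    preserved. A ``read_id`` is auto-generated when column 4 is absent.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 3:
        raise ParseError("BED needs at least 3 columns", path=path)
    df = raw.iloc[:, :3].copy()
    df.columns = ["chrom", "bed_start", "bed_end"]
    try:
        df["bed_start"] = df["bed_start"].astype("int64")
        df["bed_end"] = df["bed_end"].astype("int64")
    except ValueError as exc:
        raise ParseError(f"non-integer BED coordinate ({exc})", path=path)
    if raw.shape[1] >= 4:
        df["read_id"] = raw.iloc[:, 3].astype(str)
    else:
        df["read_id"] = [f"read{i}" for i in range(len(df))]
    bad = df["bed_end"] <= df["bed_start"]
    if bad.any():
        if not skip_bad_rows:
            first = int(bad.idxmax())
            raise ParseError("chromEnd <= chromStart", path=path, line=first + 1)
        logger.warning("read_intervals_bed: skipped %d bad row(s) in %s", int(bad.sum()), path)
        df = df[~bad]
    out = pd.DataFrame(
        {
            "read_id": df["read_id"],
            "chrom": df["chrom"],
            "start": df["bed_start"].astype("int64") + 1,
            "end": df["bed_end"].astype("int64"),
        }
    )
    if out["read_id"].duplicated().any():
        raise ParseError("duplicate read_id(s)", path=path)
    return out.reset_index(drop=True)


def write_intervals_bed(reads: pd.DataFrame, path) -> None:
    """Write the canonical read table as BED4 (inverse of the reader)."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "bed_start": reads["start"] - 1,
            "bed_end": reads["end"],
            "read_id": reads["read_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DRG table and annotation pairs
# ---------------------------------------------------------------------------

def read_drg_table(path) -> pd.DataFrame:
    """Read the DRG table (gene_id, direction, fold_change, source).

    ``fold_change`` is the absolute fold change (strictly positive);
    ``direction`` must be ``up`` or ``down``. A gene may appear on several
    rows when reported by more than one source study.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "direction": str, "source": str})
    missing = set(DRG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s): {sorted(missing)}", path=path)
    df = df[DRG_COLUMNS].copy()
    if not df["direction"].isin(["up", "down"]).all():
        bad = df.loc[~df["direction"].isin(["up", "down"]), "direction"].iloc[0]
        raise ParseError(f"direction must be up/down, got {bad!r}", path=path)
    df["fold_change"] = df["fold_change"].astype(float)
    if (df["fold_change"] <= 0).any():
        raise ParseError("fold_change must be > 0", path=path)
    return df.reset_index(drop=True)


def read_pair_table(path, kind: str) -> pd.DataFrame:
    """Read a two-column (subject_id, gene_id[, score]) annotation table.

    Pairs are deduplicated. For ``kind="ppi_edge"`` a score column is
    required, self-loops are dropped, and edges are stored undirected with
    endpoints in lexicographic order so (a,b) and (b,a) collapse.
    """
    if kind not in PAIR_KINDS:
        raise ValueError(f"unknown annotation kind: {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "gene_id": str})
    required = {"subject_id", "gene_id"} | ({"score"} if kind == "ppi_edge" else set())
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s): {sorted(missing)}", path=path)
    if kind == "ppi_edge":
        df["score"] = df["score"].astype(float)
        if ((df["score"] < 0) | (df["score"] > 1)).any():
            raise ParseError("ppi_edge score outside [0, 1]", path=path)
        df = df[df["subject_id"] != df["gene_id"]]
        swap = df["subject_id"] > df["gene_id"]
        lo = df["subject_id"].where(~swap, df["gene_id"])
        hi = df["gene_id"].where(~swap, df["subject_id"])
        df = df.assign(subject_id=lo, gene_id=hi)
        df = df.sort_values("score").drop_duplicates(["subject_id", "gene_id"], keep="last")
    else:
        df = df.assign(score=float("nan"))
    df = df.assign(kind=kind).drop_duplicates(["subject_id", "gene_id", "kind"])
    return df[PAIR_COLUMNS].sort_values(["subject_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# generic TSV round-trip
# ---------------------------------------------------------------------------

def write_tsv(table: pd.DataFrame, path) -> None:
    """Write any canonical table as headered, UTF-8, tab-separated text."""
    if table is None:
        raise ValueError("table is None")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path, table: str) -> pd.DataFrame:
    """Re-read a TSV written by :func:`write_tsv` with canonical dtypes.

    ``table`` is one of ``genes``, ``reads``, ``drgs``, ``pairs``.
    """
    if table == "genes":
        return read_gene_models(path, format="tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if table == "reads":
        df = df[READ_COLUMNS].astype({"start": "int64", "end": "int64"})
        if (df["end"] < df["start"]).any():
            raise ParseError("end < start", path=path)
        return df
    if table == "drgs":
        df = df[DRG_COLUMNS].copy()
        df["fold_change"] = df["fold_change"].astype(float)
        return df
    if table == "pairs":
        df = df[PAIR_COLUMNS].copy()
        df["score"] = df["score"].astype(float)
        return df
    raise ValueError(f"unknown table name: {table!r}")
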