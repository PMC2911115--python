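"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-separated with a header row; missing values are the
literal ``NA`` (missing is never conflated with zero).  Lines starting
with ``#`` are provenance comments and are skipped on read.  Promoters
travel as FASTA with headers ``geneId|anchor|length``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    STRAINS,
    TIMEPOINTS,
    CellCyclePeakMap,
    ExpressionPanel,
    OverexpressionResponse,
    PromoterRecord,
    PromoterSet,
    normalize_gene_name,
)
from .errors import DuplicateGeneError, ParseError, SchemaError

NA = "NA"


def read_gene_table(path, schema: dict, required=None) -> pd.DataFrame:
    """Read a TSV into a typed frame.

    ``schema`` maps column name -> one of ``str``/``float``/``int``.
    Columns listed in ``required`` (default: all schema columns) must be
    present.  Unknown columns and row order are preserved.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, na_values=[NA], keep_default_na=False
    )
    required = list(schema) if required is None else list(required)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: mandatory column {col!r} is missing")
    for col, kind in schema.items():
        if col not in df.columns:
            continue
        if kind in ("float", "int"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in numeric "
                    f"column {col!r} (data row {row + 1})"
                )
            df[col] = coerced.astype("Int64") if kind == "int" else coerced
    return df


def write_tsv(df: pd.DataFrame, path, header_comments=(), index=False) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index)


# --- expression panel -------------------------------------------------------

def _panel_columns(strains) -> list[str]:
    return [f"{s}_t{t}" for s in strains for t in TIMEPOINTS]


def write_expression_panel(panel: ExpressionPanel, path, header_comments=()) -> None:
    flat = panel.values.copy()
    flat.columns = [f"{s}_t{t}" for s, t in flat.columns]
    flat.insert(0, "gene", flat.index)
    write_tsv(flat, path, header_comments)


def read_expression_panel(path, strains=STRAINS) -> ExpressionPanel:
    cols = _panel_columns(strains)
    schema = {"gene": "str", **{c: "float" for c in cols}}
    df = read_gene_table(path, schema)
    per_strain = {
        s: df[[f"{s}_t{t}" for t in TIMEPOINTS]].to_numpy(dtype=float) for s in strains
    }
    return ExpressionPanel.build(df["gene"].tolist(), per_strain)


# --- promoters --------------------------------------------------------------

def write_promoters_fasta(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.gene}|{rec.anchor}|{len(rec.sequence)}",
            description="",
        )
        for rec in promoters.records.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path, max_length: int = 1000) -> PromoterSet:
    """Parse FASTA with ``geneId|anchor|length`` headers into a PromoterSet."""
    out = PromoterSet(max_length=max_length)
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ParseError(f"{path}: header {rec.id!r} is not 'geneId|anchor|length'")
        gene, anchor, length = parts
        seq = str(rec.seq).upper()
        if int(length) != len(seq):
            raise ParseError(
                f"{path}: {gene}: declared length {length} != sequence length {len(seq)}"
            )
        try:
            out.add(PromoterRecord(gene=gene, sequence=seq, anchor=anchor))
        except DuplicateGeneError:
            raise DuplicateGeneError(f"{path}: duplicate promoter record for {gene}")
    return out


# --- simple per-gene tables -------------------------------------------------

def write_peak_map(peaks: CellCyclePeakMap, path, header_comments=()) -> None:
    df = pd.DataFrame({"gene": peaks.peaks.index, "cc_peak_percent": peaks.peaks.values})
    write_tsv(df, path, header_comments)


def read_peak_map(path) -> CellCyclePeakMap:
    df = read_gene_table(path, {"gene": "str", "cc_peak_percent": "float"})
    return CellCyclePeakMap(pd.Series(df["cc_peak_percent"].values, index=df["gene"]))


def write_overexpression(oe: OverexpressionResponse, path, header_comments=()) -> None:
    df = oe.table.copy()
    df.insert(0, "gene", df.index)
    write_tsv(df, path, header_comments)


def read_overexpression(path) -> OverexpressionResponse:
    df = read_gene_table(
        path, {"gene": "str", "cln3_induction": "float", "clb2_response": "float"}
    )
    return OverexpressionResponse(df.set_index("gene")[["cln3_induction", "clb2_response"]])


def write_gene_sets(sets: dict, path, header_comments=()) -> None:
    """Serialize named gene sets as a two-column (set, gene) table."""
    rows = [
        {"set": name, "gene": g}
        for name, genes in sets.items()
        for g in sorted(normalize_gene_name(x) for x in genes)
    ]
    write_tsv(pd.DataFrame(rows, columns=["set", "gene"]), path, header_comments)


def read_gene_sets(path) -> dict:
    df = read_gene_table(path, {"set": "str", "gene": "str"})
    out: dict = {}
    for name, sub in df.groupby("set", sort=False):
        out[name] = set(sub["gene"].map(normalize_gene_name))
    return out


# --- ranked score tables ----------------------------------------------------

def write_ranked_scores(scores: pd.DataFrame, path, header_comments=()) -> None:
    """Write a ScoreTable: one row per gene, per-classifier LLS columns, SUM,
    rank; sorted by SUM descending with lexicographic tie-break."""
    df = scores.sort_values("rank").copy()
    df.insert(0, "gene", df.index)
    write_tsv(df, path, header_comments)


def read_ranked_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], keep_default_na=False)
    if "gene" not in df.columns or "SUM" not in df.columns:
        raise SchemaError(f"{path}: score table needs 'gene' and 'SUM' columns")
    df = df.set_index("gene")
    df.index = pd.Index([normalize_gene_name(g) for g in df.index], name="gene")
    if "rank" in df.columns:
        df["rank"] = df["rank"].astype(int)
    return df
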