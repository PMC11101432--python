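"""Tabular and gene-set I/O helpers.

All tables travel as TSV.  Case tables use the column dictionary of
:data:`tnbcstrat.synthetic.CASE_COLUMNS`; expression and centroid matrices
are genes x samples with the gene id in the first column; gene sets use the
GMT convention (set name, description, then member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_cases(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    genesets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genesets[parts[0]] = [g for g in parts[2:] if g]
    return genesets


def write_gmt(genesets: dict[str, list[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def alterations_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Events x samples binary matrix -> long (case_id, gene, event_type) rows."""
    records = []
    for event, row in matrix.iterrows():
        gene, _, event_type = str(event).partition(":")
        for sample, value in row.items():
            if value:
                records.append(
                    {"case_id": sample, "gene": gene, "event_type": event_type}
                )
    return pd.DataFrame(records, columns=["case_id", "gene", "event_type"])


def long_to_alterations(long: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Long-format alteration calls -> events x samples binary matrix."""
    matrix = pd.DataFrame(0, index=[], columns=sample_ids, dtype=int)
    for rec in long.itertuples():
        event = f"{rec.gene}:{rec.event_type}"
        if event not in matrix.index:
            matrix.loc[event] = 0
        if rec.case_id in matrix.columns:
            matrix.loc[event, rec.case_id] = 1
    return matrix
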