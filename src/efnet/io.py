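"""Readers and writers for the plain-text formats used by the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_counts_tsv(path) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_lengths_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"}.issubset(df.columns):
        raise ValueError("gene-length table needs columns ['gene_id', 'length_bp']")
    return df.set_index("gene_id")["length_bp"]


def read_bw_csv(path) -> pd.DataFrame:
    """Long-format body weights: animal_id, day, bw_kg (comma or tab)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"animal_id", "day", "bw_kg"}.issubset(df.columns):
        raise ValueError("body-weight table needs columns [animal_id, day, bw_kg]")
    return df


def read_dmi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"animal_id", "dmi_kg_d"}.issubset(df.columns):
        raise ValueError("intake table needs columns [animal_id, dmi_kg_d]")
    return df


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValueError("annotation needs columns [gene_id, term_id]")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
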