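"""TSV readers with schema validation.

All pipeline inputs are plain tab-separated tables with a header row;
the score and expression matrices carry the gene identifier as the
first (index) column. Readers check required columns up front so a
malformed input fails with a message naming the table and the missing
columns rather than deep inside a stage.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "SCHEMAS", "read_table", "read_matrix"]


class SchemaError(ValueError):
    """An input table does not match its expected schema."""


#: Required columns per named input table.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "crosses": (
        "line_id", "gene_id", "zygosity_class", "n_total", "n_hom",
        "procedures_total", "procedures_done", "n_significant_phenotypes",
    ),
    "embryo": ("gene_id", "stage", "n_scored", "n_live_hom"),
    "orthology": ("human_id", "mouse_id", "n_methods", "human_coding", "mouse_coding"),
    "constraints": ("gene_id", "pli", "loeuf", "hi_percentile", "oe_missense"),
    "disease": ("gene_id",),
    "evidence": ("gene_id", "in_100kgp", "in_ddd", "in_cmg",
                 "variant_in_gnomad", "oe_missense"),
    "recomb_intervals": ("chrom", "start", "end", "rate"),
    "gene_positions": ("gene_id", "chrom", "start", "end"),
    "edges": ("gene_a", "gene_b", "score"),
    "complexes": ("gene_id", "complex_id"),
    "paralogues": ("gene_id", "partner", "identity"),
    "onsets": ("gene_id", "onset"),
    "systems": ("gene_id", "system"),
    "families": ("gene_id", "family"),
    "pathways": ("gene_id", "pathway"),
    "truth": ("gene_id", "latent_class"),
}


def validate_columns(df: pd.DataFrame, name: str) -> pd.DataFrame:
    required = SCHEMAS.get(name, ())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} is missing columns: {missing}")
    return df


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    """Read a named TSV input and validate its columns."""
    df = pd.read_csv(path, sep="\t")
    return validate_columns(df, name)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-columns matrix TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"matrix {path} has no value columns")
    return df
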