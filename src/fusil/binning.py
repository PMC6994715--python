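"""FUSIL bin assignment.

Combining the mouse viability call with the human cell essentiality
call yields five mutually exclusive bins spanning the full spectrum of
intolerance to loss of function:

========  =====================================================
CL        cellular lethal: mouse lethal, cell essential
DL        developmental lethal: mouse lethal, cell non-essential
SV        subviable, cell non-essential
VP        viable with at least one significant phenotype
VN        viable with no significant phenotype
========  =====================================================

Three exclusion labels cover genes that do not enter the bins: the two
small outlier groups of subviable/viable genes whose mean score falls
at or below the essentiality threshold (SV.outlier, V.outlier), and
viable genes with under half of their phenotyping procedures complete
(V.insuffProcedures).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FUSIL_BINS",
    "EXCLUSION_LABELS",
    "FusilAssignment",
    "assign_fusil",
    "summarize_bins",
    "row_percentage",
]

FUSIL_BINS = ("CL", "DL", "SV", "VP", "VN")
EXCLUSION_LABELS = ("SV.outlier", "V.outlier", "V.insuffProcedures")

#: Minimum fraction of scheduled phenotyping procedures with QCed data
#: for a viable gene to be binned as VP/VN.
COMPLETENESS_THRESHOLD = 0.5

_MOUSE_CATEGORY = {
    "lethal": "Lethal",
    "subviable": "Subviable",
}


@dataclass(frozen=True)
class FusilAssignment:
    gene_id: str
    bin: str
    viability: str
    essentiality: str
    mouse_category: str


def assign_fusil(
    viability: str,
    essentiality: str,
    n_significant_phenotypes: int = 0,
    procedures_done: int = 0,
    procedures_total: int = 0,
    gene_id: str = "",
    completeness_threshold: float = COMPLETENESS_THRESHOLD,
) -> FusilAssignment:
    """Map one gene's (viability, essentiality) pair to its FUSIL label.

    Only substantive viability calls may reach this stage; excluded
    calls indicate an upstream filtering bug and raise.
    """
    if viability not in ("lethal", "subviable", "viable"):
        raise ValueError(
            f"gene {gene_id or '?'}: viability call {viability!r} must be "
            "filtered out before binning"
        )
    if essentiality not in ("essential", "non_essential"):
        raise ValueError(f"unknown essentiality call: {essentiality!r}")
    essential = essentiality == "essential"
    if viability == "lethal":
        label = "CL" if essential else "DL"
        mouse = "Lethal"
    elif viability == "subviable":
        label = "SV.outlier" if essential else "SV"
        mouse = "Subviable"
    else:
        has_phenotype = n_significant_phenotypes >= 1
        mouse = (
            "Viable with phenotypic abnormalities"
            if has_phenotype
            else "Viable with normal phenotype"
        )
        completeness = (
            procedures_done / procedures_total if procedures_total > 0 else 0.0
        )
        if essential:
            label = "V.outlier"
        elif completeness < completeness_threshold:
            label = "V.insuffProcedures"
            mouse = "Viable with insufficient procedures"
        else:
            label = "VP" if has_phenotype else "VN"
    return FusilAssignment(gene_id, label, viability, essentiality, mouse)


def row_percentage(count: int, row_total: int, decimals: int = 2) -> float:
    """Row percentage rounded half-to-even at ``decimals`` places.

    Exact decimal division, so e.g. 2/320 -> 0.62 and 318/320 -> 99.38
    (half-to-even reproduces the published table on the exact-half
    cases, where half-away-from-zero would print 0.63).
    """
    if row_total <= 0:
        raise ValueError("row_total must be positive")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100 * count) / Decimal(row_total)).quantize(
        q, rounding=ROUND_HALF_EVEN
    )
    return float(pct)


def summarize_bins(assignments: Sequence[FusilAssignment]) -> pd.DataFrame:
    """Cross-tabulate mouse category against cell essentiality.

    Returns one row per (mouse category, cell category) with the gene
    count and the row percentage (two decimals, half away from zero).
    Genes excluded for insufficient procedures do not enter the table;
    the essential-scored outlier groups appear as the Essential column
    of their mouse category, mirroring the published layout.
    """
    if not assignments:
        raise ValueError("no assignments to summarise")
    rows = []
    kept = [a for a in assignments if a.bin != "V.insuffProcedures"]
    order = [
        "Lethal",
        "Subviable",
        "Viable with phenotypic abnormalities",
        "Viable with normal phenotype",
    ]
    counts: dict[tuple[str, str], int] = {}
    for a in kept:
        cell = "Essential" if a.essentiality == "essential" else "Non-essential"
        counts[(a.mouse_category, cell)] = counts.get((a.mouse_category, cell), 0) + 1
    for mouse in order:
        total = sum(counts.get((mouse, c), 0) for c in ("Essential", "Non-essential"))
        if total == 0:
            continue
        for cell in ("Essential", "Non-essential"):
            n = counts.get((mouse, cell), 0)
            if n == 0:
                continue
            rows.append(
                {
                    "mouse_category": mouse,
                    "cell_category": cell,
                    "n_genes": n,
                    "pct_overlap": row_percentage(n, total),
                }
            )
    return pd.DataFrame(rows)
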