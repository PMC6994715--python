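"""Staged prioritisation of developmental-disorder candidate genes.

The funnel starts from the developmental-lethal (DL) bin — mouse lethal
yet non-essential in human cells — removes genes already associated
with Mendelian disease, keeps genes highly likely to be
haploinsufficient (HI percentile < 10, or LoF observed/expected upper
bound < 0.35, or pLI > 0.90), intersects with de novo evidence from
three large sequencing programmes, and finally keeps genes with
replicated consortium evidence, variants absent from population
databases, and intolerance to missense variation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CandidateFunnel",
    "filter_dl_candidates",
    "consortium_overlap",
    "final_candidates",
    "shared_annotation_rates",
    "HI_THRESHOLD",
    "LOEUF_THRESHOLD",
    "PLI_THRESHOLD",
    "OE_MISSENSE_THRESHOLD",
]

logger = logging.getLogger(__name__)

HI_THRESHOLD = 10.0
LOEUF_THRESHOLD = 0.35
PLI_THRESHOLD = 0.90
OE_MISSENSE_THRESHOLD = 0.8

CONSORTIA = ("in_100kgp", "in_ddd", "in_cmg")


@dataclass(frozen=True)
class CandidateFunnel:
    """Successive gene sets of the prioritisation cascade."""

    dl_genes: frozenset[str]
    non_disease: frozenset[str]
    prioritised: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "dl": len(self.dl_genes),
            "non_disease": len(self.non_disease),
            "prioritised": len(self.prioritised),
        }


def _passes_constraint(
    hi: float, loeuf: float, pli: float,
    hi_threshold: float, loeuf_threshold: float, pli_threshold: float,
) -> bool:
    # a missing score fails its own clause only
    ok = False
    if np.isfinite(hi):
        ok = ok or hi < hi_threshold
    if np.isfinite(loeuf):
        ok = ok or loeuf < loeuf_threshold
    if np.isfinite(pli):
        ok = ok or pli > pli_threshold
    return ok


def filter_dl_candidates(
    assignments: pd.DataFrame,
    disease_sets: Mapping[str, Iterable[str]],
    constraints: pd.DataFrame,
    hi_threshold: float = HI_THRESHOLD,
    loeuf_threshold: float = LOEUF_THRESHOLD,
    pli_threshold: float = PLI_THRESHOLD,
) -> CandidateFunnel:
    """DL genes, not in any disease resource, passing the
    haploinsufficiency constraint disjunction.

    ``assignments`` needs columns ``gene_id, bin``; ``constraints``
    needs ``gene_id`` plus ``hi_percentile, loeuf, pli`` (missing rows
    or NaN scores fail their clause, so a gene lacking all three scores
    cannot pass).
    """
    dl = frozenset(assignments.loc[assignments["bin"] == "DL", "gene_id"].astype(str))
    disease = set()
    for genes in disease_sets.values():
        disease |= {str(g) for g in genes}
    non_disease = frozenset(dl - disease)
    cons = constraints.set_index(constraints["gene_id"].astype(str))
    kept = []
    for g in non_disease:
        if g not in cons.index:
            continue
        row = cons.loc[g]
        if _passes_constraint(
            float(row.get("hi_percentile", np.nan)),
            float(row.get("loeuf", np.nan)),
            float(row.get("pli", np.nan)),
            hi_threshold, loeuf_threshold, pli_threshold,
        ):
            kept.append(g)
    return CandidateFunnel(dl, non_disease, frozenset(kept))


def consortium_overlap(
    candidates: Iterable[str], evidence: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene consortium evidence matrix and Venn region counts.

    Evidence rows for genes outside the candidate set are ignored with
    a warning; candidates with no evidence row get all-False flags.
    Region keys name the consortia present, e.g. ``100kgp&ddd``; the
    union is under ``any``.
    """
    cand = sorted({str(g) for g in candidates})
    ev = evidence.copy()
    ev["gene_id"] = ev["gene_id"].astype(str)
    outside = set(ev["gene_id"]) - set(cand)
    if outside:
        logger.warning("%d evidence row(s) for genes outside the candidate set ignored",
                       len(outside))
    ev = ev[ev["gene_id"].isin(cand)].set_index("gene_id")
    matrix = pd.DataFrame(False, index=cand, columns=list(CONSORTIA))
    for col in CONSORTIA:
        if col in ev.columns:
            matrix.loc[ev.index, col] = ev[col].astype(bool)
    names = {"in_100kgp": "100kgp", "in_ddd": "ddd", "in_cmg": "cmg"}
    venn: dict[str, int] = {}
    for r in range(1, len(CONSORTIA) + 1):
        for combo in itertools.combinations(CONSORTIA, r):
            inside = matrix[list(combo)].all(axis=1)
            rest = [c for c in CONSORTIA if c not in combo]
            if rest:
                inside &= ~matrix[rest].any(axis=1)
            venn["&".join(names[c] for c in combo)] = int(inside.sum())
    venn["any"] = int(matrix.any(axis=1).sum())
    return matrix, venn


def final_candidates(
    evidence: pd.DataFrame,
    oe_missense_threshold: float = OE_MISSENSE_THRESHOLD,
) -> list[str]:
    """Final selection: evidence from the 100KGP and from DDD or CMG,
    variants absent from gnomAD, and o/e missense below threshold
    (missense-intolerant genes are kept)."""
    for col in ("gene_id", "in_100kgp", "in_ddd", "in_cmg",
                "variant_in_gnomad", "oe_missense"):
        if col not in evidence.columns:
            raise ValueError(f"evidence table missing column {col!r}")
    keep = (
        evidence["in_100kgp"].astype(bool)
        & (evidence["in_ddd"].astype(bool) | evidence["in_cmg"].astype(bool))
        & ~evidence["variant_in_gnomad"].astype(bool)
        & (evidence["oe_missense"].astype(float) < oe_missense_threshold)
    )
    return sorted(evidence.loc[keep, "gene_id"].astype(str))


def shared_annotation_rates(
    gene_set: Iterable[str],
    reference_set: Iterable[str],
    family_map: Mapping[str, Iterable[str]],
    pathway_map: Mapping[str, Iterable[str]],
    edges: pd.DataFrame,
    min_score: float = 0.7,
) -> tuple[float, float, float]:
    """Percentage of genes sharing a protein family, a pathway, or a
    direct high-confidence interaction with any reference gene.

    Self-matches are excluded: a gene that is itself in the reference
    set is compared against the other reference genes only.
    """
    genes = sorted({str(g) for g in gene_set})
    if not genes:
        raise ValueError("empty gene set")
    reference = {str(g) for g in reference_set}
    kept = edges[edges["score"] > min_score]
    graph = nx.Graph()
    graph.add_edges_from(zip(kept["gene_a"].astype(str), kept["gene_b"].astype(str)))

    def shares(g: str, annot: Mapping[str, Iterable[str]]) -> bool:
        mine = set(annot.get(g, ()))
        if not mine:
            return False
        return any(
            mine & set(annot.get(r, ())) for r in reference if r != g
        )

    n_fam = sum(shares(g, family_map) for g in genes)
    n_path = sum(shares(g, pathway_map) for g in genes)
    n_int = sum(
        1
        for g in genes
        if g in graph and any(r in reference and r != g for r in graph[g])
    )
    k = len(genes)
    return (100.0 * n_fam / k, 100.0 * n_path / k, 100.0 * n_int / k)
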