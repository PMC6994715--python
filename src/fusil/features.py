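"""Per-gene features and per-bin comparisons.

Gene properties known to track essentiality — local recombination rate,
expression breadth, protein-protein interaction network position,
protein-complex membership, paralogy, age of disease onset, and the
number of physiological systems affected — are computed here and
compared across FUSIL bins with two-sided Wilcoxon rank-sum tests under
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

__all__ = [
    "ONSET_ORDER",
    "average_recombination_per_gene",
    "drop_correlated_columns",
    "network_node_stats",
    "paralogue_free_rate",
    "earliest_onset",
    "count_affected_systems",
    "pairwise_bin_tests",
]

logger = logging.getLogger(__name__)

#: Disease onset categories, earliest first.
ONSET_ORDER = (
    "antenatal",
    "neonatal",
    "infancy",
    "childhood",
    "adolescence",
    "adult",
    "elderly",
)
_ONSET_RANK = {c: i for i, c in enumerate(ONSET_ORDER)}


def average_recombination_per_gene(
    intervals: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Mean recombination rate (cM/Mb) of the intervals nearest each gene.

    Every interval is assigned to the gene minimising genomic distance
    on its chromosome (0 for overlaps); distance ties go to the
    upstream, lower-coordinate gene. Coordinates are 0-based half-open.
    Intervals on chromosomes without genes are dropped with a warning.
    Returns a Series indexed by gene_id (genes with no assigned
    interval are absent).
    """
    for col in ("chrom", "start", "end", "rate"):
        if col not in intervals.columns:
            raise ValueError(f"interval table missing column {col!r}")
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if (intervals["start"] >= intervals["end"]).any():
        raise ValueError("intervals must satisfy start < end")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for chrom, ivs in intervals.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            logger.warning(
                "%d interval(s) on chromosome %s have no genes; dropped",
                len(ivs), chrom,
            )
            continue
        gs = gsub["start"].to_numpy(float)
        ge = gsub["end"].to_numpy(float)
        gid = gsub["gene_id"].to_numpy()
        order = np.lexsort((gid, gs))  # upstream first, then id for determinism
        gs, ge, gid = gs[order], ge[order], gid[order]
        for s, e, rate in zip(
            ivs["start"].to_numpy(float),
            ivs["end"].to_numpy(float),
            ivs["rate"].to_numpy(float),
        ):
            # gap between [s, e) and [gs, ge); 0 when they overlap or abut
            dist = np.maximum(gs - e, s - ge)
            np.maximum(dist, 0.0, out=dist)
            j = int(np.argmin(dist))  # first minimum = upstream tie-break
            g = gid[j]
            sums[g] = sums.get(g, 0.0) + rate
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(
        {g: sums[g] / counts[g] for g in sums}, name="recomb_rate", dtype=float
    )


def drop_correlated_columns(
    matrix: pd.DataFrame, rho_max: float = 0.8
) -> list[str]:
    """Greedy retention of mutually non-correlated columns.

    Columns are visited in input order; a column is retained iff its
    absolute Spearman correlation with every already-retained column is
    <= ``rho_max``. Constant columns (undefined rho) are retained with
    a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    retained: list[str] = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(float)
        if np.nanstd(x) == 0:
            logger.warning("column %s is constant; correlation undefined, retained", col)
            retained.append(col)
            continue
        ok = True
        for kept in retained:
            rho = stats.spearmanr(x, matrix[kept].to_numpy(float)).statistic
            if np.isfinite(rho) and abs(rho) > rho_max:
                ok = False
                break
        if ok:
            retained.append(col)
    return retained


def network_node_stats(
    edges: pd.DataFrame, min_score: float = 0.7
) -> pd.DataFrame:
    """Degree and topological coefficient on the high-confidence graph.

    Edges with ``score > min_score`` form an undirected simple graph
    (self-loops dropped with a warning). The topological coefficient of
    a node n with k_n >= 2 neighbours averages J(n, m) / k_n over all
    nodes m sharing at least one neighbour with n, where J(n, m) is the
    shared-neighbour count plus one if n and m are directly linked;
    nodes with fewer than two neighbours get 0.
    """
    for col in ("gene_a", "gene_b", "score"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    kept = edges[edges["score"] > min_score]
    loops = kept["gene_a"] == kept["gene_b"]
    if loops.any():
        logger.warning("dropped %d self-loop(s)", int(loops.sum()))
        kept = kept[~loops]
    graph = nx.Graph()
    graph.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))
    rows = []
    for n in graph.nodes:
        nbrs = set(graph[n])
        k = len(nbrs)
        if k < 2:
            rows.append((n, k, 0.0))
            continue
        total, count = 0.0, 0
        partners = {m for v in nbrs for m in graph[v]} - {n}
        for m in partners:
            shared = len(nbrs & set(graph[m]))
            if shared == 0:
                continue
            total += shared + (1 if graph.has_edge(n, m) else 0)
            count += 1
        tc = total / (count * k) if count else 0.0
        rows.append((n, k, tc))
    return pd.DataFrame(rows, columns=["gene_id", "degree", "topo_coeff"])


def paralogue_free_rate(
    bins: Mapping[str, str],
    paralogue_pairs: pd.DataFrame,
    cutoff: float = 30.0,
) -> dict[str, float]:
    """Percentage of genes per bin with no paralogue at or above the
    amino-acid identity cutoff (percent identity in [0, 100])."""
    if not paralogue_pairs.empty:
        ident = paralogue_pairs["identity"]
        if ((ident < 0) | (ident > 100)).any():
            raise ValueError("identity must be a percentage in [0, 100]")
        with_par = set(
            paralogue_pairs.loc[ident >= cutoff, "gene_id"].astype(str)
        )
    else:
        with_par = set()
    out: dict[str, float] = {}
    by_bin: dict[str, list[str]] = {}
    for gene, b in bins.items():
        by_bin.setdefault(b, []).append(gene)
    for b, genes in by_bin.items():
        free = sum(1 for g in genes if g not in with_par)
        out[b] = 100.0 * free / len(genes)
    return out


def earliest_onset(per_gene_onsets: Mapping[str, Iterable[str]]) -> dict[str, str]:
    """Earliest (minimum-rank) onset category per gene; genes with an
    empty set are omitted."""
    out: dict[str, str] = {}
    for gene, cats in per_gene_onsets.items():
        cats = list(cats)
        if not cats:
            continue
        for c in cats:
            if c not in _ONSET_RANK:
                raise ValueError(f"unknown onset category {c!r}")
        out[gene] = min(cats, key=_ONSET_RANK.__getitem__)
    return out


def count_affected_systems(
    per_gene_terms: Mapping[str, Iterable[str]],
) -> dict[str, int]:
    """Number of unique top-level phenotype systems per gene."""
    return {gene: len(set(terms)) for gene, terms in per_gene_terms.items()}


def pairwise_bin_tests(
    feature: Mapping[str, float],
    bins: Mapping[str, str],
    min_genes: int = 3,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between every pair of bins.

    Returns a symmetric bin x bin matrix of BH-adjusted p-values
    (adjustment across the pairs of this feature); the diagonal is NaN
    and pairs involving a bin with fewer than ``min_genes`` observed
    values are skipped with a warning.
    """
    values: dict[str, np.ndarray] = {}
    for b in sorted(set(bins.values())):
        v = np.array(
            [feature[g] for g, gb in bins.items() if gb == b and g in feature],
            dtype=float,
        )
        values[b] = v[np.isfinite(v)]
    labels = sorted(values)
    if len(labels) < 2:
        raise ValueError("need at least two bins")
    pairs, raw = [], []
    for b1, b2 in itertools.combinations(labels, 2):
        if len(values[b1]) < min_genes or len(values[b2]) < min_genes:
            logger.warning("pair (%s, %s) skipped: fewer than %d genes", b1, b2, min_genes)
            continue
        p = stats.mannwhitneyu(values[b1], values[b2], alternative="two-sided").pvalue
        pairs.append((b1, b2))
        raw.append(float(p))
    adjusted = bh_adjust(raw)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (b1, b2), q in zip(pairs, adjusted):
        mat.loc[b1, b2] = q
        mat.loc[b2, b1] = q
    return mat
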