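"""Disease-gene enrichment statistics.

Per FUSIL bin, disease-gene overrepresentation is measured on a 2x2
contingency table (disease/non-disease x in-bin/outside-bin) with the
Wald (unconditional maximum likelihood) odds ratio, a normal-
approximation confidence interval on the log scale, a two-sided Fisher
exact p-value, and Benjamini-Hochberg adjustment across the bins of
each disease resource. A generic one-sided hypergeometric test covers
term (GO/pathway style) over-representation against a reference
universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "odds_ratio_wald",
    "fisher_two_sided",
    "bh_adjust",
    "bin_disease_enrichment",
    "term_overrepresentation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a/b = disease/non-disease genes inside the group,
    c/d = disease/non-disease genes outside it."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")


@dataclass(frozen=True)
class WaldOddsRatio:
    or_hat: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    group: str
    resource: str
    table: ContingencyTable
    or_hat: float
    ci_low: float
    ci_high: float
    degenerate: bool
    p_fisher: float
    p_adjusted: float


def odds_ratio_wald(t: ContingencyTable, level: float = 0.95) -> WaldOddsRatio:
    """Wald odds ratio (a*d)/(b*c) with log-normal CI.

    Tables with a zero cell yield a 0 or infinite point estimate, an
    undefined (NaN) interval and ``degenerate=True``; no continuity
    correction is applied by default.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if a * d == 0 and b * c == 0:
            or_hat = float("nan")
        elif b * c == 0:
            or_hat = float("inf")
        else:
            or_hat = 0.0
        return WaldOddsRatio(or_hat, float("nan"), float("nan"), True)
    or_hat = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_hat)
    return WaldOddsRatio(
        or_hat, math.exp(log_or - z * se), math.exp(log_or + z * se), False
    )


def haldane_corrected_or(t: ContingencyTable, level: float = 0.95) -> WaldOddsRatio:
    """Variant with the Haldane-Anscombe 0.5 correction on every cell,
    for callers who prefer a finite estimate on sparse tables."""
    a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
    or_hat = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_hat)
    return WaldOddsRatio(
        or_hat, math.exp(log_or - z * se), math.exp(log_or + z * se), False
    )


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value, probability-ordering convention.

    Exact integer arithmetic: conditioned on the margins, the
    hypergeometric probability of a table with top-left cell k is
    C(r1, k) * C(r2, c1 - k) / C(n, c1); all tables share the
    denominator, so tables at most as probable as the observed one are
    found by comparing integer numerators, avoiding floating-point tie
    ambiguity.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if lo == hi:
        return 1.0
    n_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        n_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if n_k <= n_obs:
            total += n_k
    return float(Fraction(total, math.comb(n, c1)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bin_disease_enrichment(
    assignments: pd.DataFrame,
    disease_sets: Mapping[str, Iterable[str]],
    level: float = 0.95,
) -> list[EnrichmentResult]:
    """Disease-gene enrichment of every FUSIL bin against the rest.

    ``assignments`` needs columns ``gene_id`` and ``bin``; only the five
    FUSIL bins form the comparison universe. For each resource, the
    disease set is compared with the genes annotated in *no* resource
    (genes annotated only in other resources drop out of that
    resource's table), and BH adjustment runs across the bins of the
    resource.
    """
    from .binning import FUSIL_BINS

    df = assignments[assignments["bin"].isin(FUSIL_BINS)]
    if df["bin"].nunique() < 2:
        raise ValueError("need assignments covering at least two bins")
    universe = set(df["gene_id"])
    gene_bin = dict(zip(df["gene_id"], df["bin"]))
    any_disease = set()
    cleaned: dict[str, set[str]] = {}
    for resource, genes in disease_sets.items():
        cleaned[resource] = set(genes) & universe
        any_disease |= cleaned[resource]
    non_disease = universe - any_disease

    results: list[EnrichmentResult] = []
    for resource, disease in cleaned.items():
        if not disease:
            logger.warning("resource %s has no genes in the universe; skipped", resource)
            continue
        partial = []
        for b in FUSIL_BINS:
            in_bin_d = sum(1 for g in disease if gene_bin[g] == b)
            in_bin_n = sum(1 for g in non_disease if gene_bin[g] == b)
            table = ContingencyTable(
                in_bin_d,
                in_bin_n,
                len(disease) - in_bin_d,
                len(non_disease) - in_bin_n,
            )
            wald = odds_ratio_wald(table, level)
            partial.append((b, table, wald, fisher_two_sided(table)))
        adjusted = bh_adjust([p for *_, p in partial])
        for (b, table, wald, p), q in zip(partial, adjusted):
            results.append(
                EnrichmentResult(
                    b,
                    resource,
                    table,
                    wald.or_hat,
                    wald.ci_low,
                    wald.ci_high,
                    wald.degenerate,
                    p,
                    float(q),
                )
            )
    return results


def term_overrepresentation(
    study_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of annotation terms
    in a study set, BH-adjusted across terms.

    The universe is the reference gene set (e.g. every gene entering
    the FUSIL analysis); the study set must be contained in it.
    """
    universe_set = set(universe)
    study = set(study_set)
    if not study <= universe_set:
        raise ValueError("study set must be a subset of the universe")
    M, N = len(universe_set), len(study)
    partial = []
    for term, genes in annotations.items():
        term_genes = set(genes) & universe_set
        if not term_genes:
            logger.warning("term %s has no genes in the universe; skipped", term)
            continue
        K = len(term_genes)
        k = len(term_genes & study)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        p = min(p, 1.0)
        table = ContingencyTable(k, N - k, K - k, M - K - (N - k))
        wald = odds_ratio_wald(table)
        partial.append((term, table, wald, p))
    adjusted = bh_adjust([p for *_, p in partial])
    return [
        EnrichmentResult(
            term, "terms", table, wald.or_hat, wald.ci_low, wald.ci_high,
            wald.degenerate, p, float(q),
        )
        for (term, table, wald, p), q in zip(partial, adjusted)
    ]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results to the tabular output schema."""
    return pd.DataFrame(
        {
            "resource": [r.resource for r in results],
            "group": [r.group for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.or_hat for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_fisher": [r.p_fisher for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
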