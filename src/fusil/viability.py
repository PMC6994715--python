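"""Mouse knockout viability calling.

The primary viability screen genotypes pups from a heterozygote-by-
heterozygote intercross. Under Mendelian segregation one quarter of the
pups should be homozygous null; a complete absence of homozygotes marks
the gene as lethal, a significant deficit (less than half the expected
fraction, supported by an exact binomial test) as subviable, and
anything else as viable. Genes are additionally screened as embryos at
fixed gestational stages to place lethal genes into a window of
lethality (early / mid / late gestation).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityObservation",
    "ViabilityCall",
    "EmbryoRecord",
    "call_primary_viability",
    "call_probabilities",
    "resolve_gene_calls",
    "assign_lethality_window",
    "call_viability_table",
    "MIN_PUPS",
    "EXPECTED_HOM_FRACTION",
    "SUBVIABLE_FRACTION",
    "STAGES",
]

#: Minimum genotyped pups for a fully-powered primary call.
MIN_PUPS = 28
#: Mendelian expectation for homozygotes from a het x het cross.
EXPECTED_HOM_FRACTION = 0.25
#: Subviable lines show less than half the expected homozygote fraction.
SUBVIABLE_FRACTION = 0.125
#: With fewer than MIN_PUPS pups, this many homozygotes still implies a
#: homozygote fraction of at least 14% had 28 pups been genotyped.
VIABLE_EXCEPTION_MIN_HOM = 4

#: Embryonic stages scored for a live homozygote heartbeat, in
#: developmental order.
STAGES = ("E9.5", "E12.5", "E14.5_15.5", "E18.5")

SUBSTANTIVE_CALLS = frozenset({"lethal", "subviable", "viable"})


@dataclass(frozen=True)
class ViabilityObservation:
    """Genotyping counts for one mouse line."""

    line_id: str
    gene_id: str
    zygosity_class: str = "autosomal"
    n_total: int = 0
    n_hom: int = 0
    procedures_total: int = 0
    procedures_done: int = 0
    n_significant_phenotypes: int = 0

    def __post_init__(self) -> None:
        if self.zygosity_class not in ("autosomal", "hemizygous"):
            raise ValueError(f"unknown zygosity_class: {self.zygosity_class!r}")
        if not 0 <= self.n_hom <= self.n_total:
            raise ValueError(
                f"line {self.line_id}: n_hom={self.n_hom} outside [0, n_total={self.n_total}]"
            )
        if self.procedures_done > self.procedures_total:
            raise ValueError(
                f"line {self.line_id}: procedures_done exceeds procedures_total"
            )


@dataclass(frozen=True)
class ViabilityCall:
    gene_id: str
    call: str
    hom_fraction: float = float("nan")
    binom_p: float = float("nan")


@dataclass(frozen=True)
class EmbryoRecord:
    """Embryo heartbeat screen at one gestational stage."""

    gene_id: str
    stage: str
    n_scored: int
    n_live_hom: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not 0 <= self.n_live_hom <= self.n_scored:
            raise ValueError("n_live_hom must lie in [0, n_scored]")


def call_primary_viability(
    obs: ViabilityObservation, alpha: float = 0.05
) -> ViabilityCall:
    """Classify one line as lethal / subviable / viable.

    Decision order:

    1. hemizygous lines are excluded outright;
    2. with fewer than 28 pups, >= 4 homozygotes still supports a
       viable call, otherwise the sample is insufficient;
    3. zero homozygotes => lethal;
    4. homozygote fraction < 12.5% *and* one-sided exact binomial
       lower-tail P(X <= n_hom; n_total, 0.25) < ``alpha`` => subviable;
    5. otherwise viable.
    """
    if obs.n_hom > obs.n_total:
        raise ValueError("n_hom exceeds n_total")
    if obs.zygosity_class == "hemizygous":
        return ViabilityCall(obs.gene_id, "excluded_hemizygous")
    frac = obs.n_hom / obs.n_total if obs.n_total else float("nan")
    if obs.n_total < MIN_PUPS:
        if obs.n_hom >= VIABLE_EXCEPTION_MIN_HOM:
            return ViabilityCall(obs.gene_id, "viable", frac)
        return ViabilityCall(obs.gene_id, "insufficient", frac)
    if obs.n_hom == 0:
        return ViabilityCall(obs.gene_id, "lethal", 0.0)
    p = float(stats.binom.cdf(obs.n_hom, obs.n_total, EXPECTED_HOM_FRACTION))
    if frac < SUBVIABLE_FRACTION and p < alpha:
        return ViabilityCall(obs.gene_id, "subviable", frac, p)
    return ViabilityCall(obs.gene_id, "viable", frac, p)


def call_probabilities(
    p_hom: float, n_total: int, alpha: float = 0.05
) -> dict[str, float]:
    """Analytic probability of each primary call for a line whose true
    homozygote rate is ``p_hom`` and which genotypes ``n_total`` pups.

    Exact binomial arithmetic over the decision rule of
    :func:`call_primary_viability`; used to flag genes whose latent
    parameters put them at non-negligible risk of an honest miscall.
    """
    if not 0.0 <= p_hom <= 1.0:
        raise ValueError("p_hom must be a probability")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    dist = stats.binom(n_total, p_hom)
    if n_total < MIN_PUPS:
        p_viable = float(dist.sf(VIABLE_EXCEPTION_MIN_HOM - 1))
        return {
            "lethal": 0.0,
            "subviable": 0.0,
            "viable": p_viable,
            "insufficient": 1.0 - p_viable,
        }
    p_lethal = float(dist.pmf(0))
    null = stats.binom(n_total, EXPECTED_HOM_FRACTION)
    # largest k passing both subviable criteria (both are monotone in k)
    k_frac = math.ceil(SUBVIABLE_FRACTION * n_total) - 1
    k_sub = -1
    for k in range(k_frac, -1, -1):
        if null.cdf(k) < alpha:
            k_sub = k
            break
    p_sub = float(dist.cdf(k_sub)) - p_lethal if k_sub >= 1 else 0.0
    p_sub = max(p_sub, 0.0)
    return {
        "lethal": p_lethal,
        "subviable": p_sub,
        "viable": 1.0 - p_lethal - p_sub,
        "insufficient": 0.0,
    }


def resolve_gene_calls(calls_per_line: Sequence[ViabilityCall]) -> ViabilityCall:
    """Collapse per-line calls into one gene-level call.

    Hemizygous lines exclude the gene; insufficient lines carry no
    category; unanimous substantive calls win; disagreement between
    substantive calls excludes the gene as conflicting.
    """
    if not calls_per_line:
        raise ValueError("resolve_gene_calls requires at least one line call")
    gene_id = calls_per_line[0].gene_id
    if any(c.call == "excluded_hemizygous" for c in calls_per_line):
        return ViabilityCall(gene_id, "excluded_hemizygous")
    substantive = [c for c in calls_per_line if c.call in SUBSTANTIVE_CALLS]
    if not substantive:
        return ViabilityCall(gene_id, "insufficient")
    categories = {c.call for c in substantive}
    if len(categories) > 1:
        return ViabilityCall(gene_id, "excluded_conflicting")
    if len(substantive) == 1:
        return substantive[0]
    return ViabilityCall(gene_id, substantive[0].call)


_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}
# death intervals: index i means death between stage i-1 and stage i;
# i == len(STAGES) means death after the last scored stage (the gene is
# known preweaning lethal). Intervals 0 -> early; 1, 2 -> mid; rest late.
_INTERVAL_GROUP = {0: "early", 1: "mid", 2: "mid", 3: "late", 4: "late"}


def assign_lethality_window(
    records: Iterable[EmbryoRecord], min_scored: int = MIN_PUPS
) -> str:
    """Place a preweaning-lethal gene into a window of lethality.

    A stage is *dead* when no live homozygote was seen among at least
    ``min_scored`` embryos, *alive* when any live homozygote was seen
    (regardless of how many were scored). The fine window is the
    interval between the last alive stage and the first dead stage;
    windows collapse to early (death before E9.5), mid (E9.5 to
    E14.5/15.5) or late (any later death, including genes still alive
    at E18.5). If the scored stages leave the group ambiguous the gene
    is unassigned.
    """
    status: dict[int, str] = {}
    for rec in records:
        i = _STAGE_INDEX[rec.stage]
        if rec.n_live_hom > 0:
            s = "alive"
        elif rec.n_scored >= min_scored:
            s = "dead"
        else:
            continue  # underpowered zero count: uninformative
        if status.get(i, s) != s:
            raise ValueError(f"contradictory records for stage {rec.stage}")
        status[i] = s
    candidates = []
    for interval in range(len(STAGES) + 1):
        if any(s == "dead" for i, s in status.items() if i < interval):
            continue
        if any(s == "alive" for i, s in status.items() if i >= interval):
            continue
        candidates.append(interval)
    groups = {_INTERVAL_GROUP[i] for i in candidates}
    if len(groups) == 1:
        return groups.pop()
    return "unassigned"


def call_viability_table(
    observations: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Vectorised convenience wrapper: per-line calls then gene-level
    resolution for a table of :class:`ViabilityObservation` rows.

    Returns one row per gene with columns ``gene_id, call,
    hom_fraction, binom_p``.
    """
    required = {"line_id", "gene_id", "zygosity_class", "n_total", "n_hom"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    calls: dict[str, list[ViabilityCall]] = {}
    for row in observations.itertuples(index=False):
        obs = ViabilityObservation(
            line_id=str(row.line_id),
            gene_id=str(row.gene_id),
            zygosity_class=str(row.zygosity_class),
            n_total=int(row.n_total),
            n_hom=int(row.n_hom),
        )
        calls.setdefault(obs.gene_id, []).append(call_primary_viability(obs, alpha))
    resolved = [resolve_gene_calls(v) for v in calls.values()]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in resolved],
            "call": [c.call for c in resolved],
            "hom_fraction": [c.hom_fraction for c in resolved],
            "binom_p": [c.binom_p for c in resolved],
        }
    )
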