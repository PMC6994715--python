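"""Synthetic dataset generator with known ground truth.

Every input table the pipeline consumes can be generated here from a
latent truth: each gene is assigned a latent FUSIL class, which drives
its mouse intercross counts (homozygote rate 0 for lethal classes, a
small rate for subviable, the Mendelian 0.25 for viable), its
cell-line proliferation scores (essential genes centred at -1,
non-essential at 0, the outlier groups placed just below the -0.45
threshold), its disease-gene status (per-bin odds ratios against a
baseline prevalence), and class-conditional gene features. The truth
table records everything needed for parameter-recovery tests.

All randomness flows from one seeded :class:`numpy.random.Generator`;
a fixed config and seed reproduce the bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import functools
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .viability import EXPECTED_HOM_FRACTION, MIN_PUPS, call_probabilities

__all__ = [
    "SyntheticConfig",
    "DatasetBundle",
    "ConfigurationError",
    "generate_dataset",
    "generate_cross",
    "generate_disease_flags",
    "write_bundle",
]

LATENT_CLASSES = (
    "CL", "DL", "SV", "VP", "VN",
    "V.insuffProcedures", "SV.outlier", "V.outlier",
)

_DEFAULT_PROPORTIONS = {
    "CL": 0.09, "DL": 0.17, "SV": 0.09, "VP": 0.42, "VN": 0.07,
    "V.insuffProcedures": 0.14, "SV.outlier": 0.01, "V.outlier": 0.01,
}

# class-conditional feature levels; only the ordering across bins (and,
# for constraints, position relative to the filter thresholds) matters
_EXPRESSION_BASE = {"CL": 6.0, "DL": 5.0, "SV": 4.5, "VP": 3.5, "VN": 3.0,
                    "V.insuffProcedures": 3.5, "SV.outlier": 4.5, "V.outlier": 3.5}
_RECOMB_BASE = {"CL": 0.8, "DL": 1.2, "SV": 1.6, "VP": 2.0, "VN": 2.4,
                "V.insuffProcedures": 2.0, "SV.outlier": 1.6, "V.outlier": 2.0}
_DEGREE_WEIGHT = {"CL": 6.0, "DL": 4.0, "SV": 3.0, "VP": 2.0, "VN": 1.5,
                  "V.insuffProcedures": 2.0, "SV.outlier": 3.0, "V.outlier": 2.0}
_COMPLEX_PROB = {"CL": 0.55, "DL": 0.40, "SV": 0.30, "VP": 0.18, "VN": 0.10,
                 "V.insuffProcedures": 0.20, "SV.outlier": 0.30, "V.outlier": 0.20}
_PARALOGUE_PROB = {"CL": 0.30, "DL": 0.45, "SV": 0.55, "VP": 0.70, "VN": 0.80,
                   "V.insuffProcedures": 0.60, "SV.outlier": 0.55, "V.outlier": 0.60}
_SYSTEMS_LAMBDA = {"CL": 3.0, "DL": 3.0, "SV": 2.0, "VP": 1.0, "VN": 1.0,
                   "V.insuffProcedures": 1.0, "SV.outlier": 2.0, "V.outlier": 1.0}
# windows of lethality for the lethal classes (early, mid, late)
_WINDOW_PROBS = {"CL": (0.80, 0.10, 0.10), "DL": (0.30, 0.14, 0.56)}

ESSENTIAL_CLASSES = frozenset({"CL", "SV.outlier", "V.outlier"})
LETHAL_CLASSES = frozenset({"CL", "DL"})
SUBVIABLE_CLASSES = frozenset({"SV", "SV.outlier"})


class ConfigurationError(ValueError):
    """Invalid synthetic configuration; the message names the field."""


@dataclass
class SyntheticConfig:
    n_genes: int = 5000
    n_cell_lines: int = 100
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    hom_rate_lethal: float = 0.0
    hom_rate_subviable_range: tuple[float, float] = (0.01, 0.08)
    hom_rate_viable: float = 0.25
    litter_extra_mean: float = 20.0  # litter total = 28 + Poisson(mean)
    small_litter_fraction: float = 0.02  # forced below 28 pups
    hemizygous_rate: float = 0.0
    score_mean_essential: float = -1.0
    score_mean_nonessential: float = 0.0
    score_sd_between: float = 0.2
    score_sd_within: float = 0.3
    score_missing_rate: float = 0.01
    disease_baseline_prevalence: float = 0.20
    true_bin_or: dict[str, float] = field(default_factory=lambda: {"DL": 2.6})
    resource_rates: dict[str, float] = field(
        default_factory=lambda: {"omim": 0.7, "orphanet": 0.5, "ddg2p": 0.35}
    )
    orthology_ambiguity_rate: float = 0.02
    true_candidate_fraction: float = 0.10  # of DL non-disease genes
    consortium_hit_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "candidate": {"in_100kgp": 0.95, "in_ddd": 0.75, "in_cmg": 0.50},
            "background": {"in_100kgp": 0.05, "in_ddd": 0.05, "in_cmg": 0.05},
        }
    )
    gnomad_rate_candidate: float = 0.05
    gnomad_rate_background: float = 0.50
    n_tissues: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_cell_lines < 1:
            raise ConfigurationError("n_cell_lines must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions must sum to 1 (got {total})"
            )
        for cls, p in self.class_proportions.items():
            if cls not in LATENT_CLASSES:
                raise ConfigurationError(f"class_proportions: unknown class {cls!r}")
            if p < 0:
                raise ConfigurationError("class_proportions must be non-negative")
        for name in (
            "hom_rate_lethal", "hom_rate_viable", "small_litter_fraction",
            "hemizygous_rate", "score_missing_rate", "disease_baseline_prevalence",
            "orthology_ambiguity_rate", "true_candidate_fraction",
            "gnomad_rate_candidate", "gnomad_rate_background",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        lo, hi = self.hom_rate_subviable_range
        if not 0.0 <= lo <= hi <= EXPECTED_HOM_FRACTION:
            raise ConfigurationError(
                "hom_rate_subviable_range must lie within [0, 0.25]"
            )
        if not 0.0 < self.disease_baseline_prevalence < 1.0:
            raise ConfigurationError(
                "disease_baseline_prevalence must lie strictly in (0, 1)"
            )
        for b, r in self.true_bin_or.items():
            if r <= 0:
                raise ConfigurationError(f"true_bin_or[{b!r}] must be > 0")
        for group, rates in self.consortium_hit_rates.items():
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(
                        f"consortium_hit_rates[{group!r}][{k!r}] must be in [0, 1]"
                    )
        if self.score_sd_between < 0 or self.score_sd_within < 0:
            raise ConfigurationError("score standard deviations must be >= 0")
        if self.litter_extra_mean < 0:
            raise ConfigurationError("litter_extra_mean must be >= 0")
        if self.n_tissues < 2:
            raise ConfigurationError("n_tissues must be >= 2")


@dataclass
class DatasetBundle:
    """Every generated input table plus the latent truth."""

    config: SyntheticConfig
    truth: pd.DataFrame
    crosses: pd.DataFrame
    embryo: pd.DataFrame
    scores: pd.DataFrame
    orthology: pd.DataFrame
    constraints: pd.DataFrame
    disease: pd.DataFrame
    onsets: pd.DataFrame
    systems: pd.DataFrame
    evidence: pd.DataFrame
    recomb_intervals: pd.DataFrame
    gene_positions: pd.DataFrame
    edges: pd.DataFrame
    complexes: pd.DataFrame
    paralogues: pd.DataFrame
    expression: pd.DataFrame
    families: pd.DataFrame
    pathways: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "config"
        }

    def disease_sets(self) -> dict[str, set[str]]:
        return {
            res: set(self.disease.loc[self.disease[f"in_{res}"], "gene_id"])
            for res in ("omim", "orphanet", "ddg2p")
        }


def generate_cross(
    p_hom: float, total_pups: int, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Simulate genotyped pup counts from one het x het intercross.

    Homozygotes are Binomial(total, p_hom); the remaining pups split
    het:wt as 2:1 of the residual probability mass. Returns
    (n_total, n_hom, n_het, n_wt).
    """
    if p_hom < 0:
        raise ValueError("p_hom must be non-negative")
    if p_hom > EXPECTED_HOM_FRACTION:
        raise ValueError(
            f"p_hom={p_hom} exceeds the Mendelian expectation of 0.25"
        )
    if total_pups < 1:
        raise ValueError("total_pups must be >= 1")
    n_hom = int(rng.binomial(total_pups, p_hom))
    n_het = int(rng.binomial(total_pups - n_hom, 2.0 / 3.0))
    n_wt = total_pups - n_hom - n_het
    return total_pups, n_hom, n_het, n_wt


def generate_disease_flags(
    bins: Mapping[str, str],
    baseline: float,
    true_bin_or: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, bool]:
    """Disease-gene flags with configured per-bin odds ratios.

    A gene in bin b with target odds ratio r gets disease probability
    p_b solving odds(p_b) = r * odds(baseline); bins not listed in
    ``true_bin_or`` stay at the baseline prevalence.
    """
    if not 0.0 < baseline < 1.0:
        raise ConfigurationError("baseline must lie strictly in (0, 1)")
    for b, r in true_bin_or.items():
        if r <= 0:
            raise ConfigurationError(f"odds ratio for bin {b!r} must be > 0")
    base_odds = baseline / (1.0 - baseline)
    probs = {}
    for b, r in true_bin_or.items():
        odds = r * base_odds
        probs[b] = odds / (1.0 + odds)
    genes = list(bins)
    p = np.array([probs.get(bins[g], baseline) for g in genes])
    draws = rng.random(len(genes)) < p
    return dict(zip(genes, (bool(x) for x in draws)))


@functools.lru_cache(maxsize=4096)
def _miscall_prob(p_hom: float, n_total: int, expected_call: str) -> float:
    probs = call_probabilities(p_hom, n_total)
    return 1.0 - probs[expected_call]


def _expected_call(cls: str) -> str:
    if cls in LETHAL_CLASSES:
        return "lethal"
    if cls in SUBVIABLE_CLASSES:
        return "subviable"
    return "viable"


def generate_dataset(config: SyntheticConfig) -> DatasetBundle:
    """Generate the full input bundle and its latent truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])

    classes_pool = list(config.class_proportions)
    props = np.array([config.class_proportions[c] for c in classes_pool])
    classes = rng.choice(classes_pool, size=n, p=props / props.sum())

    # --- mouse crosses -------------------------------------------------
    hom_rate = np.full(n, config.hom_rate_viable)
    lethal_mask = np.isin(classes, list(LETHAL_CLASSES))
    sub_mask = np.isin(classes, list(SUBVIABLE_CLASSES))
    hom_rate[lethal_mask] = config.hom_rate_lethal
    lo, hi = config.hom_rate_subviable_range
    hom_rate[sub_mask] = rng.uniform(lo, hi, size=int(sub_mask.sum()))

    totals = MIN_PUPS + rng.poisson(config.litter_extra_mean, size=n)
    small = rng.random(n) < config.small_litter_fraction
    totals[small] = rng.integers(10, MIN_PUPS, size=int(small.sum()))
    hemizygous = rng.random(n) < config.hemizygous_rate

    cross_rows = []
    for g, cls, p_h, tot, hemi in zip(genes, classes, hom_rate, totals, hemizygous):
        _, n_hom, n_het, n_wt = generate_cross(float(p_h), int(tot), rng)
        cross_rows.append((f"{g}_L1", g, "hemizygous" if hemi else "autosomal",
                           int(tot), n_hom, n_het, n_wt))
    crosses = pd.DataFrame(
        cross_rows,
        columns=["line_id", "gene_id", "zygosity_class", "n_total", "n_hom",
                 "n_het", "n_wt"],
    )
    procedures_total = np.full(n, 20)
    procedures_done = rng.integers(10, 21, size=n)
    insuff = classes == "V.insuffProcedures"
    procedures_done[insuff] = rng.integers(0, 10, size=int(insuff.sum()))
    n_signif = np.zeros(n, dtype=int)
    vp = classes == "VP"
    n_signif[vp] = 1 + rng.poisson(2.0, size=int(vp.sum()))
    voutlier = classes == "V.outlier"
    n_signif[voutlier] = rng.poisson(1.0, size=int(voutlier.sum()))
    crosses["procedures_total"] = procedures_total
    crosses["procedures_done"] = procedures_done
    crosses["n_significant_phenotypes"] = n_signif

    # --- embryo screen for lethal classes ------------------------------
    windows = np.array(["none"] * n, dtype=object)
    embryo_rows = []
    for idx in np.flatnonzero(lethal_mask):
        cls = classes[idx]
        w = rng.choice(["early", "mid", "late"], p=_WINDOW_PROBS[cls])
        windows[idx] = w
        g = genes[idx]
        if w == "early":
            embryo_rows.append((g, "E9.5", 30, 0))
        elif w == "mid":
            embryo_rows.append((g, "E9.5", 30, int(1 + rng.binomial(29, 0.25))))
            embryo_rows.append((g, "E12.5", 30, 0))
        else:
            embryo_rows.append((g, "E9.5", 30, int(1 + rng.binomial(29, 0.25))))
            embryo_rows.append((g, "E12.5", 30, int(1 + rng.binomial(29, 0.25))))
            embryo_rows.append((g, "E14.5_15.5", 30, int(1 + rng.binomial(29, 0.25))))
            if rng.random() < 0.8:
                embryo_rows.append((g, "E18.5", 30, 0))
            else:  # died between E18.5 and weaning
                embryo_rows.append((g, "E18.5", 30, int(1 + rng.binomial(29, 0.2))))
    embryo = pd.DataFrame(
        embryo_rows, columns=["gene_id", "stage", "n_scored", "n_live_hom"]
    )

    # --- cell-line proliferation scores --------------------------------
    latent_mean = np.where(
        classes == "CL",
        rng.normal(config.score_mean_essential, config.score_sd_between, size=n),
        rng.normal(config.score_mean_nonessential, config.score_sd_between, size=n),
    )
    outlier_mask = np.isin(classes, ["SV.outlier", "V.outlier"])
    # outliers sit just below the -0.45 essentiality threshold
    latent_mean[outlier_mask] = rng.uniform(-0.60, -0.46, size=int(outlier_mask.sum()))
    score_matrix = latent_mean[:, None] + rng.normal(
        0.0, config.score_sd_within, size=(n, config.n_cell_lines)
    )
    if config.score_missing_rate > 0:
        miss = rng.random(score_matrix.shape) < config.score_missing_rate
        score_matrix[miss] = np.nan
    scores = pd.DataFrame(
        score_matrix,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"CELL{j:03d}" for j in range(1, config.n_cell_lines + 1)],
    )

    # --- orthology ------------------------------------------------------
    n_methods = rng.integers(9, 13, size=n)
    ambiguous = rng.random(n) < config.orthology_ambiguity_rate
    orth_rows = []
    for g, nm, amb in zip(genes, n_methods, ambiguous):
        orth_rows.append((g, f"M_{g}", int(nm), True, True))
        if amb:  # duplicated maximum: both edges of this mouse gene rejected
            orth_rows.append((f"{g}_alt", f"M_{g}", int(nm), True, True))
    orthology = pd.DataFrame(
        orth_rows,
        columns=["human_id", "mouse_id", "n_methods", "human_coding", "mouse_coding"],
    )

    # --- disease flags and resources ------------------------------------
    bins_map = dict(zip(genes, classes))
    flags = generate_disease_flags(
        bins_map, config.disease_baseline_prevalence, config.true_bin_or, rng
    )
    is_disease = np.array([flags[g] for g in genes])
    resources = {}
    for res, rate in config.resource_rates.items():
        resources[res] = is_disease & (rng.random(n) < rate)
    in_any = np.zeros(n, dtype=bool)
    for v in resources.values():
        in_any |= v
    orphan = is_disease & ~in_any  # every disease gene sits in >= 1 resource
    first = next(iter(resources))
    resources[first] = resources[first] | orphan
    disease = pd.DataFrame({"gene_id": genes, "is_disease": is_disease})
    for res, v in resources.items():
        disease[f"in_{res}"] = v

    # --- candidates, constraints, consortium evidence --------------------
    dl_non_disease = np.flatnonzero((classes == "DL") & ~is_disease)
    n_cand = int(round(config.true_candidate_fraction * dl_non_disease.size))
    cand_idx = rng.choice(dl_non_disease, size=n_cand, replace=False) if n_cand else []
    is_candidate = np.zeros(n, dtype=bool)
    is_candidate[cand_idx] = True

    pli = rng.uniform(0.0, 1.0, size=n)
    loeuf = rng.uniform(0.1, 1.5, size=n)
    hi_pct = rng.uniform(0.0, 100.0, size=n)
    pli[is_candidate] = rng.uniform(0.92, 1.0, size=n_cand)
    loeuf[is_candidate] = rng.uniform(0.05, 0.30, size=n_cand)
    hi_pct[is_candidate] = rng.uniform(0.0, 9.0, size=n_cand)
    for arr in (pli, loeuf, hi_pct):  # sparse missingness in real tables
        missing = (rng.random(n) < 0.02) & ~is_candidate
        arr[missing] = np.nan
    constraints = pd.DataFrame(
        {
            "gene_id": genes,
            "pli": pli,
            "loeuf": loeuf,
            "hi_percentile": hi_pct,
            "oe_missense": rng.uniform(0.5, 1.4, size=n),
            "gims": rng.normal(0.0, 1.0, size=n),
            "prob_mutation": rng.uniform(1e-6, 1e-4, size=n),
            "transcript_length_max": rng.integers(500, 100_000, size=n),
        }
    )

    hit = config.consortium_hit_rates
    evidence = pd.DataFrame({"gene_id": genes})
    for col in ("in_100kgp", "in_ddd", "in_cmg"):
        rate = np.where(is_candidate, hit["candidate"][col], hit["background"][col])
        evidence[col] = rng.random(n) < rate
    evidence["variant_in_gnomad"] = rng.random(n) < np.where(
        is_candidate, config.gnomad_rate_candidate, config.gnomad_rate_background
    )
    oe_mis = rng.uniform(0.5, 1.4, size=n)
    oe_mis[is_candidate] = rng.uniform(0.3, 0.7, size=n_cand)
    evidence["oe_missense"] = oe_mis
    constraints["oe_missense"] = oe_mis

    # --- genome layout and recombination map -----------------------------
    half = (n + 1) // 2
    chrom = np.where(np.arange(n) < half, "1", "2")
    within = np.where(np.arange(n) < half, np.arange(n), np.arange(n) - half)
    g_start = within * 100_000
    gene_positions = pd.DataFrame(
        {"gene_id": genes, "chrom": chrom, "start": g_start, "end": g_start + 20_000}
    )
    recomb_latent = np.array([_RECOMB_BASE[c] for c in classes]) + np.abs(
        rng.normal(0.0, 0.2, size=n)
    )
    iv_rows = []
    for g, ch, s, r in zip(genes, chrom, g_start, recomb_latent):
        for off in (1_000, 8_000):
            iv_rows.append(
                (ch, int(s + off), int(s + off + 5_000),
                 max(0.0, r + rng.normal(0.0, 0.05)))
            )
    recomb_intervals = pd.DataFrame(iv_rows, columns=["chrom", "start", "end", "rate"])

    # --- interaction network ---------------------------------------------
    weights = np.array([_DEGREE_WEIGHT[c] for c in classes])
    weights = weights / weights.sum()
    m_edges = 2 * n
    a = rng.choice(n, size=m_edges, p=weights)
    b = rng.choice(n, size=m_edges, p=weights)
    keep = a != b
    edges = pd.DataFrame(
        {
            "gene_a": genes[a[keep]],
            "gene_b": genes[b[keep]],
            "score": rng.uniform(0.4, 1.0, size=int(keep.sum())),
        }
    )

    # --- complexes, paralogues, expression, annotation maps --------------
    cplx_prob = np.array([_COMPLEX_PROB[c] for c in classes])
    in_complex = rng.random(n) < cplx_prob
    complexes = pd.DataFrame(
        {
            "gene_id": genes[in_complex],
            "complex_id": [
                f"CPX{int(x):04d}"
                for x in rng.integers(0, max(1, n // 10), size=int(in_complex.sum()))
            ],
        }
    )
    par_prob = np.array([_PARALOGUE_PROB[c] for c in classes])
    has_par = rng.random(n) < par_prob
    paralogues = pd.DataFrame(
        {
            "gene_id": genes[has_par],
            "partner": [f"P_{g}" for g in genes[has_par]],
            "identity": rng.uniform(10.0, 90.0, size=int(has_par.sum())),
        }
    )

    expr_base = np.array([_EXPRESSION_BASE[c] for c in classes])
    tissue_effect = rng.normal(0.0, 0.3, size=config.n_tissues)
    expr = (
        expr_base[:, None]
        + tissue_effect[None, :]
        + rng.normal(0.0, 0.5, size=(n, config.n_tissues))
    )
    expr_cols = [f"T{j:02d}" for j in range(1, config.n_tissues + 1)]
    # two near-duplicate tissues exercise the decorrelation filter
    dup1 = expr[:, 0] + rng.normal(0.0, 0.05, size=n)
    dup2 = expr[:, 1] + rng.normal(0.0, 0.05, size=n)
    expression = pd.DataFrame(
        np.column_stack([expr, dup1, dup2]),
        index=pd.Index(genes, name="gene_id"),
        columns=expr_cols
        + [f"T{config.n_tissues + 1:02d}", f"T{config.n_tissues + 2:02d}"],
    )

    fam_pool = [f"FAM{i:03d}" for i in range(200)]
    path_pool = [f"PATH{i:03d}" for i in range(300)]
    fam_rows, path_rows = [], []
    for g in genes:
        for f_ in rng.choice(fam_pool, size=rng.integers(1, 3), replace=False):
            fam_rows.append((g, f_))
        for p_ in rng.choice(path_pool, size=rng.integers(1, 4), replace=False):
            path_rows.append((g, p_))
    families = pd.DataFrame(fam_rows, columns=["gene_id", "family"])
    pathways = pd.DataFrame(path_rows, columns=["gene_id", "pathway"])

    # --- onsets and affected systems (disease genes only) -----------------
    from .features import ONSET_ORDER

    onset_rows, system_rows = [], []
    early_w = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
    late_w = early_w[::-1].copy()
    sys_pool = [f"SYS{i:02d}" for i in range(1, 16)]
    for idx in np.flatnonzero(is_disease):
        g, cls = genes[idx], classes[idx]
        w = early_w if cls in ("CL", "DL", "SV", "SV.outlier") else late_w
        k = int(rng.integers(1, 3))
        cats = rng.choice(list(ONSET_ORDER), size=k, replace=False, p=w / w.sum())
        onset_rows.extend((g, c) for c in cats)
        n_sys = 1 + int(rng.poisson(_SYSTEMS_LAMBDA[cls]))
        n_sys = min(n_sys, len(sys_pool))
        system_rows.extend(
            (g, s) for s in rng.choice(sys_pool, size=n_sys, replace=False)
        )
    onsets = pd.DataFrame(onset_rows, columns=["gene_id", "onset"])
    systems = pd.DataFrame(system_rows, columns=["gene_id", "system"])

    # --- borderline flags (analytic, from the latent truth) ---------------
    n_hom_obs = crosses["n_hom"].to_numpy()
    borderline = np.zeros(n, dtype=bool)
    for i in range(n):
        if abs(latent_mean[i] - (-0.45)) < 0.10:
            borderline[i] = True
            continue
        if totals[i] < MIN_PUPS:
            borderline[i] = True
            continue
        expected = _expected_call(classes[i])
        if _miscall_prob(round(float(hom_rate[i]), 6), int(totals[i]), expected) > 0.01:
            borderline[i] = True

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "latent_class": classes,
            "latent_window": windows,
            "latent_mean_score": latent_mean,
            "latent_essential": np.isin(classes, list(ESSENTIAL_CLASSES)),
            "hom_rate": hom_rate,
            "n_total": totals,
            "is_disease": is_disease,
            "is_true_candidate": is_candidate,
            "is_borderline": borderline,
            "orthology_ambiguous": ambiguous,
        }
    )
    for res, v in resources.items():
        truth[f"is_disease_{res}"] = v

    return DatasetBundle(
        config=config, truth=truth, crosses=crosses, embryo=embryo, scores=scores,
        orthology=orthology, constraints=constraints, disease=disease,
        onsets=onsets, systems=systems, evidence=evidence,
        recomb_intervals=recomb_intervals, gene_positions=gene_positions,
        edges=edges, complexes=complexes, paralogues=paralogues,
        expression=expression, families=families, pathways=pathways,
    )


def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> Path:
    """Write one TSV per table plus a JSON manifest with the config,
    seed and SHA-256 checksum of every file. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, df in bundle.tables().items():
        path = outdir / f"{name}.tsv"
        index = name in ("scores", "expression")
        df.to_csv(path, sep="\t", index=index)
        checksums[f"{name}.tsv"] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "seed": bundle.config.seed,
        "checksums": checksums,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
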