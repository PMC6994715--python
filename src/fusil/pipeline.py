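"""End-to-end orchestration of the FUSIL analysis.

A single config drives the whole cascade: (optionally) simulate the
input bundle, call mouse viability, select one-to-one orthologues,
summarise and threshold cell essentiality, assign FUSIL bins, run the
disease-gene enrichment, compute gene features, and run the candidate
prioritisation funnel. Every stage output is a pure function of the
stage inputs and the config; with a fixed seed the report reproduces
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .binning import FUSIL_BINS, FusilAssignment, assign_fusil, summarize_bins
from .enrichment import bin_disease_enrichment, enrichment_table
from .essentiality import (
    DEFAULT_THRESHOLD,
    classify_essential,
    gene_mean_scores,
    select_threshold_f1,
)
from .features import (
    average_recombination_per_gene,
    drop_correlated_columns,
    network_node_stats,
    pairwise_bin_tests,
    paralogue_free_rate,
)
from .orthology import select_one_to_one_table
from .prioritization import (
    HI_THRESHOLD,
    LOEUF_THRESHOLD,
    OE_MISSENSE_THRESHOLD,
    PLI_THRESHOLD,
    consortium_overlap,
    filter_dl_candidates,
    final_candidates,
)
from .synthetic_data import DatasetBundle, SyntheticConfig, generate_dataset
from .viability import call_viability_table

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulate: SyntheticConfig | None = None
    input_dir: str | None = None
    alpha: float = 0.05
    essentiality_threshold: float | str = DEFAULT_THRESHOLD  # or "fit"
    completeness_threshold: float = 0.5
    hi_threshold: float = HI_THRESHOLD
    loeuf_threshold: float = LOEUF_THRESHOLD
    pli_threshold: float = PLI_THRESHOLD
    oe_missense_threshold: float = OE_MISSENSE_THRESHOLD
    paralogue_identity_cutoff: float = 30.0
    min_edge_score: float = 0.7
    rho_max: float = 0.8
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate / input_dir must be set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.completeness_threshold <= 1:
            raise ValueError("completeness_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        config = cls(
            simulate=SyntheticConfig(**sim) if sim is not None else None, **raw
        )
        if config.simulate is not None:
            config.simulate.seed = int(raw.get("seed", config.simulate.seed))
        return config


@dataclass
class PipelineReport:
    assignments: pd.DataFrame
    table1: pd.DataFrame
    enrichment: pd.DataFrame
    features: pd.DataFrame
    funnel_counts: dict[str, int]
    venn: dict[str, int]
    final_genes: list[str]
    selected_threshold: float
    stage_counts: dict[str, int]
    confusion: pd.DataFrame | None = None
    recovery_rate: float | None = None
    outdir: str | None = None


def _load_bundle(config: PipelineConfig) -> DatasetBundle:
    if config.simulate is not None:
        return generate_dataset(config.simulate)
    d = Path(config.input_dir)
    tables = {
        name: fio.read_table(d / f"{name}.tsv", name)
        for name in (
            "crosses", "embryo", "orthology", "constraints", "disease",
            "onsets", "systems", "evidence", "recomb_intervals",
            "gene_positions", "edges", "complexes", "paralogues",
            "families", "pathways",
        )
    }
    truth_path = d / "truth.tsv"
    truth = fio.read_table(truth_path, "truth") if truth_path.exists() else pd.DataFrame()
    return DatasetBundle(
        config=SyntheticConfig(),  # placeholder; inputs came from disk
        truth=truth,
        scores=fio.read_matrix(d / "scores.tsv"),
        expression=fio.read_matrix(d / "expression.tsv"),
        **tables,
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    bundle = _load_bundle(config)
    stage_counts: dict[str, int] = {}

    # --- stage 1: mouse viability ---------------------------------------
    calls = call_viability_table(bundle.crosses, alpha=config.alpha)
    stage_counts["genes_with_viability_data"] = len(calls)
    substantive = calls[calls["call"].isin(["lethal", "subviable", "viable"])]
    stage_counts["substantive_viability_calls"] = len(substantive)
    logger.info("viability: %d/%d genes with substantive calls",
                len(substantive), len(calls))

    # --- stage 2: orthologue selection -----------------------------------
    accepted = select_one_to_one_table(bundle.orthology)
    accepted_human = set(accepted["human_id"].astype(str))
    stage_counts["one_to_one_orthologues"] = len(accepted_human)
    genes = substantive[substantive["gene_id"].isin(accepted_human)]
    stage_counts["genes_after_orthology"] = len(genes)

    # --- stage 3: cell essentiality ---------------------------------------
    profiles = gene_mean_scores(bundle.scores)
    means = {p.gene_id: p.mean_score for p in profiles}
    if config.essentiality_threshold == "fit":
        if bundle.truth.empty or "latent_essential" not in bundle.truth.columns:
            raise ValueError(
                "essentiality_threshold='fit' needs a reference labelling "
                "(truth table with latent_essential)"
            )
        reference = {
            str(g): ("essential" if e else "non_essential")
            for g, e in zip(bundle.truth["gene_id"], bundle.truth["latent_essential"])
        }
        search = select_threshold_f1(means, reference)
        threshold = search.selected
        logger.info("fitted essentiality threshold: %.3f", threshold)
    else:
        threshold = float(config.essentiality_threshold)
    stage_counts["genes_with_scores"] = len(means)

    # --- stage 4: FUSIL binning -------------------------------------------
    line_info = bundle.crosses.drop_duplicates("gene_id").set_index("gene_id")
    assignments: list[FusilAssignment] = []
    for row in genes.itertuples(index=False):
        g = str(row.gene_id)
        if g not in means:
            continue
        info = line_info.loc[g]
        assignments.append(
            assign_fusil(
                viability=row.call,
                essentiality=classify_essential(means[g], threshold),
                n_significant_phenotypes=int(info["n_significant_phenotypes"]),
                procedures_done=int(info["procedures_done"]),
                procedures_total=int(info["procedures_total"]),
                gene_id=g,
                completeness_threshold=config.completeness_threshold,
            )
        )
    assign_df = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "bin": [a.bin for a in assignments],
            "viability": [a.viability for a in assignments],
            "essentiality": [a.essentiality for a in assignments],
        }
    )
    stage_counts["genes_binned"] = len(assign_df)
    for b in FUSIL_BINS:
        stage_counts[f"bin_{b}"] = int((assign_df["bin"] == b).sum())
    table1 = summarize_bins(assignments)

    # --- stage 5: disease-gene enrichment ----------------------------------
    disease_sets = {
        col.removeprefix("in_"): set(
            bundle.disease.loc[bundle.disease[col].astype(bool), "gene_id"].astype(str)
        )
        for col in bundle.disease.columns
        if col.startswith("in_")
    }
    enrich = enrichment_table(bin_disease_enrichment(assign_df, disease_sets))

    # --- stage 6: gene features --------------------------------------------
    recomb = average_recombination_per_gene(
        bundle.recomb_intervals, bundle.gene_positions
    )
    net = network_node_stats(bundle.edges, min_score=config.min_edge_score).set_index(
        "gene_id"
    )
    retained = drop_correlated_columns(bundle.expression, rho_max=config.rho_max)
    expr_median = bundle.expression[retained].median(axis=1)
    features = pd.DataFrame(index=assign_df.set_index("gene_id").index)
    features["recomb_rate"] = recomb.reindex(features.index)
    features["degree"] = net["degree"].reindex(features.index).fillna(0).astype(int)
    features["topo_coeff"] = net["topo_coeff"].reindex(features.index).fillna(0.0)
    features["expression_median"] = expr_median.reindex(features.index)
    features["in_complex"] = features.index.isin(set(bundle.complexes["gene_id"]))
    features = features.reset_index()
    bins_map = dict(zip(assign_df["gene_id"], assign_df["bin"]))
    paralogue_free = paralogue_free_rate(
        bins_map, bundle.paralogues, cutoff=config.paralogue_identity_cutoff
    )
    recomb_tests = pairwise_bin_tests(
        dict(zip(features["gene_id"], features["recomb_rate"])), bins_map
    )

    # --- stage 7: prioritisation funnel --------------------------------------
    funnel = filter_dl_candidates(
        assign_df, disease_sets, bundle.constraints,
        hi_threshold=config.hi_threshold,
        loeuf_threshold=config.loeuf_threshold,
        pli_threshold=config.pli_threshold,
    )
    ev = bundle.evidence[bundle.evidence["gene_id"].isin(funnel.prioritised)]
    ev_matrix, venn = consortium_overlap(funnel.prioritised, ev)
    finals = final_candidates(ev, oe_missense_threshold=config.oe_missense_threshold)
    funnel_counts = funnel.counts() | {"with_any_evidence": venn["any"],
                                       "final": len(finals)}
    logger.info("funnel: %s", funnel_counts)

    # --- truth-vs-called confusion (simulated runs) ---------------------------
    confusion = None
    recovery = None
    if not bundle.truth.empty and "latent_class" in bundle.truth.columns:
        merged = assign_df.merge(bundle.truth, on="gene_id")
        confusion = pd.crosstab(merged["latent_class"], merged["bin"])
        scored = merged[
            merged["latent_class"].isin(FUSIL_BINS)
            & ~merged["is_borderline"].astype(bool)
        ]
        if len(scored):
            recovery = float((scored["bin"] == scored["latent_class"]).mean())
            stage_counts["non_borderline_scored"] = len(scored)
            logger.info("label recovery on non-borderline genes: %.4f", recovery)

    report = PipelineReport(
        assignments=assign_df, table1=table1, enrichment=enrich, features=features,
        funnel_counts=funnel_counts, venn=venn, final_genes=finals,
        selected_threshold=threshold, stage_counts=stage_counts,
        confusion=confusion, recovery_rate=recovery, outdir=config.outdir,
    )
    if config.outdir:
        _write_report(report, config, paralogue_free, recomb_tests, ev_matrix)
    return report


def _write_report(
    report: PipelineReport,
    config: PipelineConfig,
    paralogue_free: dict[str, float],
    recomb_tests: pd.DataFrame,
    ev_matrix: pd.DataFrame,
) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.assignments.to_csv(out / "fusil_assignments.tsv", sep="\t", index=False)
    report.table1.to_csv(out / "bin_summary.tsv", sep="\t", index=False)
    report.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report.features.to_csv(out / "features.tsv", sep="\t", index=False)
    recomb_tests.to_csv(out / "recomb_pairwise_tests.tsv", sep="\t")
    ev_matrix.to_csv(out / "consortium_evidence.tsv", sep="\t")
    pd.DataFrame(
        sorted(paralogue_free.items()), columns=["bin", "pct_paralogue_free"]
    ).to_csv(out / "paralogue_free.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": report.final_genes}).to_csv(
        out / "final_candidates.tsv", sep="\t", index=False
    )
    if report.confusion is not None:
        report.confusion.to_csv(out / "truth_confusion.tsv", sep="\t")
    summary = {
        "selected_threshold": report.selected_threshold,
        "stage_counts": report.stage_counts,
        "funnel_counts": report.funnel_counts,
        "venn": report.venn,
        "recovery_rate": report.recovery_rate,
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
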