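"""Candidate funnel: constraint filter, consortium overlap, final set."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fusil.prioritization import (
    consortium_overlap,
    filter_dl_candidates,
    final_candidates,
    shared_annotation_rates,
)


def make_constraints(rows):
    return pd.DataFrame(
        [{"gene_id": g, "hi_percentile": hi, "loeuf": lo, "pli": pli}
         for g, hi, lo, pli in rows]
    )


def test_constraint_filter_rules():
    assignments = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3", "g4", "g5"],
         "bin": ["DL", "DL", "DL", "CL", "DL"]}
    )
    constraints = make_constraints(
        [
            ("g1", 50.0, 0.5, 0.95),  # passes via pLI
            ("g2", 50.0, 0.5, 0.5),   # all clauses fail
            ("g3", 50.0, 0.5, 1.0),   # disease gene -> dropped earlier
            ("g4", 5.0, 0.1, 1.0),    # wrong bin
            ("g5", np.nan, np.nan, np.nan),  # all missing -> cannot pass
        ]
    )
    funnel = filter_dl_candidates(
        assignments, {"omim": {"g3"}}, constraints
    )
    assert funnel.dl_genes == {"g1", "g2", "g3", "g5"}
    assert funnel.non_disease == {"g1", "g2", "g5"}
    assert funnel.prioritised == {"g1"}


def test_missing_score_fails_its_clause_only():
    assignments = pd.DataFrame({"gene_id": ["g1"], "bin": ["DL"]})
    constraints = make_constraints([("g1", 5.0, np.nan, np.nan)])
    funnel = filter_dl_candidates(assignments, {}, constraints)
    assert funnel.prioritised == {"g1"}  # HI clause alone suffices


def test_funnel_monotone(small_bundle):
    from fusil.pipeline import PipelineConfig, run_pipeline
    from fusil.synthetic_data import SyntheticConfig

    report = run_pipeline(
        PipelineConfig(simulate=SyntheticConfig(n_genes=800, n_cell_lines=30, seed=11))
    )
    c = report.funnel_counts
    assert c["dl"] >= c["non_disease"] >= c["prioritised"] >= c["with_any_evidence"] >= c["final"]


def test_venn_regions_match_set_algebra(rng):
    genes = [f"g{i}" for i in range(60)]
    ev = pd.DataFrame(
        {
            "gene_id": genes,
            "in_100kgp": rng.random(60) < 0.4,
            "in_ddd": rng.random(60) < 0.4,
            "in_cmg": rng.random(60) < 0.4,
        }
    )
    matrix, venn = consortium_overlap(genes, ev)
    sets = {
        "100kgp": set(ev.loc[ev["in_100kgp"], "gene_id"]),
        "ddd": set(ev.loc[ev["in_ddd"], "gene_id"]),
        "cmg": set(ev.loc[ev["in_cmg"], "gene_id"]),
    }
    # exclusive regions by direct set algebra
    for r in range(1, 4):
        for combo in itertools.combinations(["100kgp", "ddd", "cmg"], r):
            inside = set(genes)
            for s in combo:
                inside &= sets[s]
            for s in sets:
                if s not in combo:
                    inside -= sets[s]
            assert venn["&".join(combo)] == len(inside)
    assert venn["any"] == len(sets["100kgp"] | sets["ddd"] | sets["cmg"])
    # inclusion-exclusion: exclusive regions partition the union
    assert sum(v for k, v in venn.items() if k != "any") == venn["any"]


def test_disjoint_singleton_sets():
    ev = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "in_100kgp": [True, True, True, False, False, False],
            "in_ddd": [False, False, False, True, True, False],
            "in_cmg": [False, False, False, False, False, True],
        }
    )
    _, venn = consortium_overlap(ev["gene_id"], ev)
    assert venn["any"] == 6
    assert venn["100kgp&ddd"] == venn["100kgp&cmg"] == venn["ddd&cmg"] == 0
    assert venn["100kgp&ddd&cmg"] == 0


def evidence_row(g, kgp, ddd, cmg, gnomad, oe):
    return {"gene_id": g, "in_100kgp": kgp, "in_ddd": ddd, "in_cmg": cmg,
            "variant_in_gnomad": gnomad, "oe_missense": oe}


@pytest.mark.parametrize(
    "kgp,ddd,cmg,gnomad,oe,kept",
    [
        (True, True, False, False, 0.53, True),   # 100KGP + DDD, constrained
        (True, False, True, False, 0.53, True),   # 100KGP + CMG
        (False, True, True, False, 0.53, False),  # no 100KGP evidence
        (True, True, False, True, 0.53, False),   # variant seen in gnomAD
        (True, True, False, False, 0.9, False),   # tolerant to missense
        (True, False, False, False, 0.5, False),  # 100KGP alone insufficient
    ],
)
def test_final_criteria(kgp, ddd, cmg, gnomad, oe, kept):
    ev = pd.DataFrame([evidence_row("g", kgp, ddd, cmg, gnomad, oe)])
    assert (final_candidates(ev) == ["g"]) is kept


def test_shared_annotation_rates():
    edges = pd.DataFrame(
        [{"gene_a": "g1", "gene_b": "r1", "score": 0.9},
         {"gene_a": "g2", "gene_b": "x", "score": 0.9},
         {"gene_a": "g3", "gene_b": "r2", "score": 0.5}]  # low confidence
    )
    fam = {"g1": {"F1"}, "g2": {"F2"}, "r1": {"F1"}, "r2": {"F9"}}
    path = {"g1": {"P1"}, "g2": {"P1"}, "g3": {"P2"}, "r1": {"P1"}, "r2": {"P1"}}
    pct_fam, pct_path, pct_int = shared_annotation_rates(
        ["g1", "g2", "g3"], ["r1", "r2"], fam, path, edges
    )
    assert pct_fam == pytest.approx(100 / 3)
    assert pct_path == pytest.approx(200 / 3)
    assert pct_int == pytest.approx(100 / 3)


def test_shared_annotations_exclude_self():
    edges = pd.DataFrame([{"gene_a": "a", "gene_b": "b", "score": 0.9}])
    fam = {"g1": {"F1"}}  # only matches itself
    pct_fam, pct_path, pct_int = shared_annotation_rates(
        ["g1"], ["g1"], fam, {}, edges
    )
    assert (pct_fam, pct_path, pct_int) == (0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        shared_annotation_rates([], ["r"], {}, {}, edges)


def test_planted_candidate_recall():
    """Planted true candidates survive to the constraint-filter stage."""
    from fusil.pipeline import PipelineConfig, run_pipeline
    from fusil.synthetic_data import SyntheticConfig, generate_dataset

    config = SyntheticConfig(n_genes=2000, n_cell_lines=40, seed=3)
    bundle = generate_dataset(config)
    report = run_pipeline(PipelineConfig(simulate=config))
    planted = set(bundle.truth.loc[bundle.truth["is_true_candidate"], "gene_id"])
    assert planted
    funnel = filter_dl_candidates(
        report.assignments, bundle.disease_sets(), bundle.constraints
    )
    recall = len(planted & funnel.prioritised) / len(planted)
    assert recall >= 0.95
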