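"""Gene features: recombination mapping, decorrelation, network stats,
paralogues, onset, systems, pairwise bin comparisons."""

import numpy as np
import pandas as pd
import pytest

from fusil.features import (
    average_recombination_per_gene,
    count_affected_systems,
    drop_correlated_columns,
    earliest_onset,
    network_node_stats,
    pairwise_bin_tests,
    paralogue_free_rate,
)


def iv(chrom, start, end, rate):
    return {"chrom": chrom, "start": start, "end": end, "rate": rate}


def gene(gid, chrom, start, end):
    return {"gene_id": gid, "chrom": chrom, "start": start, "end": end}


def test_interval_inside_gene_and_mean():
    intervals = pd.DataFrame([iv("1", 100, 200, 1.0), iv("1", 300, 400, 3.0)])
    genes = pd.DataFrame([gene("A", "1", 0, 1000)])
    rates = average_recombination_per_gene(intervals, genes)
    assert rates["A"] == pytest.approx(2.0)


def test_tie_goes_upstream_gene():
    # interval equidistant from two genes -> lower-coordinate gene wins
    intervals = pd.DataFrame([iv("1", 450, 550, 2.5)])
    genes = pd.DataFrame([gene("up", "1", 0, 400), gene("down", "1", 600, 1000)])
    rates = average_recombination_per_gene(intervals, genes)
    assert list(rates.index) == ["up"]


def test_chrom_without_genes_dropped():
    intervals = pd.DataFrame([iv("2", 0, 10, 1.0), iv("1", 0, 10, 5.0)])
    genes = pd.DataFrame([gene("A", "1", 0, 100)])
    rates = average_recombination_per_gene(intervals, genes)
    assert rates.to_dict() == {"A": 5.0}


def brute_force_assignment(intervals, genes):
    sums, counts = {}, {}
    for _, ivr in intervals.iterrows():
        best, best_d = None, None
        for _, g in genes.iterrows():
            if g["chrom"] != ivr["chrom"]:
                continue
            d = max(g["start"] - ivr["end"], ivr["start"] - g["end"], 0)
            if best_d is None or d < best_d or (
                d == best_d and (g["start"], g["gene_id"]) < best[1:]
            ):
                best, best_d = (g["gene_id"], g["start"], g["gene_id"]), d
        if best is None:
            continue
        gid = best[0]
        sums[gid] = sums.get(gid, 0.0) + ivr["rate"]
        counts[gid] = counts.get(gid, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def test_assignment_matches_all_pairs_oracle(rng):
    for _ in range(30):
        n_g, n_i = rng.integers(1, 6), rng.integers(1, 10)
        genes = pd.DataFrame(
            [
                gene(f"g{j}", str(rng.integers(1, 3)),
                     int(s := rng.integers(0, 5000)), int(s + rng.integers(50, 500)))
                for j in range(n_g)
            ]
        )
        intervals = pd.DataFrame(
            [
                iv(str(rng.integers(1, 3)), int(s := rng.integers(0, 5000)),
                   int(s + rng.integers(10, 300)), float(rng.uniform(0, 4)))
                for _ in range(n_i)
            ]
        )
        got = average_recombination_per_gene(intervals, genes).to_dict()
        want = brute_force_assignment(intervals, genes)
        assert got == pytest.approx(want)


def test_every_interval_assigned_or_dropped(small_bundle):
    rates = average_recombination_per_gene(
        small_bundle.recomb_intervals, small_bundle.gene_positions
    )
    # synthetic intervals sit inside gene bodies: all genes get their own
    assert len(rates) == len(small_bundle.gene_positions)


def test_identical_column_dropped(rng):
    x = rng.normal(size=300)
    m = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=300)})
    assert drop_correlated_columns(m) == ["a", "c"]


def test_independent_columns_retained(rng):
    m = pd.DataFrame(rng.normal(size=(500, 6)), columns=list("abcdef"))
    assert drop_correlated_columns(m) == list("abcdef")


def test_rho_max_one_retains_all(rng):
    x = rng.normal(size=100)
    m = pd.DataFrame({"a": x, "b": x})
    assert drop_correlated_columns(m, rho_max=1.0) == ["a", "b"]


def test_constant_column_retained_with_warning(rng, caplog):
    m = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
    assert drop_correlated_columns(m) == ["a", "b"]


def edges_df(pairs, score=0.9):
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "score": score} for a, b in pairs]
    )


def test_triangle_degree_and_topological_coefficient():
    stats = network_node_stats(edges_df([("a", "b"), ("b", "c"), ("a", "c")]))
    assert (stats["degree"] == 2).all()
    assert stats["topo_coeff"].to_numpy() == pytest.approx([1.0, 1.0, 1.0])


def test_star_graph_stats():
    stats = network_node_stats(
        edges_df([("hub", f"leaf{i}") for i in range(5)])
    ).set_index("gene_id")
    assert stats.loc["hub", "degree"] == 5
    # leaves share the hub pairwise but have degree 1 -> coefficient 0
    assert (stats.loc[[f"leaf{i}" for i in range(5)], "topo_coeff"] == 0).all()
    assert stats.loc["hub", "topo_coeff"] == 0.0  # nobody shares hub's leaves


def test_low_score_edges_and_self_loops_excluded():
    df = pd.DataFrame(
        [
            {"gene_a": "a", "gene_b": "b", "score": 0.9},
            {"gene_a": "a", "gene_b": "c", "score": 0.5},  # below threshold
            {"gene_a": "a", "gene_b": "a", "score": 0.95},  # self-loop
        ]
    )
    stats = network_node_stats(df).set_index("gene_id")
    assert "c" not in stats.index
    assert stats.loc["a", "degree"] == 1


def test_topo_coeff_in_unit_interval_and_degree_sum(small_bundle):
    stats = network_node_stats(small_bundle.edges)
    assert ((stats["topo_coeff"] >= 0) & (stats["topo_coeff"] <= 1)).all()
    kept = small_bundle.edges[small_bundle.edges["score"] > 0.7]
    kept = kept[kept["gene_a"] != kept["gene_b"]]
    n_unique = len({tuple(sorted(p)) for p in zip(kept["gene_a"], kept["gene_b"])})
    assert stats["degree"].sum() == 2 * n_unique


def test_paralogue_free_rates():
    bins = {"g1": "CL", "g2": "CL", "g3": "DL"}
    pairs = pd.DataFrame(
        [
            {"gene_id": "g1", "partner": "p1", "identity": 29.0},  # below cutoff
            {"gene_id": "g2", "partner": "p2", "identity": 90.0},
            {"gene_id": "g3", "partner": "p3", "identity": 45.0},
        ]
    )
    rates = paralogue_free_rate(bins, pairs, cutoff=30)
    assert rates == {"CL": 50.0, "DL": 0.0}
    # cutoff 0: any partner row disqualifies
    assert paralogue_free_rate(bins, pairs, cutoff=0)["CL"] == 0.0
    assert paralogue_free_rate({"g9": "VN"}, pairs)["VN"] == 100.0


def test_earliest_onset_rules():
    out = earliest_onset(
        {"g1": {"adult", "neonatal"}, "g2": {"antenatal"}, "g3": set(),
         "g4": {"elderly", "antenatal", "childhood"}}
    )
    assert out == {"g1": "neonatal", "g2": "antenatal", "g4": "antenatal"}
    with pytest.raises(ValueError):
        earliest_onset({"g": {"sometime"}})


def test_affected_system_counts():
    assert count_affected_systems(
        {"g1": ["a", "a", "b"], "g2": [], "g3": list("abcde")}
    ) == {"g1": 2, "g2": 0, "g3": 5}


def test_pairwise_tests_detect_separated_bins(rng):
    feature, bins = {}, {}
    for i in range(200):
        feature[f"a{i}"] = float(rng.normal(0, 1))
        bins[f"a{i}"] = "CL"
        feature[f"b{i}"] = float(rng.normal(1, 1))
        bins[f"b{i}"] = "VN"
    mat = pairwise_bin_tests(feature, bins)
    assert mat.loc["CL", "VN"] < 1e-3
    assert mat.loc["CL", "VN"] == mat.loc["VN", "CL"]  # symmetric
    assert np.isnan(mat.loc["CL", "CL"])


def test_pairwise_tests_null_calibration(rng):
    """Identical distributions are rejected at roughly the nominal rate."""
    rejections = 0
    n_reps = 60
    for _ in range(n_reps):
        feature = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=400))}
        bins = {f"g{i}": ("CL" if i < 200 else "DL") for i in range(400)}
        mat = pairwise_bin_tests(feature, bins)
        rejections += mat.loc["CL", "DL"] < 0.05
    # Binomial(60, 0.05): P(X > 9) < 1e-4
    assert rejections <= 9


def test_small_bins_skipped(caplog):
    feature = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 1.0}
    bins = {"a1": "CL", "a2": "CL", "a3": "CL", "b1": "DL"}
    mat = pairwise_bin_tests(feature, bins)
    assert np.isnan(mat.loc["CL", "DL"])


def test_synthetic_recombination_ordering(small_bundle):
    """Configured class trend (CL lowest recombination) is reproduced."""
    rates = average_recombination_per_gene(
        small_bundle.recomb_intervals, small_bundle.gene_positions
    )
    truth = small_bundle.truth.set_index("gene_id")
    medians = rates.groupby(truth["latent_class"]).median()
    assert medians["CL"] < medians["DL"] < medians["VP"] < medians["VN"]
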