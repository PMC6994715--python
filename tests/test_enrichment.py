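"""Odds ratios, Fisher exact test, BH correction, set enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fusil.enrichment import (
    ContingencyTable,
    bh_adjust,
    bin_disease_enrichment,
    fisher_two_sided,
    odds_ratio_wald,
    term_overrepresentation,
)


def test_symmetric_table_or_one():
    r = odds_ratio_wald(ContingencyTable(10, 10, 10, 10))
    assert r.or_hat == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high


def test_or_closed_form_and_ci():
    r = odds_ratio_wald(ContingencyTable(20, 10, 10, 20))
    assert r.or_hat == pytest.approx(4.0)
    se = math.sqrt(0.3)
    assert r.ci_low == pytest.approx(math.exp(math.log(4) - 1.959964 * se), rel=1e-4)
    assert r.ci_high == pytest.approx(math.exp(math.log(4) + 1.959964 * se), rel=1e-4)
    assert (r.ci_low, r.ci_high) == pytest.approx((1.366, 11.71), abs=0.01)


def test_zero_cell_degenerate():
    r = odds_ratio_wald(ContingencyTable(5, 0, 3, 7))
    assert math.isinf(r.or_hat) and r.degenerate
    r0 = odds_ratio_wald(ContingencyTable(0, 5, 3, 7))
    assert r0.or_hat == 0.0 and r0.degenerate


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


def fisher_oracle(a, b, c, d):
    """Exact enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        # hypergeometric via factorials, exact rational arithmetic
        return Fraction(
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(k) * math.factorial(r1 - k)
            * math.factorial(c1 - k) * math.factorial(r2 - c1 + k)
            * math.factorial(n),
        )

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(k)
        if p <= p_obs:
            total += p
    return float(total)


def test_fisher_worked_example():
    # margins (4,4)x(4,4): 34/70
    assert fisher_two_sided(ContingencyTable(3, 1, 1, 3)) == pytest.approx(
        34 / 70, abs=1e-12
    )


def test_fisher_degenerate_margin():
    assert fisher_two_sided(ContingencyTable(0, 0, 3, 7)) == 1.0
    assert fisher_two_sided(ContingencyTable(0, 4, 0, 6)) == 1.0


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if a + b + c + d == 0:
            continue
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )


def test_fisher_agrees_with_scipy(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
        ours = fisher_two_sided(ContingencyTable(a, b, c, d))
        scipy_p = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(scipy_p, abs=1e-9)


def test_fisher_invariance_under_table_symmetries(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
        if a + b + c + d == 0:
            continue
        p = fisher_two_sided(ContingencyTable(a, b, c, d))
        assert fisher_two_sided(ContingencyTable(a, c, b, d)) == pytest.approx(p, abs=1e-12)
        assert fisher_two_sided(ContingencyTable(c, d, a, b)) == pytest.approx(p, abs=1e-12)
        assert fisher_two_sided(ContingencyTable(b, a, d, c)) == pytest.approx(p, abs=1e-12)


def bh_oracle(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_worked_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_oracle_and_fixed_point(pvals):
    adj = bh_adjust(pvals)
    assert adj == pytest.approx(bh_oracle(pvals), abs=1e-12)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    # the adjusted vector is a fixed point of the step-up monotone
    # envelope: sorted by raw p it is already non-decreasing (note the
    # full adjustment, which rescales by m/rank, is NOT idempotent:
    # [0.1, 0.9] -> [0.2, 0.9] -> [0.4, 0.9])
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.integers(0, 19))
def test_bh_monotone_in_inputs(pvals, idx):
    idx = idx % len(pvals)
    adj = bh_adjust(pvals)
    bumped = list(pvals)
    bumped[idx] = min(1.0, bumped[idx] + 0.1)
    adj2 = bh_adjust(bumped)
    assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(adj, adj2))


def test_bin_enrichment_recovers_planted_or(rng):
    """Flags generated at odds ratio 2.6 in DL yield a DL estimate near 2.6."""
    import pandas as pd

    from fusil.synthetic_data import generate_disease_flags

    genes = [f"g{i}" for i in range(5000)]
    bins = dict(zip(genes, rng.choice(["CL", "DL", "SV", "VP", "VN"], size=5000)))
    flags = generate_disease_flags(bins, 0.20, {"DL": 2.6}, rng)
    assignments = pd.DataFrame({"gene_id": genes, "bin": [bins[g] for g in genes]})
    results = bin_disease_enrichment(
        assignments, {"sim": {g for g, f in flags.items() if f}}
    )
    dl = next(r for r in results if r.group == "DL")
    assert dl.or_hat == pytest.approx(2.6, abs=0.5)
    assert dl.p_adjusted < 0.001
    assert dl.p_adjusted >= dl.p_fisher


def test_bin_enrichment_excludes_other_resource_genes():
    import pandas as pd

    assignments = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(8)],
         "bin": ["DL"] * 4 + ["VP"] * 4}
    )
    sets = {"r1": {"g0", "g4"}, "r2": {"g1", "g5"}}
    results = bin_disease_enrichment(assignments, sets)
    r1_dl = next(r for r in results if r.resource == "r1" and r.group == "DL")
    # universe for r1: 2 disease genes + 4 genes in no resource
    assert (r1_dl.table.a, r1_dl.table.b) == (1, 2)
    assert (r1_dl.table.c, r1_dl.table.d) == (1, 2)


def test_term_overrepresentation_edges():
    universe = {f"g{i}" for i in range(20)}
    study = {f"g{i}" for i in range(5)}
    nested = term_overrepresentation(study, {"t": set(study)}, universe)
    assert nested[0].p_fisher == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
    all_p = term_overrepresentation(
        universe, {"term_a": {"g0", "g1"}, "term_b": {"g3"}}, universe
    )
    assert all(r.p_fisher == pytest.approx(1.0) for r in all_p)
    with pytest.raises(ValueError):
        term_overrepresentation({"zz"}, {"t": {"zz"}}, universe)


def test_term_overrepresentation_matches_tail_enumeration(rng):
    universe = [f"g{i}" for i in range(15)]
    for _ in range(50):
        study = set(rng.choice(universe, size=6, replace=False))
        term = set(rng.choice(universe, size=int(rng.integers(1, 10)), replace=False))
        res = term_overrepresentation(study, {"t": term}, set(universe))[0]
        M, N, K = 15, 6, len(term)
        k_obs = len(term & study)
        tail = sum(
            math.comb(K, k) * math.comb(M - K, N - k) / math.comb(M, N)
            for k in range(k_obs, min(K, N) + 1)
        )
        assert res.p_fisher == pytest.approx(tail, rel=1e-9)
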