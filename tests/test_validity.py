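"""Cohort assignment, rank tests vs enumeration oracles, report assembly."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from fluorosim.errors import (
    BothZeroError,
    EmptyCohortError,
    EmptyGroupError,
    InsufficientGroupsError,
    NegativeCountError,
    OutOfScaleError,
)
from fluorosim.fixtures import CohortSpec, make_cohort
from fluorosim.validity import (
    adjust_p,
    assign_cohort,
    cohort_medians,
    kruskal_wallis,
    likert_agreement,
    mann_whitney_u,
    percent_difference,
    validity_report,
)

# -- brute-force oracles (independent of the implementation) ---------------


def mwu_oracle(a, b):
    """Exact two-sided Mann-Whitney p by direct pairwise counting over all
    relabelings of the pooled sample."""
    pooled = list(a) + list(b)
    n_a, n_b = len(a), len(b)
    mu = n_a * n_b / 2.0

    def u_of(sub_a, sub_b):
        u = 0.0
        for x in sub_a:
            for y in sub_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    dev = abs(u_of(a, b) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(sa, sb) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def kw_oracle(groups):
    """Exact Kruskal-Wallis permutation p using scipy's H on every
    relabeling of the pooled sample into the observed group sizes."""
    def h_of(gs):
        if len(set(v for g in gs for v in g)) == 1:
            return 0.0
        return stats.kruskal(*gs).statistic

    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = h_of(groups)
    hits = total = 0

    def rec(remaining, sizes_left, built):
        nonlocal hits, total
        if len(sizes_left) == 1:
            gs = built + [[pooled[i] for i in remaining]]
            total += 1
            if h_of(gs) >= h_obs - 1e-12:
                hits += 1
            return
        for chosen in combinations(remaining, sizes_left[0]):
            rest = tuple(i for i in remaining if i not in set(chosen))
            rec(rest, sizes_left[1:], built + [[pooled[i] for i in chosen]])

    rec(tuple(range(len(pooled))), sizes, [])
    return hits / total


# -- cohort assignment ------------------------------------------------------


@pytest.mark.parametrize("count, cohort", [
    (0, "novice"), (9, "novice"),
    (10, "intermediate"), (39, "intermediate"),
    (40, "expert"), (250, "expert"),
])
def test_cohort_boundaries(count, cohort):
    assert assign_cohort(count) == cohort


def test_negative_caseload_rejected():
    with pytest.raises(NegativeCountError):
        assign_cohort(-1)


def test_cohort_medians_even_and_singleton():
    spec = CohortSpec(n={"novice": 1, "intermediate": 4, "expert": 3},
                      dispersion=0.0, seed=0)
    records = make_cohort(spec)
    med = cohort_medians(records, "tad_mm")
    assert med["novice"] == pytest.approx(47.0)
    assert med["intermediate"] == pytest.approx(28.0)  # even n, all equal
    assert med["expert"] == pytest.approx(24.0)


def test_empty_cohort_raises():
    spec = CohortSpec(n={"novice": 2, "intermediate": 2, "expert": 2},
                      dispersion=0.0)
    records = [r for r in make_cohort(spec) if r.cohort != "expert"]
    with pytest.raises(EmptyCohortError):
        cohort_medians(records, "tad_mm")


# -- rank tests -------------------------------------------------------------


def test_kw_identical_groups_h_zero():
    r = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.raw_p == 1.0


def test_kw_hand_computed_h():
    # ranks 1..6 -> rank sums 3, 7, 11; H = 12/(6*7) * (9+49+121)/2 - 21
    r = kruskal_wallis([[1, 2], [3, 4], [5, 6]], exact=False)
    assert r.statistic == pytest.approx(12 / 42 * (9 + 49 + 121) / 2 - 21)
    assert r.statistic == pytest.approx(4.571428571428571)


def test_kw_matches_scipy_asymptotic(rng):
    for _ in range(20):
        groups = [rng.normal(size=rng.integers(3, 10)).tolist()
                  for _ in range(3)]
        ours = kruskal_wallis(groups, exact=False)
        ref = stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.raw_p == pytest.approx(ref.pvalue, rel=1e-12)


def test_kw_single_group_rejected():
    with pytest.raises(InsufficientGroupsError):
        kruskal_wallis([[1, 2, 3]])


def test_mwu_separated_groups_exact_p():
    # all of a below all of b: 2 of C(6,3)=20 labelings are as extreme
    r = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.raw_p == pytest.approx(0.1)


def test_mwu_singletons():
    r = mann_whitney_u([1], [2])
    assert r.raw_p == 1.0


def test_mwu_interleaved_exact_p_matches_oracle():
    a, b = [1, 3, 5], [2, 4, 6]
    r = mann_whitney_u(a, b)
    assert r.statistic == 3.0  # pairs with a > b
    assert r.raw_p == pytest.approx(mwu_oracle(a, b))


def test_mwu_empty_group_rejected():
    with pytest.raises(EmptyGroupError):
        mann_whitney_u([], [1, 2])


def test_mwu_exact_equals_oracle_all_configurations(rng):
    """Every (n_a, n_b) with pooled n <= 8, continuous and tied data."""
    for n in range(2, 9):
        for n_a in range(1, n):
            cont = rng.uniform(0, 1, size=n)
            tied = rng.integers(0, 3, size=n).astype(float)
            for vals in (cont, tied):
                a, b = vals[:n_a].tolist(), vals[n_a:].tolist()
                r = mann_whitney_u(a, b)
                assert r.raw_p == pytest.approx(mwu_oracle(a, b), abs=1e-12)


def test_kw_exact_equals_oracle_all_configurations(rng):
    """Every 3-group size composition with pooled n <= 8."""
    for n in range(3, 9):
        for n1 in range(1, n - 1):
            for n2 in range(1, n - n1):
                n3 = n - n1 - n2
                if n3 < 1:
                    continue
                vals = rng.integers(0, 4, size=n).astype(float)
                groups = [vals[:n1].tolist(), vals[n1:n1 + n2].tolist(),
                          vals[n1 + n2:].tolist()]
                r = kruskal_wallis(groups, exact=True)
                assert r.raw_p == pytest.approx(kw_oracle(groups), abs=1e-12)


def test_mwu_normal_approximation_matches_scipy(rng):
    a = rng.normal(size=15).tolist()
    b = rng.normal(0.8, size=18).tolist()
    ours = mann_whitney_u(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert ours.raw_p == pytest.approx(ref.pvalue, rel=1e-9)


# -- adjustment, percent difference, Likert ---------------------------------


@pytest.mark.parametrize("raw, expected", [(0.01, 0.03), (0.4, 1.0), (0.0, 0.0)])
def test_adjust_p_times_three_capped(raw, expected):
    assert adjust_p(raw) == pytest.approx(expected)


def test_adjust_p_bounds(rng):
    for p in rng.uniform(0, 1, 50):
        adj = adjust_p(float(p))
        assert p <= adj <= 1.0


@pytest.mark.parametrize("m1, m2, expected", [
    (47, 28, 40),     # published TAD novice vs intermediate cell
    (206, 190, 8),    # published time novice vs intermediate cell
    (190, 222, 14),
    (3.0, 3.0, 0),
    (0, 1, 100),
])
def test_percent_difference_examples(m1, m2, expected):
    assert percent_difference(m1, m2) == expected
    assert percent_difference(m2, m1) == expected  # symmetry


def test_percent_difference_both_zero():
    with pytest.raises(BothZeroError):
        percent_difference(0.0, 0.0)


@pytest.mark.parametrize("responses, expected", [
    ([7, 7, 7, 7, 7], (5, 1.0)),
    ([5, 6, 7, 4, 1], (3, 0.6)),
    ([4], (0, 0.0)),
])
def test_likert_agreement_threshold(responses, expected):
    assert likert_agreement(responses) == expected


def test_likert_out_of_scale():
    with pytest.raises(OutOfScaleError):
        likert_agreement([5, 8])


# -- full report ------------------------------------------------------------


def test_report_structure_and_degenerate_values():
    records = make_cohort(CohortSpec(
        n={"novice": 3, "intermediate": 3, "expert": 3},
        tad_median={"novice": 30.0, "intermediate": 30.0, "expert": 30.0},
        time_median={"novice": 100.0, "intermediate": 100.0, "expert": 100.0},
        radiographs_median={"novice": 10, "intermediate": 10, "expert": 10},
        retries_median={"novice": 1, "intermediate": 1, "expert": 1},
        dispersion=0.0, seed=3))
    rep = validity_report(records)
    assert set(rep["medians"]) == {"tad_mm", "cor_pct", "time_s",
                                   "n_radiographs", "n_retries"}
    for metric, row in rep["medians"].items():
        assert row["kw_h"] == pytest.approx(0.0, abs=1e-12)
    for metric, pairs in rep["pairwise"].items():
        assert set(pairs) == {"novice_vs_intermediate", "novice_vs_expert",
                              "intermediate_vs_expert"}
        for cell in pairs.values():
            assert cell["pct_diff"] == 0
            assert cell["adjusted_p"] == 1.0
    assert set(rep["likert"]) == {"q1", "q2", "q3", "q4"}


def test_report_discriminates_cohorts_at_scale():
    records = make_cohort(CohortSpec(
        n={"novice": 50, "intermediate": 50, "expert": 50},
        dispersion=0.3, seed=7))
    rep = validity_report(records)
    assert rep["medians"]["tad_mm"]["kw_p"] < 0.05
    assert rep["medians"]["cor_pct"]["kw_p"] < 0.05
    assert rep["pairwise"]["tad_mm"]["novice_vs_expert"]["adjusted_p"] < 0.05
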