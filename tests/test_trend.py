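"""Statistical core: median profiles, monotone rule, Kruskal-Wallis,
Bonferroni and the per-tissue screen, each checked against an
independent oracle."""

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agetrend import (
    GeneratorConfig,
    TrendConfig,
    bonferroni,
    build_age_profiles,
    classify_sequence,
    classify_trend,
    generate_expression,
    kruskal_wallis,
    screen_tissue,
)
from conftest import make_profile_dataset


# ------------------------------------------------------------- oracles

def kw_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from first principles: mid-ranks by
    explicit position averaging, then the rank-sum formula."""
    pooled = sorted(v for g in groups for v in g)
    positions = defaultdict(list)
    for i, v in enumerate(pooled, start=1):
        positions[v].append(i)
    rank_of = {v: sum(pos) / len(pos) for v, pos in positions.items()}
    n_total = len(pooled)
    s = sum(sum(rank_of[v] for v in g) ** 2 / len(g) for g in groups)
    h = 12.0 / (n_total * (n_total + 1)) * s - 3.0 * (n_total + 1)
    c = 1.0 - sum(len(p) ** 3 - len(p) for p in positions.values()) / (n_total**3 - n_total)
    return h / c if c > 0 else 0.0


def chi2_sf_oracle(x, df):
    """Chi-square survival function via the regularised upper incomplete
    gamma, evaluated symbolically (independent of scipy)."""
    import sympy

    return float(sympy.uppergamma(sympy.Rational(df, 2), sympy.Float(x) / 2)
                 / sympy.gamma(sympy.Rational(df, 2)))


def classify_oracle(seq, rule):
    diffs = [b - a for a, b in zip(seq, seq[1:])]
    if not diffs:
        return "none"
    if rule == "strict":
        if all(d > 0 for d in diffs):
            return "increasing"
        if all(d < 0 for d in diffs):
            return "decreasing"
        return "none"
    if all(d >= 0 for d in diffs) and any(d > 0 for d in diffs):
        return "increasing"
    if all(d <= 0 for d in diffs) and any(d < 0 for d in diffs):
        return "decreasing"
    return "none"


# -------------------------------------------------------- age profiles

def test_even_count_median_convention():
    ds = make_profile_dataset([[1, 2, 3, 4], [5], [6], [7], [8], [9]])
    (prof,), skipped = build_age_profiles(ds, "liver", ["G1"])
    assert not skipped
    assert prof.bin_medians[0] == 2.5
    assert prof.bin_counts.tolist() == [4, 1, 1, 1, 1, 1]


def test_absent_gene_reported_not_fatal():
    ds = make_profile_dataset([[1], [2], [3], [4], [5], [6]])
    profiles, skipped = build_age_profiles(ds, "liver", ["G1", "MISSING"])
    assert [p.gene for p in profiles] == ["G1"]
    assert skipped == ["MISSING"]
    with pytest.raises(KeyError):
        build_age_profiles(ds, "lung", ["G1"])
    with pytest.raises(ValueError):
        build_age_profiles(ds, "liver", ["MISSING"])


def test_profile_medians_match_sort_and_pick():
    rng = np.random.default_rng(5)
    bins = [list(rng.uniform(0, 50, size=rng.integers(1, 9))) for _ in range(6)]
    ds = make_profile_dataset(bins)
    (prof,), _ = build_age_profiles(ds, "liver", ["G1"])
    for vals, med in zip(bins, prof.bin_medians):
        srt = sorted(vals)
        k = len(srt)
        expect = srt[k // 2] if k % 2 else (srt[k // 2 - 1] + srt[k // 2]) / 2
        assert med == pytest.approx(expect)


def test_empty_bin_is_excluded_from_trend():
    ds = make_profile_dataset([[1, 1], [2, 2], [], [3, 3], [4, 4], [5, 5]])
    (prof,), _ = build_age_profiles(ds, "liver", ["G1"])
    assert np.isnan(prof.bin_medians[2])
    assert classify_trend(prof, TrendConfig(min_bin_count=2)) == "increasing"


# ------------------------------------------------------ monotone rule

@pytest.mark.parametrize("rule", ["weak", "strict"])
def test_classifier_matches_rule_on_all_sign_patterns(rule):
    """All 3^5 = 243 sign patterns of consecutive differences."""
    for pattern in itertools.product((-1, 0, 1), repeat=5):
        seq = list(itertools.accumulate((0,) + pattern))
        assert classify_sequence(seq, rule) == classify_oracle(seq, rule), pattern


def test_classifier_examples():
    assert classify_sequence([5, 5, 5, 5, 5, 5]) == "none"
    assert classify_sequence([1, 2, 2, 3, 4, 6], "weak") == "increasing"
    assert classify_sequence([1, 2, 2, 3, 4, 6], "strict") == "none"
    assert classify_sequence([6, 5, 5, 4, 3, 2], "weak") == "decreasing"
    assert classify_sequence([3.0]) == "none"  # fewer than two usable bins


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=6))
def test_classifier_reflection_symmetry(seq):
    swap = {"increasing": "decreasing", "decreasing": "increasing", "none": "none"}
    for rule in ("weak", "strict"):
        assert classify_sequence(seq[::-1], rule) == swap[classify_sequence(seq, rule)]


# ---------------------------------------------------- Kruskal-Wallis

def test_kw_textbook_example_and_exact_permutation_p():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert round(h, 3) == 3.857
    assert p == pytest.approx(chi2_sf_oracle(h, df=1), abs=1e-12)
    # exact permutation reference: of the C(6,3)=20 equal-sized labelings
    # only the two fully separated ones reach H >= 3.857
    values = [1, 2, 3, 4, 5, 6]
    hs = [kw_oracle([list(combo), [v for v in values if v not in combo]])
          for combo in itertools.combinations(values, 3)]
    assert sum(hh >= h - 1e-12 for hh in hs) / len(hs) == pytest.approx(2 / 20)


def test_kw_identical_groups_and_degenerate_input():
    h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert h == pytest.approx(0.0, abs=1e-12)
    assert kruskal_wallis([[7, 7], [7, 7, 7]]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], [2]])  # fewer than three observations


def test_kw_matches_oracle_on_all_small_partitions():
    """H equals the brute-force rank-sum oracle over every 2-group
    labeling of n <= 6 distinct values."""
    for n in range(3, 7):
        values = list(range(1, n + 1))
        for labels in itertools.product((0, 1), repeat=n):
            groups = [[v for v, g in zip(values, labels) if g == j] for j in (0, 1)]
            if any(not g for g in groups):
                continue
            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(kw_oracle(groups), abs=1e-12)


def test_kw_tie_correction_and_chi2_p_random_suite():
    rng = np.random.default_rng(17)
    for _ in range(200):
        k = int(rng.integers(2, 5))
        groups = [list(rng.integers(0, 5, size=rng.integers(2, 6))) for _ in range(k)]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            continue
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-12)
        assert p == pytest.approx(chi2_sf_oracle(h, df=k - 1), abs=1e-12)


def test_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    groups = [list(rng.uniform(1, 10, size=6)) for _ in range(3)]
    h0, _ = kruskal_wallis(groups)
    for f in (np.exp, np.log, lambda x: np.asarray(x) ** 3):
        ht, _ = kruskal_wallis([list(f(np.asarray(g))) for g in groups])
        assert ht == pytest.approx(h0, abs=1e-9)


# -------------------------------------------------------- Bonferroni

def test_bonferroni_arithmetic_cap_and_identity():
    assert bonferroni([0.004], 5) == [pytest.approx(0.02)]
    assert bonferroni([0.3], 5) == [1.0]
    assert bonferroni([0.2]) == [pytest.approx(0.2)]  # m = 1
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)
    with pytest.raises(ValueError):
        bonferroni([1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_bonferroni_monotone_and_never_below_input(ps):
    adj = bonferroni(ps)
    assert all(a >= p for a, p in zip(adj, ps))
    order = np.argsort(ps)
    assert all(adj[order[i]] <= adj[order[i + 1]] for i in range(len(ps) - 1))


# ------------------------------------------------------------ screen

def test_screen_noise_free_recovers_planted_truth_exactly():
    cfg = GeneratorConfig(n_genes=30, n_tissues=2, samples_per_bin=4,
                          planted_increasing=3, planted_decreasing=3,
                          noise_sigma=0.0, effect_size=0.5,
                          planted_term_size=5, planted_term_overlap=4, seed=2)
    ds, truth = generate_expression(cfg)
    for tissue in ds.tissues:
        results = screen_tissue(ds, tissue, ds.genes)
        for r in results:
            want = truth.direction(r.gene, tissue)
            assert r.direction == want
            assert r.significant == (want != "none")


def test_screen_all_flat_means_no_tests():
    cfg = GeneratorConfig(n_genes=20, n_tissues=1, samples_per_bin=4,
                          planted_increasing=0, planted_decreasing=0,
                          noise_sigma=0.0, planted_term_size=5,
                          planted_term_overlap=0, seed=4)
    ds, _ = generate_expression(cfg)
    results = screen_tissue(ds, ds.tissues[0], ds.genes)
    assert all(r.direction == "none" and not r.significant for r in results)
    assert screen_tissue(ds, ds.tissues[0], []) == []


def test_screen_family_size_is_number_of_tests(tiny_bundle):
    ds, _ = tiny_bundle
    results = screen_tissue(ds, ds.tissues[0], ds.genes)
    tested = [r for r in results if r.direction != "none"]
    m = len(tested)
    for r in tested:
        assert r.p_adj == pytest.approx(min(1.0, r.p_raw * m))
        assert r.p_adj >= r.p_raw
    # sorted by adjusted p then gene
    keys = [(r.p_adj, r.gene) for r in results]
    assert keys == sorted(keys)
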