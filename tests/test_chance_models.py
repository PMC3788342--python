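"""Poisson-binomial tails and the two Monte Carlo null constructions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apexchange.chance_models import (
    FreeSelectionNull,
    joint_behavior_pvalue,
    null_histogram_tsv,
    poisson_binomial_pmf,
    poisson_binomial_upper_tail,
    selection_pvalue_free,
    simulate_free_selection,
)
from apexchange.exact_tests import binom_upper_tail
from apexchange.model import k_profile

MM_PROBS = [1.0, 0.5, 0.25, 0.25, 0.25, 0.25, 0.25, 0.5, 0.25, 0.5,
            0.25, 0.25]


def brute_force_tail(probs, x):
    """Independent oracle: enumerate all 2^n inclusion patterns."""
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=len(probs)):
        if sum(pattern) >= x:
            total += math.prod(p if b else 1 - p
                               for p, b in zip(probs, pattern))
    return total


@pytest.fixture(scope="module")
def fixture_nulls(records):
    return {name: FreeSelectionNull.from_trials(
        records[name].experiments["exp2"])
        for name in ("Manda", "Maria-Magdalena", "Naong")}


class TestPoissonBinomial:
    def test_maria_magdalena_profile_rounds_to_published_value(self):
        p = poisson_binomial_upper_tail(MM_PROBS, 7)
        assert p == pytest.approx(0.0936279296875, abs=1e-12)
        assert round(p, 3) == 0.094

    def test_forced_success_and_whole_support(self):
        assert poisson_binomial_upper_tail([1.0], 1) == 1.0
        assert poisson_binomial_upper_tail([0.3, 0.7], 0) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=0, max_size=12),
           st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pmf_sums_to_one_and_matches_enumeration(self, probs, x_frac):
        pmf = poisson_binomial_pmf(probs)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        x = round(x_frac * len(probs))
        assert poisson_binomial_upper_tail(probs, x) == pytest.approx(
            brute_force_tail(probs, x), abs=1e-12)

    @given(n=st.integers(1, 20), p=st.floats(0, 1),
           x_frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equal_probs_reduce_to_binomial(self, n, p, x_frac):
        x = round(x_frac * n)
        assert poisson_binomial_upper_tail([p] * n, x) == pytest.approx(
            binom_upper_tail(x, n, p), abs=1e-10)

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_upper_tail([0.5, 1.2], 1)
        with pytest.raises(ValueError):
            poisson_binomial_upper_tail([0.5], 2)


class TestSelectionPvalueFree:
    # frozen from the exact convolution oracle
    @pytest.mark.parametrize("subject,observed,expected", [
        ("Maria-Magdalena", 7, 0.0936279296875),
        ("Manda", 12, 8.58306884765625e-6),   # product of inclusion probs
        ("Naong", 7, 7.01904296875e-4),
    ])
    def test_fixture_pvalues_exact(self, fixture_nulls, subject, observed,
                                   expected):
        res = selection_pvalue_free(fixture_nulls[subject], observed)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_manda_is_product_of_inclusion_probs(self, fixture_nulls):
        null = fixture_nulls["Manda"]
        res = selection_pvalue_free(null, null.n_trials)
        assert res.p_value == pytest.approx(
            math.prod(null.inclusion_probs), abs=1e-15)

    @pytest.mark.parametrize("subject,observed", [
        ("Maria-Magdalena", 7), ("Manda", 12), ("Naong", 7)])
    def test_monte_carlo_within_three_se_of_exact(self, fixture_nulls,
                                                  subject, observed):
        null = fixture_nulls[subject]
        exact = selection_pvalue_free(null, observed).p_value
        mc = selection_pvalue_free(null, observed, method="monte_carlo",
                                   n_sims=50_000, seed=7)
        se = math.sqrt(exact * (1 - exact) / mc.n_sims)
        assert abs(mc.p_value - exact) <= 3 * se + 1e-12
        assert mc.method == "monte_carlo" and mc.seed == 7

    def test_all_single_removals_reduce_to_binomial(self):
        null = FreeSelectionNull((1,) * 9, m=4)
        for x in range(10):
            assert selection_pvalue_free(null, x).p_value == pytest.approx(
                binom_upper_tail(x, 9, 0.25), abs=1e-12)

    def test_observed_beyond_trials_rejected(self, fixture_nulls):
        with pytest.raises(ValueError):
            selection_pvalue_free(fixture_nulls["Naong"], 9)


class TestJointBehaviorPvalue:
    def test_maria_magdalena_twelve_of_twelve(self, fixture_nulls):
        res = joint_behavior_pvalue(fixture_nulls["Maria-Magdalena"], 12)
        assert res.p_value == pytest.approx(0.25**12, abs=1e-15)
        assert res.p_value < 0.001

    def test_naong_seven_of_eight(self, fixture_nulls):
        res = joint_behavior_pvalue(fixture_nulls["Naong"], 7)
        assert res.p_value == pytest.approx(3.814697265625e-4, abs=1e-12)
        assert res.p_value < 0.001

    def test_zero_observed_gives_one(self, fixture_nulls):
        assert joint_behavior_pvalue(fixture_nulls["Manda"], 0).p_value \
            == 1.0

    @pytest.mark.parametrize("policy", ["always_offer", "offer_or_refuse"])
    def test_exact_branch_matches_monte_carlo(self, fixture_nulls, policy):
        null = fixture_nulls["Naong"]
        for observed in (4, 7):
            exact = joint_behavior_pvalue(null, observed,
                                          offer_policy=policy).p_value
            mc = joint_behavior_pvalue(null, observed, method="monte_carlo",
                                       n_sims=50_000, seed=11,
                                       offer_policy=policy)
            se = math.sqrt(exact * (1 - exact) / mc.n_sims)
            assert abs(mc.p_value - exact) <= 3 * se + 1e-12

    def test_per_trial_probability_is_one_over_m(self, fixture_nulls):
        # removing k of m then offering one of the k uniformly gives 1/m
        # exactly, so the null collapses to Binomial(n, 1/m)
        null = fixture_nulls["Maria-Magdalena"]
        for x in range(null.n_trials + 1):
            assert joint_behavior_pvalue(null, x).p_value == pytest.approx(
                binom_upper_tail(x, null.n_trials, 0.25), abs=1e-12)

    def test_refusal_policy_uses_k_plus_one_options(self):
        null = FreeSelectionNull((1, 3), m=4)
        expected = brute_force_tail([0.5, 0.25], 1)
        assert joint_behavior_pvalue(
            null, 1, offer_policy="offer_or_refuse").p_value == \
            pytest.approx(expected, abs=1e-12)


class TestSimulateFreeSelection:
    def test_certain_inclusion_when_all_items_removed(self):
        null = FreeSelectionNull((4, 4, 4), m=4)
        assert simulate_free_selection(null, 0).all()

    def test_empty_profile_gives_empty_vector(self):
        assert simulate_free_selection(FreeSelectionNull((), 4), 0).size == 0

    def test_replicate_mean_matches_expectation(self, fixture_nulls):
        # E[target retrievals] for Maria-Magdalena = 1 + 3*0.5 + 8*0.25 = 4.5
        null = fixture_nulls["Maria-Magdalena"]
        rng = np.random.default_rng(3)
        counts = [simulate_free_selection(null, rng).sum()
                  for _ in range(50_000)]
        mean = np.mean(counts)
        var = sum(p * (1 - p) for p in null.inclusion_probs)
        se = math.sqrt(var / len(counts))
        assert abs(mean - 4.5) <= 3 * se

    def test_deterministic_given_seed(self, fixture_nulls):
        null = fixture_nulls["Manda"]
        a = simulate_free_selection(null, 42)
        b = simulate_free_selection(null, 42)
        assert (a == b).all()


def test_invalid_null_profiles_rejected():
    with pytest.raises(ValueError):
        FreeSelectionNull((0, 2), m=4)
    with pytest.raises(ValueError):
        FreeSelectionNull((5,), m=4)


def test_null_histogram_tsv_lists_full_support(fixture_nulls):
    text = null_histogram_tsv(fixture_nulls["Naong"])
    lines = text.strip().splitlines()
    assert lines[0] == "count\tprobability"
    assert len(lines) == 10  # counts 0..8
    probs = [float(l.split("\t")[1]) for l in lines[1:]]
    assert sum(probs) == pytest.approx(1.0, abs=1e-9)
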