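"""Checkerboard swaps, permutation chains, coefficients and p-values."""

import numpy as np
import pytest
from scipy import stats

from firenet.network_core import GBIMatrix
from firenet.permutation_inference import (
    BaciConfig,
    SwapConstraint,
    checkerboard_swap,
    period_coefficient,
    permutation_pvalue,
    permute_stream,
    run_baci,
    run_scenario_test,
)
from firenet.synthetic_data import (
    DEFAULT_WINDOWS,
    SyntheticConfig,
    generate_dataset,
)

from conftest import random_gbi


def gbi_from(rows, row_prefix="g", cols=None):
    m = np.array(rows, dtype=np.uint8)
    cols = cols or tuple(f"i{j}" for j in range(m.shape[1]))
    return GBIMatrix(m, tuple(f"{row_prefix}{i}" for i in range(m.shape[0])), cols)


class TestCheckerboardSwap:
    def test_identity_pattern_flips(self):
        gbi = gbi_from([[1, 0], [0, 1]])
        swapped = checkerboard_swap(gbi, np.random.default_rng(0))
        assert swapped.entries.tolist() == [[0, 1], [1, 0]]

    def test_all_ones_matrix_passes_through_unchanged(self):
        gbi = gbi_from([[1, 1], [1, 1]])
        swapped = checkerboard_swap(gbi, np.random.default_rng(0))
        assert np.array_equal(swapped.entries, gbi.entries)

    def test_margins_preserved_over_ten_thousand_swaps(self, rng):
        gbi = random_gbi(rng, max_rows=8, max_cols=8)
        row_sums = gbi.entries.sum(axis=1).copy()
        col_sums = gbi.entries.sum(axis=0).copy()
        current = gbi
        for _ in range(10_000):
            current = checkerboard_swap(current, rng)
            assert np.array_equal(current.entries.sum(axis=1), row_sums)
            assert np.array_equal(current.entries.sum(axis=0), col_sums)

    def test_swaps_never_cross_constraint_blocks(self, rng):
        constraint = SwapConstraint(
            blocks=(frozenset({"i0", "i1"}), frozenset({"i2", "i3"}))
        )
        gbi = gbi_from(
            [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]]
        )
        # block-wise column sums are invariant per row if swaps stay in-block
        block_a = [0, 1]
        per_row_a = gbi.entries[:, block_a].sum(axis=1).copy()
        current = gbi
        for _ in range(2000):
            current = checkerboard_swap(current, rng, constraint)
            assert np.array_equal(current.entries[:, block_a].sum(axis=1), per_row_a)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            SwapConstraint(blocks=(frozenset({"a", "b"}), frozenset({"b"})))


class TestPermuteStream:
    def test_zero_swaps_yields_identity_chain(self):
        gbi = gbi_from([[1, 0, 1], [0, 1, 1]])
        for perm in permute_stream(gbi, 5, swaps_per_permutation=0, seed=3):
            assert np.array_equal(perm.entries, gbi.entries)

    def test_same_seed_reproduces_sequence_exactly(self, rng):
        gbi = random_gbi(rng)
        seq1 = [p.entries.copy() for p in permute_stream(gbi, 20, seed=11)]
        seq2 = [p.entries.copy() for p in permute_stream(gbi, 20, seed=11)]
        assert all(np.array_equal(a, b) for a, b in zip(seq1, seq2))

    def test_two_by_two_identity_alternates_between_patterns(self):
        gbi = gbi_from([[1, 0], [0, 1]])
        states = [p.entries.tolist() for p in permute_stream(gbi, 4, seed=0)]
        assert states == [
            [[0, 1], [1, 0]], [[1, 0], [0, 1]],
            [[0, 1], [1, 0]], [[1, 0], [0, 1]],
        ]

    def test_rejects_nonpositive_permutation_count(self, rng):
        with pytest.raises(ValueError):
            list(permute_stream(random_gbi(rng), 0))


class TestPeriodCoefficient:
    def test_binary_predictor_slope_is_mean_difference(self):
        assert period_coefficient([1, 2], [2, 3]) == 1.0

    def test_identical_samples_give_zero(self):
        assert period_coefficient([1.5, 2.5], [1.5, 2.5]) == 0.0

    def test_equals_ols_slope_to_machine_precision(self, rng):
        for _ in range(50):
            pre = rng.normal(1.4, 0.6, size=rng.integers(2, 40))
            post = rng.normal(2.3, 0.9, size=rng.integers(2, 40))
            x = np.concatenate([np.zeros(pre.size), np.ones(post.size)])
            y = np.concatenate([pre, post])
            slope = np.polyfit(x, y, 1)[0]
            assert period_coefficient(pre, post) == pytest.approx(slope, abs=1e-10)

    def test_shift_invariance_of_coefficient(self, rng):
        pre = rng.normal(size=10)
        post = rng.normal(size=12)
        assert period_coefficient(pre + 7.3, post + 7.3) == pytest.approx(
            period_coefficient(pre, post)
        )

    def test_means_echoing_observed_shift(self):
        pre = np.full(28, 1.41)
        post = np.full(29, 2.35)
        assert period_coefficient(pre, post) == pytest.approx(0.94)

    def test_empty_period_errors(self):
        with pytest.raises(ValueError):
            period_coefficient([], [1.0])


class TestPermutationPvalue:
    def test_observed_beyond_all_999_nulls_gives_one_in_a_thousand(self):
        nulls = np.linspace(-1, 1, 999)
        assert permutation_pvalue(2.0, nulls, "greater") == pytest.approx(0.001)

    def test_observed_equal_to_every_null_gives_one(self):
        assert permutation_pvalue(0.5, [0.5] * 100, "greater") == 1.0

    def test_hand_counted_small_case(self):
        assert permutation_pvalue(1.0, [0.2, 0.5, 1.5], "greater") == 0.5

    def test_less_tail_mirrors_greater(self):
        nulls = [0.2, 0.5, 1.5]
        assert permutation_pvalue(0.3, nulls, "less") == (1 + 1) / 4


class TestScenarioTest:
    def test_identical_single_group_matrices_give_zero_coef(self):
        gbi = gbi_from([[1, 1, 1]])
        res = run_scenario_test(gbi, gbi, n_permutations=20, seed=0)
        assert res.observed_coef == 0.0
        assert 0 < res.p_one_tailed <= 1

    def test_zero_swaps_gives_p_one(self, rng):
        gbi = random_gbi(rng)
        res = run_scenario_test(
            gbi, gbi, n_permutations=50, swaps_per_permutation=0, seed=1
        )
        assert res.p_one_tailed == 1.0

    def test_same_seed_reproduces_null_coefficients_exactly(self, rng):
        pre, post = random_gbi(rng), random_gbi(rng)
        a = run_scenario_test(pre, post, n_permutations=50, seed=7)
        b = run_scenario_test(pre, post, n_permutations=50, seed=7)
        assert np.array_equal(a.null_coefs, b.null_coefs)

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError):
            run_scenario_test(random_gbi(rng), random_gbi(rng), metric="betweenness")

    def test_permuted_matrices_keep_margins_every_permutation(self, rng):
        gbi = random_gbi(rng, max_rows=8, max_cols=6)
        for perm in permute_stream(gbi, 200, seed=5):
            assert np.array_equal(perm.group_sizes(), gbi.group_sizes())
            assert np.array_equal(perm.sighting_counts(), gbi.sighting_counts())


class TestNullUniformity:
    def test_pvalues_approximately_uniform_under_null_generator(
        self, null_calibration_pvalues
    ):
        ks = stats.kstest(null_calibration_pvalues, "uniform").statistic
        assert ks < 0.1


@pytest.fixture(scope="module")
def baci_result():
    cfg = SyntheticConfig(seed=5)
    population, observations, _, _ = generate_dataset(cfg)
    return run_baci(
        observations, population.scar, DEFAULT_WINDOWS,
        BaciConfig(n_permutations=300, seed=9),
    )


class TestRunBaci:
    def test_effect_in_affected_arm_only(self, baci_result):
        p = {
            (t.label, t.metric): t.p_one_tailed for t in baci_result.tests
        }
        assert p[("affected", "weighted_degree")] < 0.05
        assert p[("unaffected", "weighted_degree")] > 0.05

    def test_summary_has_one_cell_per_arm_period(self, baci_result):
        cells = {(c["scenario"], c["period"]) for c in baci_result.summary}
        assert cells == {
            ("affected", "pre"), ("affected", "post"),
            ("unaffected", "pre"), ("unaffected", "post"),
        }

    def test_single_period_input_reports_missing_not_crash(self):
        cfg = SyntheticConfig(seed=5, n_obs_days_post=1, groups_per_day=1)
        population, observations, _, _ = generate_dataset(cfg)
        pre_only = [
            o for o in observations
            if DEFAULT_WINDOWS["pre"].contains(o.obs_date)
        ]
        result = run_baci(
            pre_only, population.scar, DEFAULT_WINDOWS,
            BaciConfig(n_permutations=10, seed=0),
        )
        assert "affected-post" in result.missing
        assert result.tests == ()
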