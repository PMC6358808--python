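"""Partition enumeration, AUROC statistics, and the validation engine."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metapair import (
    PartitionPlan,
    ValidationError,
    auroc,
    auroc_pvalue,
    count_partitions,
    evaluate_partition,
    paired_auroc_pvalue,
    run_validation,
    systematic_sample,
    unrank_combination,
)
from metapair.validation import _exact_u_pmf, _paired_u_pmf, histogram_table


class TestCountPartitions:
    def test_study_design_count(self):
        assert count_partitions(32, 22) == 64_512_240

    @pytest.mark.parametrize("n,k,expected", [(4, 2, 6), (5, 0, 1), (5, 5, 1)])
    def test_small_cases(self, n, k, expected):
        assert count_partitions(n, k) == expected

    def test_k_above_n_rejected(self):
        with pytest.raises(ValidationError):
            count_partitions(3, 4)


class TestSystematicSample:
    def test_study_design_thinning(self):
        ranks = systematic_sample(64_512_240, 310)
        assert len(ranks) == 208_104
        assert ranks[0] == 0 and ranks[-1] < 64_512_240

    def test_step_one_enumerates_everything(self):
        assert list(systematic_sample(10, 1)) == list(range(10))

    def test_step_seven_of_hundred(self):
        ranks = list(systematic_sample(100, 7))
        assert len(ranks) == 15 and ranks[-1] == 98

    def test_offset_shifts_grid(self):
        assert list(systematic_sample(10, 3, offset=1)) == [1, 4, 7]

    def test_zero_step_rejected(self):
        with pytest.raises(ValidationError):
            systematic_sample(10, 0)


class TestUnrankCombination:
    def test_first_and_last(self):
        assert unrank_combination(0, 4, 2) == (0, 1)
        assert unrank_combination(5, 4, 2) == (2, 3)

    def test_specific_rank_matches_enumeration(self):
        combos = list(itertools.combinations(range(5), 2))
        assert unrank_combination(3, 5, 2) == combos[3]

    @pytest.mark.parametrize("n", range(1, 13))
    def test_bijection_against_bruteforce(self, n):
        """Unranking 0..C(n,k)-1 reproduces lexicographic enumeration."""
        for k in range(n + 1):
            expected = list(itertools.combinations(range(n), k))
            got = [unrank_combination(r, n, k) for r in range(len(expected))]
            assert got == expected

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValidationError):
            unrank_combination(6, 4, 2)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.ones(6), [1, 1, 1, 0, 0, 0]) == 0.5

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            labels[0] = 1 - labels[0]
        concordant = 0.0
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        for sp in pos:
            for sn in neg:
                concordant += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        expected = concordant / (len(pos) * len(neg))
        assert auroc(np.array(scores, float), np.array(labels)) == pytest.approx(
            expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([0.1, 0.2], [1, 1])


class TestAurocPvalue:
    def test_chance_value_gives_one(self):
        assert auroc_pvalue(0.5, 10, 10) == 1.0

    def test_symmetry(self):
        for n_pos, n_neg in [(10, 10), (7, 9), (3, 15)]:
            assert auroc_pvalue(0.8, n_pos, n_neg) == pytest.approx(
                auroc_pvalue(0.2, n_pos, n_neg))

    def test_perfect_auroc_exact_tail(self):
        """AUROC 1 at 10 vs 10 has two-sided p = 2 P(U = 0) = 2 / C(20,10)."""
        assert auroc_pvalue(1.0, 10, 10) == pytest.approx(
            2 / math.comb(20, 10))

    def test_exact_pmf_matches_enumeration(self):
        """DP-based U pmf equals brute-force enumeration of orderings."""
        for m, n in [(2, 3), (3, 3), (4, 2)]:
            counts = np.zeros(m * n + 1)
            for pos_ranks in itertools.combinations(range(m + n), m):
                u = sum(pos_ranks) - m * (m - 1) // 2
                counts[u] += 1
            np.testing.assert_allclose(
                _exact_u_pmf(m, n), counts / counts.sum(), atol=1e-12)

    def test_normal_approximation_branch(self):
        p = auroc_pvalue(0.7, 25, 25)  # product 625 > exact cutoff
        assert 0 < p < 0.05

    def test_directional_is_half_of_two_sided_in_tail(self):
        two = auroc_pvalue(0.9, 10, 10)
        one = auroc_pvalue(0.9, 10, 10, directional=True)
        assert one == pytest.approx(two / 2)

    def test_out_of_range_auroc_rejected(self):
        with pytest.raises(ValidationError):
            auroc_pvalue(1.2, 5, 5)


class TestPairedNull:
    def test_pmf_matches_sign_enumeration(self):
        """Mirrored-pair U pmf equals enumeration over sign patterns."""
        for n in (2, 3, 4, 5):
            counts = np.zeros(n * n + 1)
            for signs in itertools.product([0, 1], repeat=n):
                u = sum((2 * (i + 1) - 1) * s for i, s in enumerate(signs))
                counts[u] += 1
            np.testing.assert_allclose(
                _paired_u_pmf(n), counts / counts.sum(), atol=1e-12)

    def test_pmf_matches_mirrored_score_simulation(self):
        """Monte-Carlo AUROC of mirrored gaussian scores follows the pmf."""
        rng = np.random.default_rng(1)
        n = 6
        labels = np.array([1] * n + [0] * n)
        us = []
        for _ in range(4000):
            e = rng.standard_normal(n)
            scores = np.concatenate([e, -e])
            us.append(round(auroc(scores, labels) * n * n))
        observed = np.bincount(us, minlength=n * n + 1) / len(us)
        expected = _paired_u_pmf(n)
        assert np.abs(observed - expected).max() < 0.02

    def test_chance_value_gives_one(self):
        assert paired_auroc_pvalue(0.5, 10) == 1.0

    def test_symmetry(self):
        assert paired_auroc_pvalue(0.85, 10) == pytest.approx(
            paired_auroc_pvalue(0.15, 10))

    def test_wider_than_mann_whitney(self):
        """The mirrored null has heavier tails, hence larger p at the same
        AUROC."""
        assert paired_auroc_pvalue(0.8, 10) > auroc_pvalue(0.8, 10, 10)


class TestPartitionPlan:
    def test_study_design_plan(self):
        plan = PartitionPlan()
        assert plan.total_partitions == 64_512_240
        assert plan.n_models == 208_104

    def test_max_models_caps_ranks(self):
        plan = PartitionPlan(max_models=100)
        assert plan.n_models == 100

    def test_ranks_strictly_increasing_below_total(self):
        plan = PartitionPlan(n_pairs=8, n_train_pairs=5, step=3)
        ranks = plan.ranks
        assert all(b > a for a, b in zip(ranks, ranks[1:]))
        assert ranks[-1] < plan.total_partitions
        assert len(ranks) == math.ceil(plan.total_partitions / 3)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValidationError):
            PartitionPlan(n_pairs=8, n_train_pairs=8)


def _mirrored_data(rng, n_pairs=16, n_vars=6, effect=0.0):
    """Within-pair transformed data with an optional planted class shift."""
    ids = np.repeat([f"P{i:02d}" for i in range(n_pairs)], 2)
    labels = np.tile([1, 0], n_pairs)
    X = rng.standard_normal((2 * n_pairs, n_vars))
    X[labels == 1, 0] += effect
    from metapair import within_pair_transform

    return within_pair_transform(X, ids), ids, labels


class TestEvaluatePartition:
    def test_deterministic(self, rng):
        X, ids, labels = _mirrored_data(rng)
        r1 = evaluate_partition(X, ids, labels, rank=5, n_train_pairs=11)
        r2 = evaluate_partition(X, ids, labels, rank=5, n_train_pairs=11)
        assert r1.auroc == r2.auroc and r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.vip, r2.vip)

    def test_train_test_split_sizes(self, default_cohort):
        """22 training pairs leave 10 test pairs: 44 / 20 samples."""
        from metapair.validation import _pair_blocks, unrank_combination

        cohort, _ = default_cohort
        pairs, rows = _pair_blocks(cohort.pair_ids.to_numpy())
        assert len(pairs) == 32
        train = unrank_combination(123456, 32, 22)
        train_rows = sum(len(rows[i]) for i in train)
        assert train_rows == 44 and 64 - train_rows == 20

    def test_planted_perfect_separator(self, rng):
        X, ids, labels = _mirrored_data(rng, effect=50.0)
        for rank in (0, 99, 1234):
            res = evaluate_partition(X, ids, labels, rank, n_train_pairs=11)
            assert res.auroc == 1.0

    def test_null_auroc_centered_at_half(self, rng):
        """Label-exchangeable data: AUROC distribution centered on 0.5."""
        aurocs = []
        for seed in range(60):
            X, ids, labels = _mirrored_data(np.random.default_rng(seed))
            res = evaluate_partition(X, ids, labels, rank=seed * 7,
                                     n_train_pairs=11)
            aurocs.append(res.auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.08


class TestRunValidation:
    def test_summary_determinism_and_stream(self, rng, tmp_path):
        X, ids, labels = _mirrored_data(rng)
        plan = PartitionPlan(n_pairs=16, n_train_pairs=11, step=101,
                             max_models=50)
        path = tmp_path / "models.jsonl"
        s1, r1 = run_validation(X, ids, labels, plan, stream_path=path)
        s2, r2 = run_validation(X, ids, labels, plan)
        assert s1.to_dict() == s2.to_dict()
        lines = path.read_text().splitlines()
        assert len(lines) == s1.n_models
        first = json.loads(lines[0])
        assert first["rank"] == plan.ranks[0]
        assert 0 <= first["auroc"] <= 1

    def test_fraction_accounting(self, rng):
        X, ids, labels = _mirrored_data(rng, effect=1.0)
        plan = PartitionPlan(n_pairs=16, n_train_pairs=11, step=75,
                             max_models=80)
        s, r = run_validation(X, ids, labels, plan)
        assert s.fraction_significant == pytest.approx(
            s.fraction_significantly_better + s.fraction_significantly_worse)
        assert 0 <= s.fraction_significant <= 1

    def test_weak_data_no_selection(self, rng):
        """Median AUROC around chance: the decision rule blocks selection."""
        X, ids, labels = _mirrored_data(rng)
        plan = PartitionPlan(n_pairs=16, n_train_pairs=11, step=200,
                             max_models=60)
        s, _ = run_validation(X, ids, labels, plan)
        assert s.median_auroc < 0.8
        assert not s.decision
        assert s.selected_variables == []

    def test_strong_effect_selects_planted_variables(self, rng):
        X, ids, labels = _mirrored_data(rng, n_pairs=16, n_vars=8, effect=3.0)
        plan = PartitionPlan(n_pairs=16, n_train_pairs=11, step=150,
                             max_models=80)
        names = [f"v{j}" for j in range(8)]
        s, _ = run_validation(X, ids, labels, plan, variable_names=names)
        assert s.median_auroc >= 0.8 and s.median_p <= 0.05
        assert s.decision
        assert "v0" in s.selected_variables

    def test_thinning_consistency(self, rng):
        """A coarser systematic grid gives a consistent median AUROC."""
        X, ids, labels = _mirrored_data(rng, n_pairs=16, effect=1.0)
        fine = PartitionPlan(n_pairs=16, n_train_pairs=11, step=40)
        coarse = PartitionPlan(n_pairs=16, n_train_pairs=11, step=160)
        s_fine, _ = run_validation(X, ids, labels, fine)
        s_coarse, _ = run_validation(X, ids, labels, coarse)
        assert abs(s_fine.median_auroc - s_coarse.median_auroc) < 0.1

    def test_failure_names_offending_rank(self, rng):
        X, ids, labels = _mirrored_data(rng, n_pairs=4, n_vars=3)
        labels = np.ones_like(labels)  # single class: every fit fails
        plan = PartitionPlan(n_pairs=4, n_train_pairs=2, step=2)
        with pytest.raises(ValidationError, match="rank 0"):
            run_validation(X, ids, labels, plan)


class TestHistogramTable:
    def test_counts_and_edges(self, rng):
        vals = rng.random(500)
        table = histogram_table(vals, bins=20)
        assert table["count"].sum() == 500
        assert table["bin_left"].iloc[0] == 0.0
        assert table["bin_right"].iloc[-1] == 1.0
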