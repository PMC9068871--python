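"""Repeated divisions, intersection, rank matrix, signature, subset screen."""

import numpy as np
import pandas as pd
import pytest

from permsig import (
    InputError,
    ScoreTable,
    SelectionResult,
    balanced_split,
    intersect_selections,
    rank_matrix,
    signature_topk,
    subset_combination_screen,
)
from permsig.stability import run_divisions


def selection(ordered_ids, scores_by_id, threshold=0.0):
    """Hand-built SelectionResult with a consistent score table."""
    ids = sorted(scores_by_id)
    return SelectionResult(
        threshold=threshold,
        selected_feature_ids=list(ordered_ids),
        all_scores=ScoreTable(ids, [scores_by_id[f] for f in ids], n_rounds=10),
    )


class TestIntersectSelections:
    def test_identical_selections(self):
        s = selection(["a", "b"], {"a": 0.9, "b": 0.5, "c": 0.0})
        assert intersect_selections([s, s, s]) == ["a", "b"]

    def test_disjoint_selections_empty(self):
        s1 = selection(["a"], {"a": 0.9, "b": 0.5})
        s2 = selection(["b"], {"a": 0.9, "b": 0.5})
        assert intersect_selections([s1, s2]) == []

    def test_commutative_and_idempotent(self):
        s1 = selection(["a", "b", "c"], {"a": 0.9, "b": 0.5, "c": 0.3})
        s2 = selection(["b", "a"], {"a": 0.6, "b": 0.8, "c": 0.1})
        forward = intersect_selections([s1, s2])
        backward = intersect_selections([s2, s1])
        assert forward == backward
        assert intersect_selections([s1, s1]) == intersect_selections([s1])

    def test_ordered_by_mean_score(self):
        s1 = selection(["a", "b"], {"a": 0.9, "b": 0.1})
        s2 = selection(["b", "a"], {"a": 0.1, "b": 0.9})
        # equal means -> lexicographic tie-break
        assert intersect_selections([s1, s2]) == ["a", "b"]


class TestRankMatrix:
    def test_single_division_positions(self):
        s = selection(["x", "y", "z"], {"x": 0.9, "y": 0.8, "z": 0.7})
        ranks = rank_matrix([s], ["y", "z"])
        assert ranks.loc[0, "y"] == 2 and ranks.loc[0, "z"] == 3

    def test_dominant_feature_constant_row_of_ones(self, medium_planted):
        """One overwhelming marker stays rank 1 in every division."""
        data, truth = medium_planted
        runs = run_divisions(data, R=3, n_rounds=150, root_seed=13)
        core = intersect_selections(runs)
        ranks = rank_matrix(runs, core)
        top = ranks.median(axis=0).idxmin()
        assert top in truth

    def test_ranks_are_permutation_prefix(self):
        s1 = selection(["a", "b", "c"], {"a": 3.0, "b": 2.0, "c": 1.0})
        s2 = selection(["c", "a", "b"], {"a": 2.0, "b": 1.0, "c": 3.0})
        ranks = rank_matrix([s1, s2], ["a", "b", "c"])
        for _, row in ranks.iterrows():
            assert sorted(row) == [1, 2, 3]

    def test_core_missing_from_division_rejected(self):
        s1 = selection(["a", "b"], {"a": 1.0, "b": 0.5})
        s2 = selection(["a"], {"a": 1.0, "b": 0.5})
        with pytest.raises(InputError, match="division 1"):
            rank_matrix([s1, s2], ["a", "b"])


class TestSignatureTopk:
    def test_median_rank_rule(self):
        ranks = pd.DataFrame({"a": [1, 1, 2], "b": [2, 2, 1], "c": [9, 8, 7]})
        assert signature_topk(ranks, k=2) == ["a", "b"]

    def test_all_tied_falls_back_to_mean_then_id(self):
        ranks = pd.DataFrame({"b": [1, 3], "a": [3, 1], "c": [2, 2]})
        # medians all 2 -> means all 2 -> lexicographic
        assert signature_topk(ranks, k=3) == ["a", "b", "c"]

    def test_fewer_than_k_qualifying(self):
        ranks = pd.DataFrame({"a": [1, 1], "b": [9, 9]})
        assert signature_topk(ranks, k=3) == ["a"]

    def test_independent_of_division_order(self):
        ranks = pd.DataFrame({"a": [1, 4, 2], "b": [2, 1, 3], "c": [3, 2, 1]})
        shuffled = ranks.iloc[[2, 0, 1]].reset_index(drop=True)
        assert signature_topk(ranks, 2) == signature_topk(shuffled, 2)


class TestRunDivisions:
    def test_single_division_matches_direct_pipeline(self, medium_planted):
        from permsig import run_scoring, fit_two_component_gmm, select_features, selection_threshold
        from permsig.splitting import derive_seed

        data, _ = medium_planted
        runs = run_divisions(data, R=1, n_rounds=25, root_seed=8)
        seed0 = derive_seed(8, 0, 21)
        plan = balanced_split(data, 0.5, seed=seed0)
        train = data.subset_samples(plan.train_ids)
        acc = run_scoring(train, 25, root_seed=seed0)
        table = acc.to_score_table()
        fit = fit_two_component_gmm(table.accumulated_scores, seed=0)
        direct = select_features(table, selection_threshold(fit))
        assert runs[0].selection.selected_feature_ids == direct.selected_feature_ids
        np.testing.assert_array_equal(
            runs[0].scores.per_feature, acc.per_feature
        )

    def test_same_root_seed_identical_report(self, medium_planted):
        data, _ = medium_planted
        # manual threshold keeps this focused on determinism, not EM fit
        a = run_divisions(data, R=2, n_rounds=15, root_seed=31, threshold_override=0.02)
        b = run_divisions(data, R=2, n_rounds=15, root_seed=31, threshold_override=0.02)
        for ra, rb in zip(a, b):
            assert ra.selection.selected_feature_ids == rb.selection.selected_feature_ids
            assert ra.selection.threshold == rb.selection.threshold

    def test_markers_survive_intersection(self, medium_planted):
        data, truth = medium_planted
        runs = run_divisions(data, R=3, n_rounds=150, root_seed=17)
        core = intersect_selections(runs)
        assert set(truth) <= set(core)
        signature = signature_topk(rank_matrix(runs, core), k=len(truth))
        assert set(signature) == set(truth)


class TestSubsetScreen:
    def test_subset_counts(self, small_planted):
        data, truth = small_planted
        plan = balanced_split(data, 0.5, seed=2)
        train = data.subset_samples(plan.train_ids)
        test = data.subset_samples(plan.test_ids)
        two = subset_combination_screen(train, test, truth[:2], n_rounds=2, root_seed=1)
        assert len(two) == 3
        five = subset_combination_screen(
            train, test, truth[:4] + [data.feature_ids[0]], n_rounds=1, root_seed=1
        )
        assert len(five) == 31

    def test_size_cap(self, small_planted):
        data, _ = small_planted
        with pytest.raises(InputError, match="subset"):
            subset_combination_screen(
                data, data, data.feature_ids[:13], n_rounds=1
            )

    def test_platform_shift_prefers_unshifted_subset(self):
        """With a scale shift planted on some markers, the screen's best
        subset avoids them."""
        from permsig import SyntheticConfig, generate_platform_pair

        config = SyntheticConfig(
            n_pos=60, n_neg=24, n_features=12, n_informative=4,
            effect_size=2.5, platform_shift=40.0, seed=23,
        )
        data_a, data_b, truth = generate_platform_pair(config, shifted_ids=truth_first_two(config))
        screen = subset_combination_screen(
            data_a, data_b, truth, n_rounds=8, root_seed=3
        )
        best = set(screen.iloc[0]["subset"].split(","))
        shifted = set(truth_first_two(config))
        assert not best & shifted


def truth_first_two(config):
    from permsig import generate

    _, truth = generate(config)
    return truth[:2]
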