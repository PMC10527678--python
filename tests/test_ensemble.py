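"""Group enumeration, metrics, filters, weights, entropy and selection."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermsense.ensemble import (Committee, InputGroup, ModelEvaluation,
                                committee_predict, ensemble_weights,
                                enumerate_input_groups,
                                explanation_probabilities, filter_by_mae, mae,
                                nmae, occurrence_probabilities, r2, rss,
                                rmse_from_rss, select_committee,
                                shannon_entropy, subset_dominance_filter)
from fermsense.errors import ContractError, InvalidInputError


def ev(group, mae_value, rmse=1.0):
    return ModelEvaluation(group=InputGroup(tuple(group)), mae=mae_value,
                           rss=rmse ** 2, r2=0.0, rmse=rmse)


class TestEnumeration:
    def test_counts_match_binomial_sums(self):
        pool5 = ("a", "b", "c", "d", "e")
        assert len(enumerate_input_groups(pool5, 3, 5)) == 16
        pool11 = tuple("abcdefghijk")
        assert len(enumerate_input_groups(pool11, 3, 11)) == 1981

    def test_minimal_pool_single_group(self):
        assert len(enumerate_input_groups(("a", "b", "c"), 3, 11)) == 1

    def test_deterministic_order_and_uniqueness(self):
        groups = enumerate_input_groups(tuple("abcde"), 3, 4)
        assert groups == enumerate_input_groups(tuple("abcde"), 3, 4)
        assert len({g.variables for g in groups}) == len(groups)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidInputError):
            enumerate_input_groups(("a", "b", "c"), 4, 3)
        with pytest.raises(InvalidInputError):
            InputGroup(("a", "a", "b"))


class TestMetrics:
    def test_perfect_fit(self):
        est = obs = np.array([1.0, 2.0, 3.0])
        assert mae(est, obs) == 0
        assert rss(est, obs) == 0
        assert r2(est, obs) == 1

    def test_hand_arithmetic_example(self):
        obs, est = [0.0, 2.0], [1.0, 1.0]
        assert mae(est, obs) == pytest.approx(1.0)
        assert rss(est, obs) == pytest.approx(2.0)
        assert r2(est, obs) == pytest.approx(0.0)
        assert rmse_from_rss(rss(est, obs), 2) == pytest.approx(1.0)

    def test_mean_predictor_has_zero_r2(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=30)
        assert r2(np.full(30, obs.mean()), obs) == pytest.approx(0.0, abs=1e-12)

    def test_constant_observations_rejected(self):
        with pytest.raises(InvalidInputError):
            r2([1.0, 2.0], [3.0, 3.0])

    def test_nmae(self):
        assert nmae(0.5, [0.0, 5.0]) == pytest.approx(0.1)
        assert nmae(0.0, [0.0, 5.0]) == 0.0
        with pytest.raises(InvalidInputError):
            nmae(0.1, [2.0, 2.0])

    def test_nmae_scale_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.uniform(0, 5, 20)
        est = obs + rng.normal(0, 0.3, 20)
        for c in (3.0, 0.1):
            assert nmae(mae(c * est, c * obs), c * obs) == \
                pytest.approx(nmae(mae(est, obs), obs))


class TestFilters:
    def test_mae_threshold_keeps_boundary(self):
        evals = [ev("abc", 0.3), ev("abd", 0.5), ev("abe", 0.51)]
        kept = filter_by_mae(evals, 0.5)
        assert [e.mae for e in kept] == [0.3, 0.5]

    def test_all_above_threshold_warns_and_empties(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = filter_by_mae([ev("abc", 0.9)], 0.5)
        assert out == []
        assert any("no group" in r.message for r in caplog.records)

    def test_infinite_threshold_is_identity(self):
        evals = [ev("abc", 5.0), ev("abd", 0.1)]
        assert filter_by_mae(evals, np.inf) == evals

    def test_subset_dominance_direct_rules(self):
        better_sub = [ev("ab", 0.2), ev("abc", 0.3)]
        out = subset_dominance_filter(better_sub)
        assert [e.group.variables for e in out] == [("a", "b")]
        better_super = [ev("ab", 0.3), ev("abc", 0.2)]
        assert len(subset_dominance_filter(better_super)) == 2

    def test_equal_mae_ties_keep_both(self):
        out = subset_dominance_filter([ev("ab", 0.3), ev("abc", 0.3)])
        assert len(out) == 2

    def test_subset_dominance_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pool = list("abcdef")
        for _ in range(20):
            seen = set()
            evals = []
            while len(evals) < 20:
                k = rng.integers(2, 5)
                g = tuple(sorted(rng.choice(pool, size=k, replace=False)))
                if g in seen:
                    continue
                seen.add(g)
                evals.append(ev(g, float(rng.uniform(0, 1))))
            expected = sorted(
                (e for e in evals
                 if not any(set(o.group.variables) < set(e.group.variables)
                            and o.mae < e.mae for o in evals)),
                key=lambda e: e.mae)
            assert subset_dominance_filter(evals) == expected


class TestWeights:
    def test_two_member_example(self):
        np.testing.assert_allclose(ensemble_weights([1.0, 3.0]), [0.75, 0.25])

    def test_equal_rmse_uniform(self):
        np.testing.assert_allclose(ensemble_weights([2.0] * 5), [0.2] * 5)

    def test_sum_to_one_and_antimonotone(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.1, 2.0, size=7)
        w = ensemble_weights(r)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(r)
        assert np.all(np.diff(w[order]) <= 1e-15)

    def test_degenerate_sizes(self):
        np.testing.assert_array_equal(ensemble_weights([0.7]), [1.0])
        with pytest.raises(InvalidInputError):
            ensemble_weights([])

    def test_committee_predict(self):
        est = committee_predict([[1.0, 1.0], [3.0, 3.0]], [0.75, 0.25])
        np.testing.assert_allclose(est, [1.5, 1.5])
        same = committee_predict([[2.0], [2.0]], [0.6, 0.4])
        assert same[0] == pytest.approx(2.0)
        with pytest.raises(ContractError):
            committee_predict([[1.0]], [0.5, 0.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2,
                    max_size=14))
    def test_weight_identities_hold_for_any_rmse_vector(self, rmses):
        w = ensemble_weights(rmses)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= -1e-12)
        order = np.argsort(rmses)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_committee_within_member_envelope(self):
        rng = np.random.default_rng(4)
        preds = [rng.uniform(0, 5, 10) for _ in range(4)]
        w = ensemble_weights(rng.uniform(0.5, 1.5, 4))
        est = committee_predict(preds, w)
        stack = np.vstack(preds)
        assert np.all(est >= stack.min(axis=0) - 1e-12)
        assert np.all(est <= stack.max(axis=0) + 1e-12)


class TestEntropy:
    def test_occurrence_probabilities_direct_count(self):
        probs = occurrence_probabilities([ev("ab", 0.1), ev("ac", 0.2)])
        assert probs == {"a": 1.0, "b": 0.5, "c": 0.5}

    def test_shared_group_all_ones(self):
        probs = occurrence_probabilities([ev("abc", 0.1)] * 3)
        assert set(probs.values()) == {1.0}

    def test_uniform_eighth_gives_three_bits(self):
        assert shannon_entropy([0.125] * 8) == pytest.approx(3.0)

    def test_certain_variable_contributes_nothing(self):
        assert shannon_entropy([1.0]) == 0.0
        assert shannon_entropy([0.5, 0.5, 1.0]) == pytest.approx(1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidInputError):
            shannon_entropy([1.5])


class TestSelection:
    def test_identical_groups_select_single_member(self):
        ranked = [ev("abc", 0.1 + 0.01 * i) for i in range(5)]
        committee = select_committee(ranked, max_size=5)
        assert len(committee) == 1
        assert committee.entropy == 0.0

    def test_planted_occupancy_design(self):
        # members 1-3 bring disjoint variable triples (entropy grows with
        # size); members 4-5 repeat the first group (entropy falls back)
        ranked = [ev("abc", 0.10), ev("def", 0.11), ev("ghi", 0.12),
                  ev("abc", 0.13), ev("abc", 0.14)]
        committee = select_committee(ranked, max_size=5)
        assert len(committee) == 3
        assert committee.entropy == pytest.approx(9 * (1 / 3) * math.log2(3))

    def test_contract_weights_and_ranking(self):
        ranked = [ev("abc", 0.1, rmse=0.2), ev("bcd", 0.2, rmse=0.3),
                  ev("cde", 0.3, rmse=0.4)]
        committee = select_committee(ranked, max_size=3)
        assert committee.weights.sum() == pytest.approx(1.0)
        assert [m.mae for m in committee.members] == \
            sorted(m.mae for m in committee.members)

    def test_unsorted_ranking_rejected(self):
        with pytest.raises(InvalidInputError):
            select_committee([ev("abc", 0.3), ev("bcd", 0.1)])
        with pytest.raises(InvalidInputError):
            select_committee([])


class TestExplanations:
    @staticmethod
    def _trained_stub(ds, seed=0, epochs=8):
        from fermsense.sensor import SensorConfig, train_sensor
        cfg = SensorConfig(max_epochs=epochs, window_steps=ds.X.shape[1],
                           seed=seed, patience=epochs)
        return train_sensor(ds, cfg)

    @staticmethod
    def _dataset(seed, informative=0, n_feat=2, window=6):
        from fermsense.sensor import concat_windows, make_windows
        rng = np.random.default_rng(seed)
        parts = []
        for e in range(4):
            t = np.linspace(0, 10, 30)
            f = np.column_stack([np.sin(t + rng.uniform(0, 6)) + 1.5
                                 for _ in range(n_feat)])
            y = 2.0 * f[:, informative]
            parts.append(make_windows(f, y, window, experiment_id=f"e{e}",
                                      times=t,
                                      feature_names=[f"v{j}" for j in range(n_feat)]))
        return concat_windows(parts)

    def test_single_feature_model_gets_probability_one(self):
        ds = self._dataset(0, n_feat=1)
        member = ev(["v0"], 0.1)
        member.model = self._trained_stub(ds, epochs=2)
        probs = explanation_probabilities([member], [ds], top_k=3, n_samples=50)
        assert probs == {"v0": 1.0}

    def test_probabilities_sum_to_at_most_one(self):
        ds = self._dataset(1)
        member = ev(["v0", "v1"], 0.1)
        member.model = self._trained_stub(ds, epochs=2)
        probs = explanation_probabilities([member], [ds], top_k=5, n_samples=50)
        assert sum(probs.values()) <= 1.0 + 1e-9

    def test_planted_signal_variable_ranks_first(self):
        wins = 0
        for seed in range(5):
            ds = self._dataset(seed + 10, informative=0)
            member = ev(["v0", "v1"], 0.1)
            member.model = self._trained_stub(ds, seed=seed, epochs=40)
            probs = explanation_probabilities([member], [ds], top_k=4,
                                              n_samples=150, seed=seed)
            if probs.get("v0", 0) > probs.get("v1", 0):
                wins += 1
        assert wins >= 3          # median over the 5 seeds

    def test_disabled_backend_falls_back_to_occurrence(self, caplog):
        members = [ev("ab", 0.1), ev("ac", 0.2)]
        with caplog.at_level(logging.WARNING):
            probs = explanation_probabilities(members, [], backend="none")
        assert probs == occurrence_probabilities(members)
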