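"""Rule enumeration, temporal predicates, and resampled evaluation."""

import numpy as np
import pytest

from hfsymptoms import (
    RuleSpec,
    SymptomRuleModel,
    apply_rule_single_day,
    apply_rule_two_day,
    confusion_at_cutoff,
    enumerate_rules,
    evaluate_rule,
    rank_rules,
    sample_consecutive_pairs,
    sample_random_days,
)
from hfsymptoms.cohort import SYMPTOMS
from hfsymptoms.cutoffs import DaySample
from hfsymptoms.windows import eligible_windows

from conftest import make_cohort
from oracles import exact_rule_means


class TestEnumeration:
    def test_pairs_and_triples_make_ten_rules(self):
        rules = enumerate_rules(SYMPTOMS, min_size=2, max_size=3)
        assert len(rules) == 10
        sizes = [len(r.symptoms) for r in rules]
        assert sizes == [2] * 6 + [3] * 4

    def test_sizes_two_through_four_make_eleven(self):
        assert len(enumerate_rules(SYMPTOMS, min_size=2, max_size=4)) == 11

    def test_singletons(self):
        rules = enumerate_rules(SYMPTOMS, min_size=1, max_size=1)
        assert [r.symptoms for r in rules] == [
            ("bendopnea",), ("dyspnea",), ("orthopnea",), ("pnd",)
        ]

    def test_deterministic_order(self):
        a = [r.name for r in enumerate_rules(SYMPTOMS)]
        b = [r.name for r in enumerate_rules(tuple(reversed(SYMPTOMS)))]
        assert a == b

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rules(SYMPTOMS, min_size=3, max_size=2)
        with pytest.raises(ValueError):
            enumerate_rules(SYMPTOMS, min_size=0, max_size=2)


class TestRuleSpec:
    def test_missing_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            RuleSpec(symptoms=("dyspnea",), cutoffs=())

    def test_increase_mode_needs_no_cutoffs(self):
        r = RuleSpec(symptoms=("dyspnea", "pnd"), cutoffs=(), temporal_mode="increase")
        assert r.cutoff_map == {}

    def test_unknown_symptom_rejected(self):
        with pytest.raises(KeyError):
            RuleSpec(symptoms=("cough",), cutoffs=(("cough", 3),))


class TestSingleDay:
    def _cohort(self, dysp, orth, bend):
        return make_cohort(
            [("P1", 14, {"dyspnea": dysp, "orthopnea": orth, "bendopnea": bend}),
             ("P2", 0, {})],
            [("P1", 1, 20), ("P2", 0, None)],
        )

    def test_conjunction_fires_when_all_meet_cutoffs(self):
        c = self._cohort(4, 3, 5)
        rule = RuleSpec.make(("dyspnea", "orthopnea", "bendopnea"),
                             {"dyspnea": 3, "orthopnea": 2, "bendopnea": 4})
        sample = DaySample(assignments={"P1": 14, "P2": 0})
        assert apply_rule_single_day(rule, sample, c)["P1"] is True

    def test_any_symptom_below_cutoff_blocks(self):
        c = self._cohort(4, 1, 5)
        rule = RuleSpec.make(("dyspnea", "orthopnea", "bendopnea"),
                             {"dyspnea": 3, "orthopnea": 2, "bendopnea": 4})
        sample = DaySample(assignments={"P1": 14})
        assert apply_rule_single_day(rule, sample, c)["P1"] is False

    def test_singleton_rule_matches_confusion_counts(self, tiny_cohort):
        rule = RuleSpec.make(("dyspnea",), {"dyspnea": 3})
        windows = eligible_windows(tiny_cohort)
        sample = sample_random_days(tiny_cohort, np.random.default_rng(0), windows=windows)
        preds = apply_rule_single_day(rule, sample, tiny_cohort)
        labels = tiny_cohort.labels()
        scores = []
        for pid, day in sample.assignments.items():
            visit = tiny_cohort.patient_visits(pid)
            scores.append(int(visit[visit["day"] == day]["dyspnea"].iloc[0]))
        y = [labels[p] for p in sample.assignments]
        res = confusion_at_cutoff(scores, y, 3)
        sens = np.mean([preds[p] for p in preds if labels[p] == 1])
        spec = np.mean([not preds[p] for p in preds if labels[p] == 0])
        assert sens == pytest.approx(res.sensitivity)
        assert spec == pytest.approx(res.specificity)


class TestTwoDay:
    def _pair_cohort(self, s1, s2):
        return make_cohort(
            [("P1", 14, {"dyspnea": s1}), ("P1", 17, {"dyspnea": s2}), ("P2", 0, {})],
            [("P1", 1, 21), ("P2", 0, None)],
        )

    @pytest.mark.parametrize(
        "mode, expected",
        [("either_of_two", True), ("both_of_two", False), ("increase", True)],
    )
    def test_predicates_on_rising_scores(self, mode, expected):
        c = self._pair_cohort(2, 4)
        rule = RuleSpec.make(("dyspnea",), {"dyspnea": 4}, temporal_mode=mode)
        assert apply_rule_two_day(rule, {"P1": (14, 17)}, c)["P1"] is expected

    @pytest.mark.parametrize(
        "mode, expected",
        [("either_of_two", True), ("both_of_two", True), ("increase", False)],
    )
    def test_predicates_on_constant_scores(self, mode, expected):
        c = self._pair_cohort(3, 3)
        rule = RuleSpec.make(("dyspnea",), {"dyspnea": 3}, temporal_mode=mode)
        assert apply_rule_two_day(rule, {"P1": (14, 17)}, c)["P1"] is expected

    def test_single_adjacent_pair_is_deterministic(self):
        c = self._pair_cohort(2, 3)
        windows = eligible_windows(c)
        for seed in (0, 5):
            pairs, omitted = sample_consecutive_pairs(
                c, np.random.default_rng(seed), windows=windows
            )
            assert pairs["P1"] == (14, 17)
        assert omitted == ("P2",)  # a single visit has no adjacent pair

    def test_pair_sampling_uniform_and_seeded(self):
        days = (0, 3, 7, 10, 14, 17, 21, 24, 28)
        c = make_cohort([("P1", d, {}) for d in days], [("P1", 0, None)])
        windows = eligible_windows(c)
        rng = np.random.default_rng(1)
        counts = {}
        for _ in range(8000):
            pairs, _ = sample_consecutive_pairs(c, rng, windows=windows)
            counts[pairs["P1"]] = counts.get(pairs["P1"], 0) + 1
        assert len(counts) == 8
        freqs = np.array(list(counts.values())) / 8000
        assert np.all(np.abs(freqs - 1 / 8) < 0.02)
        a, _ = sample_consecutive_pairs(c, np.random.default_rng(2), windows=windows)
        b, _ = sample_consecutive_pairs(c, np.random.default_rng(2), windows=windows)
        assert a == b

    def test_both_implies_either_pointwise(self, tiny_cohort):
        windows = eligible_windows(tiny_cohort)
        pairs, _ = sample_consecutive_pairs(
            tiny_cohort, np.random.default_rng(0), windows=windows
        )
        for rule_syms in [("dyspnea",), ("dyspnea", "bendopnea")]:
            both = RuleSpec.make(rule_syms, temporal_mode="both_of_two")
            either = RuleSpec.make(rule_syms, temporal_mode="either_of_two")
            pb = apply_rule_two_day(both, pairs, tiny_cohort)
            pe = apply_rule_two_day(either, pairs, tiny_cohort)
            assert all(pe[p] for p in pb if pb[p])


class TestMonotonicity:
    def test_cutoff_and_conjunction_monotonicity(self, tiny_cohort):
        windows = eligible_windows(tiny_cohort)
        labels = tiny_cohort.labels()

        def metrics(preds):
            sens = np.mean([preds[p] for p in preds if labels[p] == 1])
            spec = np.mean([not preds[p] for p in preds if labels[p] == 0])
            return sens, spec

        rng = np.random.default_rng(11)
        for _ in range(30):
            sample = sample_random_days(tiny_cohort, rng, windows=windows)
            for cut in (2, 3, 4):
                lo = RuleSpec.make(("dyspnea",), {"dyspnea": cut})
                hi = RuleSpec.make(("dyspnea",), {"dyspnea": cut + 1})
                s_lo, p_lo = metrics(apply_rule_single_day(lo, sample, tiny_cohort))
                s_hi, p_hi = metrics(apply_rule_single_day(hi, sample, tiny_cohort))
                assert s_hi <= s_lo and p_hi >= p_lo
            small = RuleSpec.make(("dyspnea",), {"dyspnea": 3})
            big = RuleSpec.make(("dyspnea", "pnd"), {"dyspnea": 3, "pnd": 3})
            s_small, _ = metrics(apply_rule_single_day(small, sample, tiny_cohort))
            s_big, _ = metrics(apply_rule_single_day(big, sample, tiny_cohort))
            assert s_big <= s_small


class TestEvaluation:
    def test_perfectly_separated_cohort_scores_one(self, degenerate_cohort):
        rule = RuleSpec.make(("dyspnea", "orthopnea"),
                             {"dyspnea": 5, "orthopnea": 5})
        res = evaluate_rule(rule, degenerate_cohort, n_iterations=20, seed=0)
        assert np.all(res.sensitivity == 1.0)
        assert np.all(res.specificity == 1.0)
        assert res.youden_mean == pytest.approx(1.0)
        assert res.auc_mean == pytest.approx(1.0)

    def test_single_iteration_matches_hand_enumeration(self):
        c = make_cohort(
            [
                ("A", 14, {"dyspnea": 4}),  # event, window {14}
                ("B", 14, {"dyspnea": 2}),  # event, window {14}
                ("C", 0, {"dyspnea": 5}),   # non-event, single day
                ("D", 0, {"dyspnea": 1}),   # non-event, single day
            ],
            [("A", 1, 20), ("B", 1, 20), ("C", 0, None), ("D", 0, None)],
        )
        rule = RuleSpec.make(("dyspnea",), {"dyspnea": 3})
        res = evaluate_rule(rule, c, n_iterations=1, seed=0)
        # deterministic: A fires, B doesn't -> sens 1/2; C fires, D not -> spec 1/2
        assert res.sensitivity[0] == pytest.approx(0.5)
        assert res.specificity[0] == pytest.approx(0.5)
        assert res.youden[0] == pytest.approx(0.0)
        assert res.auc[0] == pytest.approx(0.5)

    def test_binary_rule_identities_per_iteration(self, tiny_cohort):
        rule = RuleSpec.make(("dyspnea", "bendopnea"))
        res = evaluate_rule(rule, tiny_cohort, n_iterations=50, seed=4)
        np.testing.assert_allclose(
            res.youden, res.sensitivity + res.specificity - 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            res.auc, (res.sensitivity + res.specificity) / 2.0, atol=1e-12
        )

    def test_monte_carlo_matches_exact_expectation(self, tiny_cohort):
        rule = RuleSpec.make(("dyspnea", "orthopnea"), temporal_mode="either_of_two")
        res = evaluate_rule(rule, tiny_cohort, n_iterations=3000, seed=8)
        sens, spec = exact_rule_means(tiny_cohort, rule)
        assert res.sensitivity_mean == pytest.approx(sens, abs=0.03)
        assert res.specificity_mean == pytest.approx(spec, abs=0.03)

    def test_fit_reproducible_from_seed(self, tiny_cohort):
        rule = RuleSpec.make(("pnd",), temporal_mode="increase")
        a = evaluate_rule(rule, tiny_cohort, n_iterations=60, seed=2)
        b = evaluate_rule(rule, tiny_cohort, n_iterations=60, seed=2)
        assert a.to_dict() == b.to_dict()


class TestRanking:
    def test_rank_by_youden_then_auc_then_name(self, tiny_cohort):
        rules = enumerate_rules(SYMPTOMS, min_size=2, max_size=3)
        evals = [
            SymptomRuleModel(tiny_cohort, r).fit(n_iterations=40, seed=i)
            for i, r in enumerate(rules)
        ]
        ranked = rank_rules(evals)
        youdens = [e.youden_mean for e in ranked]
        assert youdens == sorted(youdens, reverse=True)
        # permuting the input leaves the output order unchanged
        ranked2 = rank_rules(list(reversed(evals)))
        assert [e.rule.name for e in ranked2] == [e.rule.name for e in ranked]

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            rank_rules([])
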