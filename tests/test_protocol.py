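"""Protocol simulation: plans, trials, agents, chance levels, binomial test."""

import math

import numpy as np
import pytest

from sonoglyph import (
    Agent,
    above_chance_test,
    build_evaluation,
    build_learning_plan,
    chance_level,
    familiarity_gated,
    make_provider,
    mismapped_observer,
    random_guesser,
    reversed_preset,
    run_session,
    split_familiar_novel,
    template_observer,
    traditional_preset,
)


class OracleAgent(Agent):
    """Perfect memory: always chooses the heard stimulus."""

    def respond(self, heard_id, options, heard_sound=None):
        return heard_id


class RogueAgent(Agent):
    def respond(self, heard_id, options, heard_sound=None):
        return "not-an-option"


class TestLearningPlan:
    def test_forward_then_reverse_sequence(self, canonical_set, partition):
        plan = build_learning_plan(canonical_set, partition, seed=3)
        block = next(b for b in plan.blocks if b.group_id == "E")
        one_rep = ("E0", "E90", "E180", "E270", "E270", "E180", "E90", "E0")
        assert block.presentation_sequence == one_rep * 3

    def test_dot_group_sequence_degenerate(self, canonical_set, partition):
        plan = build_learning_plan(canonical_set, partition, seed=3)
        block = next(b for b in plan.blocks if b.group_id == "DOT")
        assert block.presentation_sequence == ("DOT0", "DOT0") * 3
        assert len(block.probe_ids) == 2

    def test_six_groups_traversed_twice(self, canonical_set, partition):
        plan = build_learning_plan(canonical_set, partition, seed=3)
        assert len(plan.group_order) == 6
        assert len(plan.blocks) == 12
        seen = [b.group_id for b in plan.blocks]
        assert seen == list(plan.group_order) * 2

    def test_first_sequences_fixed(self, canonical_set):
        for seed in range(5):
            part = split_familiar_novel(canonical_set, seed)
            plan = build_learning_plan(canonical_set, part, seed=seed)
            assert plan.group_order[:3] == ("DOT", "PP", "D")

    def test_probe_options_are_group_variants(self, canonical_set, partition):
        plan = build_learning_plan(canonical_set, partition, seed=9)
        for block in plan.blocks:
            variants = tuple(canonical_set.ids_in_group(block.group_id))
            assert block.options == variants
            assert 1 <= len(variants) <= 4
            assert set(block.probe_ids) <= set(variants)

    def test_deterministic_under_seed(self, canonical_set, partition):
        a = build_learning_plan(canonical_set, partition, seed=5)
        b = build_learning_plan(canonical_set, partition, seed=5)
        assert a == b


class TestEvaluationTrials:
    def test_canonical_trial_count(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=1)
        assert len(trials) == 78  # 39 stimuli x 2 presentations

    def test_each_stimulus_heard_twice(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=1)
        counts = {}
        for t in trials:
            counts[t.heard_id] = counts.get(t.heard_id, 0) + 1
        assert all(c == 2 for c in counts.values())
        assert len(counts) == 39

    def test_option_composition(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=4)
        fam = set(partition.familiar_ids)
        for t in trials:
            assert len(set(t.option_ids)) == 5
            assert t.heard_id in t.option_ids
            n_fam = sum(1 for o in t.option_ids if o in fam)
            # heard familiar -> 3 familiar + 2 novel options; heard novel -> 2 + 3
            assert n_fam == (3 if t.is_heard_familiar else 2)

    def test_deterministic_under_seed(self, canonical_set, partition):
        assert build_evaluation(canonical_set, partition, seed=7) == build_evaluation(
            canonical_set, partition, seed=7
        )

    def test_small_pools_rejected(self, canonical_set, partition):
        trials_kwargs = dict(n_familiar_distractors=25, n_novel_distractors=2)
        with pytest.raises(ValueError, match="pools"):
            build_evaluation(canonical_set, partition, seed=0, **trials_kwargs)


class TestRunSession:
    def test_oracle_agent_is_perfect_on_learning_probes(self, canonical_set, partition):
        plan = build_learning_plan(canonical_set, partition, seed=2)
        result = run_session(OracleAgent(), plan)
        assert result.attempt1_accuracy == 100.0
        assert len(result.trials) == 2 * len(plan.blocks)

    def test_random_agent_learning_accuracy_matches_expectation(self, canonical_set):
        # Monte-Carlo oracle: attempt-1 accuracy of a uniform guesser over
        # probes with k options has expectation mean(1/k); compare within 3 SE
        part = split_familiar_novel(canonical_set, seed=0)
        ps, correct, total = [], 0, 0
        for seed in range(300):
            plan = build_learning_plan(canonical_set, part, seed=seed)
            res = run_session(random_guesser(seed + 10_000), plan)
            correct += int(res.trials["correct"].sum())
            total += len(res.trials)
            for b in plan.blocks:
                ps.extend([1.0 / len(b.options)] * len(b.probe_ids))
        p = np.mean(ps)
        se = math.sqrt(np.sum(np.array(ps) * (1 - np.array(ps)))) / total
        assert abs(correct / total - p) < 3 * se

    def test_failed_attempts_shrink_candidate_set(self, canonical_set, partition):
        class WorstAgent(Agent):
            """Always picks the first wrong option still available."""

            def respond(self, heard_id, options, heard_sound=None):
                wrong = [o for o in options if o != heard_id]
                return wrong[0] if wrong else heard_id

        plan = build_learning_plan(canonical_set, partition, seed=2)
        res = run_session(WorstAgent(), plan)
        e_rows = res.trials[res.trials["group_id"] == "E"]
        # 4 options, 3 attempts of distinct wrong answers -> never solved
        assert (~e_rows["solved"]).all()
        assert (e_rows["attempts_used"] == 3).all()
        dot_rows = res.trials[res.trials["group_id"] == "DOT"]
        assert dot_rows["solved"].all()  # single option: forced correct

    def test_protocol_violation_detected(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=0)
        with pytest.raises(RuntimeError, match="protocol violation"):
            run_session(RogueAgent(), trials)

    def test_evaluation_record_count(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=3)
        res = run_session(random_guesser(0), trials)
        assert len(res.trials) == len(trials)
        assert res.mode == "evaluation"


class TestAgents:
    def test_familiarity_gated_stays_in_category(self, canonical_set, partition):
        trials = build_evaluation(canonical_set, partition, seed=5)
        agent = familiarity_gated(partition, seed=1)
        res = run_session(agent, trials)
        fam = set(partition.familiar_ids)
        for _, row in res.trials.iterrows():
            assert (row["choice"] in fam) == row["is_heard_familiar"]

    def test_template_observer_saturates_on_matched_mapping(self, canonical_set, partition,
                                                            trad_spec):
        trials = build_evaluation(canonical_set, partition, seed=6)
        agent = template_observer(canonical_set, trad_spec)
        res = run_session(agent, trials, make_provider(canonical_set, trad_spec))
        assert res.accuracy == 100.0
        assert res.accuracy_familiar == 100.0
        assert res.accuracy_novel == 100.0

    def test_all_pairs_distinct_for_template_observer(self, canonical_set, trad_spec):
        # exhaustive pairwise-similarity oracle: every soundscape is its own
        # unique best spectrogram match, so saturation is structural
        agent = template_observer(canonical_set, trad_spec)
        specs = {sid: agent._template(sid).ravel() for sid in canonical_set.ids}
        ids = canonical_set.ids
        mat = np.zeros((39, 39))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                va, vb = specs[a], specs[b]
                mat[i, j] = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        off = mat - np.eye(39)
        assert np.allclose(np.diag(mat), 1.0)
        assert off.max() < 1.0 - 1e-6

    def test_mismapped_observer_degrades(self, canonical_set, partition):
        agent, provider = mismapped_observer(
            canonical_set, traditional_preset(), reversed_preset()
        )
        trials = build_evaluation(canonical_set, partition, seed=8)
        res = run_session(agent, trials, provider)
        assert res.accuracy < 100.0

    def test_template_observer_requires_audio(self, canonical_set, partition, trad_spec):
        trials = build_evaluation(canonical_set, partition, seed=9)
        with pytest.raises(ValueError, match="provider"):
            run_session(template_observer(canonical_set, trad_spec), trials)


class TestChanceLevels:
    def test_uniform_five_way(self):
        assert chance_level({"all": 5}) == pytest.approx(0.20)

    def test_category_gated_third(self):
        p = chance_level({"familiar": 3, "novel": 2}, heard_category="familiar")
        assert p == pytest.approx(1 / 3)
        p = chance_level({"familiar": 2, "novel": 3}, heard_category="novel")
        assert p == pytest.approx(1 / 3)

    def test_single_option_certainty(self):
        assert chance_level({"all": 1}) == 1.0


class TestAboveChanceTest:
    def test_all_correct_closed_form(self):
        assert above_chance_test(10, 10, 0.2) == pytest.approx(0.2**10)

    def test_zero_correct_is_one(self):
        assert above_chance_test(0, 78, 0.2) == pytest.approx(1.0)

    def test_matches_binomial_summation_oracle(self):
        # direct summation of binomial terms P(X >= 30), n=78, p=0.2
        n, k, p = 78, 30, 0.2
        expected = sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
        )
        assert above_chance_test(k, n, p) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            above_chance_test(5, 4, 0.2)
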