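import numpy as np
import pandas as pd
import pytest

from spindlekit.errors import ContractError, DegenerateSignalError, ParameterError
from spindlekit.evaluation import (
    MatchCounts,
    compare_cohorts,
    interval_iou,
    iou_f1,
    macro_f1,
    match_events,
    match_events_bruteforce,
    pairwise_agreement,
    staging_consensus,
)
from spindlekit.io import Event, EventList, Hypnogram
from spindlekit.synth import RaterParams, gen_hypnogram, gen_recording, simulate_rater


def _events(pairs):
    return EventList([Event(o, d) for o, d in pairs])


class TestMacroF1:
    def test_identical_is_one(self):
        h = Hypnogram(["W", "N2", "N3", "REM", "N1"])
        assert macro_f1(h, h) == 1.0

    def test_hand_worked_example(self):
        a = ["W", "W", "N2", "N2", "REM"]
        b = ["W", "N2", "N2", "N2", "REM"]
        assert macro_f1(a, b) == pytest.approx((2 / 3 + 0.8 + 1.0) / 3)

    def test_fully_disjoint_is_zero(self):
        assert macro_f1(["W", "W"], ["N2", "N2"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            macro_f1(["W"], ["W", "N2"])

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(0)
        stages = ["W", "N1", "N2", "N3", "REM"]
        a = [stages[i] for i in rng.integers(0, 5, 200)]
        b = [stages[i] for i in rng.integers(0, 5, 200)]
        perm = {"W": "REM", "N1": "N3", "N2": "N2", "N3": "W", "REM": "N1"}
        assert macro_f1(a, b) == pytest.approx(
            macro_f1([perm[x] for x in a], [perm[x] for x in b]))

    def test_symmetric(self):
        a = ["W", "W", "N2", "N2", "REM"]
        b = ["W", "N2", "N2", "N2", "REM"]
        assert macro_f1(a, b) == macro_f1(b, a)


class TestMatchEvents:
    def test_identical_sets_all_tp(self):
        a = _events([(0, 1), (5, 1), (10, 0.5)])
        c = match_events(a, a)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_iou_above_threshold_is_tp(self):
        c = match_events(_events([(0.0, 1.0)]), _events([(0.5, 1.0)]))
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)
        assert interval_iou((0.0, 1.0), (0.5, 1.5)) == pytest.approx(1 / 3)

    def test_iou_below_threshold_is_fp_fn(self):
        c = match_events(_events([(0.0, 1.0)]), _events([(0.9, 1.0)]))
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_overlapping_within_set_rejected(self):
        with pytest.raises(ContractError):
            match_events(_events([(0, 1), (0.5, 1)]), _events([(0, 1)]))

    def test_empty_sets(self):
        c = match_events(_events([]), _events([(0, 1)]))
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_symmetry_on_rater_corpus(self):
        for s in range(30):
            hyp = gen_hypnogram(40, seed=s)
            _, truth = gen_recording(hyp, channels=["C3"], seed=s)
            a = simulate_rater(truth, RaterParams(0.85, 0.05, 0.05, 0.5),
                               seed=2 * s, hypnogram=hyp)
            b = simulate_rater(truth, RaterParams(0.8, 0.05, 0.05, 0.8),
                               seed=2 * s + 1, hypnogram=hyp)
            if len(a) + len(b) == 0:
                continue
            assert iou_f1(match_events(a, b)) == iou_f1(match_events(b, a))

    def test_max_mode_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            sets = []
            for _ in range(2):
                t = 0.0
                pairs = []
                for _ in range(rng.integers(0, 7)):
                    t += rng.uniform(0.0, 1.0)
                    d = rng.uniform(0.2, 1.5)
                    pairs.append((t, d))
                    t += d + 0.01
                sets.append(_events(pairs))
            assert match_events(*sets, mode="max").tp == \
                   match_events_bruteforce(*sets).tp


class TestIouF1:
    def test_formula(self):
        assert iou_f1(MatchCounts(2, 1, 1)) == pytest.approx(4 / 6)

    def test_perfect(self):
        assert iou_f1(MatchCounts(5, 0, 0)) == 1.0

    def test_no_hits(self):
        assert iou_f1(MatchCounts(0, 3, 2)) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(DegenerateSignalError):
            iou_f1(MatchCounts(0, 0, 0))

    def test_counts_pool_additively(self):
        a, b = MatchCounts(1, 2, 3), MatchCounts(4, 5, 6)
        assert a + b == MatchCounts(5, 7, 9)


class TestPairwiseAgreement:
    def _annotations(self, seed=0):
        rng_seeds = np.random.SeedSequence(seed).generate_state(20) % (2 ** 31)
        truth_per_block = {}
        for b in range(6):
            hyp = Hypnogram(["N2"] * 4)
            _, truth = gen_recording(hyp, channels=["C3"],
                                     seed=int(rng_seeds[b]))
            truth_per_block[f"b{b}"] = (truth, hyp)
        return truth_per_block

    def test_pairs_below_joint_block_threshold_excluded(self):
        blocks = self._annotations()
        ann = {
            "e1": {k: v[0] for k, v in blocks.items()},
            "e2": {k: v[0] for k, v in list(blocks.items())[:4]},  # 4 joint
        }
        table = pairwise_agreement(ann, min_joint_blocks=5)
        assert len(table) == 0

    def test_scorer_vs_itself_is_one(self):
        blocks = self._annotations()
        ann = {
            "e1": {k: v[0] for k, v in blocks.items()},
            "e2": {k: v[0] for k, v in blocks.items()},
        }
        table = pairwise_agreement(ann, min_joint_blocks=5)
        assert table.iou_f1.iloc[0] == 1.0

    def test_two_lossy_raters_agree_less_than_each_with_truth(self):
        blocks = self._annotations(seed=5)
        raters = {}
        for r, name in enumerate(["r1", "r2"]):
            raters[name] = {
                k: simulate_rater(v[0], RaterParams(hit_prob=0.7),
                                  seed=100 + 10 * r + i)
                for i, (k, v) in enumerate(blocks.items())
            }
        truth_ann = {"truth": {k: v[0] for k, v in blocks.items()}}
        pair = pairwise_agreement({**raters}, min_joint_blocks=5).iou_f1.iloc[0]
        vs_truth = [
            pairwise_agreement({name: raters[name], **truth_ann},
                               min_joint_blocks=5).iou_f1.iloc[0]
            for name in raters
        ]
        assert pair < min(vs_truth)


class TestConsensus:
    def test_identical_inputs(self):
        h = Hypnogram(["W", "N2", "REM"])
        assert staging_consensus([h, h, h]) == h

    def test_majority_vote(self):
        hs = [Hypnogram(["N2"]), Hypnogram(["N2"]), Hypnogram(["W"])]
        assert staging_consensus(hs).labels == ["N2"]

    def test_tie_breaks_to_lowest_index_scorer(self):
        hs = [Hypnogram(["W"]), Hypnogram(["N2"])]
        assert staging_consensus(hs).labels == ["W"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            staging_consensus([Hypnogram(["W"]), Hypnogram(["W", "N2"])])


def _cohort_frame(values, metric="density", channel="F3-A2"):
    return pd.DataFrame({
        "subject": [f"s{i}" for i in range(len(values))],
        "channel": channel, "metric": metric, "value": values,
    })


class TestCompareCohorts:
    def test_identical_groups_p_near_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = compare_cohorts(_cohort_frame(vals), _cohort_frame(vals))
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_power_at_study_scale_effect(self):
        # fast-spindle density contrast at study scale (means 3.43 vs 2.15,
        # SDs 1.70/1.46, n=25/23): analytic power ~0.80; assert a 3-sigma
        # sound lower bound over 100 seeded replications
        rng = np.random.default_rng(0)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = _cohort_frame(rng.normal(3.43, 1.70, 25))
            b = _cohort_frame(rng.normal(2.15, 1.46, 23))
            if compare_cohorts(a, b).p_value.iloc[0] < 0.05:
                hits += 1
        assert hits / reps >= 0.68

    def test_single_subject_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_cohorts(_cohort_frame([1.0]), _cohort_frame([1.0, 2.0]))

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(DegenerateSignalError):
            compare_cohorts(_cohort_frame([2.0, 2.0, 2.0]),
                            _cohort_frame([2.0, 2.0, 2.0]))

    def test_nonnormal_group_switches_to_ranksum(self):
        rng = np.random.default_rng(1)
        a = _cohort_frame(np.exp(rng.normal(0, 1.5, 30)))  # heavy-tailed
        b = _cohort_frame(rng.normal(5, 1, 30))
        out = compare_cohorts(a, b)
        assert out.test.iloc[0] == "ranksum"
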