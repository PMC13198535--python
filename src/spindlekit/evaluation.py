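"""Agreement metrics and cohort statistics.

Epoch level: the macro F1 score between two hypnograms (per-stage F1 from
the stage-wise confusion counts, averaged over the stages present in either
annotation).

Event level: two spindle annotation sets are compared by matching each event
in the first set with the temporally closest event in the second set
(midpoint distance); a matched pair counts as a true positive when the
intersection of the two intervals divided by their union exceeds the IoU
threshold (default 20%).  Counts pool additively across recordings, and the
IoU-F1 score is ``2·TP / (2·TP + FP + FN)``.

Because "temporally closest" admits corner cases, a maximum-cardinality
matching mode (``mode="max"``) and a brute-force enumeration oracle
(:func:`match_events_bruteforce`) are also provided to bound the impact of
the matching rule; the closest-match rule is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as spstats
from scipy.sparse.csgraph import maximum_bipartite_matching

from .errors import ContractError, DegenerateSignalError, ParameterError
from .io import EventList, Hypnogram, STAGES


# ---------------------------------------------------------------------------
# Epoch-level agreement
# ---------------------------------------------------------------------------

def macro_f1(hyp_a: Hypnogram | Sequence[str], hyp_b: Hypnogram | Sequence[str]) -> float:
    """Macro F1 between two equal-length stage sequences.

    Stages absent from both annotations are excluded from the average (their
    F1 would be 0/0); a stage present in only one annotation contributes an
    F1 of 0.
    """
    a = list(hyp_a.labels if isinstance(hyp_a, Hypnogram) else hyp_a)
    b = list(hyp_b.labels if isinstance(hyp_b, Hypnogram) else hyp_b)
    if len(a) != len(b):
        raise ContractError(f"hypnogram lengths differ: {len(a)} vs {len(b)}")
    a_arr, b_arr = np.array(a), np.array(b)
    f1s = []
    for stage in STAGES:
        in_a, in_b = a_arr == stage, b_arr == stage
        if not in_a.any() and not in_b.any():
            continue
        tp = int((in_a & in_b).sum())
        fp = int((in_a & ~in_b).sum())
        fn = int((~in_a & in_b).sum())
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


# ---------------------------------------------------------------------------
# Event-level matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchCounts:
    """Pooled true-positive / false-positive / false-negative counts."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ContractError("match counts must be nonnegative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn)


def interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection over union of two half-open intervals (onset, offset)."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def _check_nonoverlapping(intervals: np.ndarray, name: str) -> None:
    if len(intervals) > 1 and np.any(intervals[1:, 0] < intervals[:-1, 1] - 1e-12):
        raise ContractError(f"events in {name} overlap within the set")


def match_events(
    set_a: EventList,
    set_b: EventList,
    min_iou: float = 0.2,
    mode: str = "closest",
) -> MatchCounts:
    """Match detections (``set_a``) against a reference (``set_b``).

    ``mode="closest"`` (default): each a-event is paired with the b-event
    whose midpoint is nearest; a pair is a TP when its IoU exceeds
    ``min_iou``.  Each event participates in at most one TP; conflicting
    candidates are resolved by larger IoU, then earlier onset.

    ``mode="max"``: maximum-cardinality bipartite matching over all pairs
    exceeding the IoU threshold (upper-bounds the TP count of any one-to-one
    matching rule).
    """
    ia, ib = set_a.intervals(), set_b.intervals()
    _check_nonoverlapping(ia, "set_a")
    _check_nonoverlapping(ib, "set_b")
    na, nb = len(ia), len(ib)
    if na == 0 or nb == 0:
        return MatchCounts(tp=0, fp=na, fn=nb)

    if mode == "closest":
        mid_a = ia.mean(axis=1)
        mid_b = ib.mean(axis=1)
        candidates = []
        for i in range(na):
            dist = np.abs(mid_b - mid_a[i])
            # nearest midpoint; ties toward the earlier-onset b-event
            j = int(np.lexsort((ib[:, 0], dist))[0])
            iou = interval_iou(ia[i], ib[j])
            if iou > min_iou:
                candidates.append((iou, ia[i, 0], ib[j, 0], i, j))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        tp = 0
        for _, _, _, i, j in candidates:
            if i not in used_a and j not in used_b:
                used_a.add(i)
                used_b.add(j)
                tp += 1
    elif mode == "max":
        rows, cols = [], []
        for i in range(na):
            for j in range(nb):
                if interval_iou(ia[i], ib[j]) > min_iou:
                    rows.append(i)
                    cols.append(j)
        if rows:
            adj = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(na, nb)
            )
            matching = maximum_bipartite_matching(adj, perm_type="column")
            tp = int((matching >= 0).sum())
        else:
            tp = 0
    else:
        raise ParameterError(f"unknown matching mode {mode!r}")
    return MatchCounts(tp=tp, fp=na - tp, fn=nb - tp)


def match_events_bruteforce(set_a: EventList, set_b: EventList,
                            min_iou: float = 0.2) -> MatchCounts:
    """Exhaustive-search oracle: the maximum number of one-to-one TP pairs.

    Enumerates assignments recursively; exponential, intended for small sets
    in property tests only.
    """
    ia, ib = set_a.intervals(), set_b.intervals()
    na, nb = len(ia), len(ib)
    valid = [
        [j for j in range(nb) if interval_iou(ia[i], ib[j]) > min_iou]
        for i in range(na)
    ]

    def best(i: int, used: frozenset) -> int:
        if i == na:
            return 0
        top = best(i + 1, used)  # leave a_i unmatched
        for j in valid[i]:
            if j not in used:
                top = max(top, 1 + best(i + 1, used | {j}))
        return top

    tp = best(0, frozenset())
    return MatchCounts(tp=tp, fp=na - tp, fn=nb - tp)


def iou_f1(counts: MatchCounts | None = None, *, tp: int | None = None,
           fp: int | None = None, fn: int | None = None) -> float:
    """IoU-F1 score 2·TP / (2·TP + FP + FN) from pooled counts."""
    if counts is not None:
        tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp is None or fp is None or fn is None:
        raise ParameterError("provide MatchCounts or all of tp/fp/fn")
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise DegenerateSignalError("IoU-F1 undefined for all-zero counts")
    return 2 * tp / denom


# ---------------------------------------------------------------------------
# Inter-rater agreement tables
# ---------------------------------------------------------------------------

def pairwise_agreement(
    annotations: Mapping[str, Mapping[str, EventList]],
    min_joint_blocks: int = 5,
    min_iou: float = 0.2,
) -> pd.DataFrame:
    """Pooled pairwise IoU-F1 between scorers over jointly annotated blocks.

    ``annotations`` maps scorer id -> block id -> events for that block.
    Pairs sharing fewer than ``min_joint_blocks`` blocks are excluded.
    Returns a table with one row per qualifying (unordered) scorer pair.
    """
    scorers = list(annotations)
    rows = []
    for i, sa in enumerate(scorers):
        for sb in scorers[i + 1:]:
            joint = sorted(set(annotations[sa]) & set(annotations[sb]))
            if len(joint) < min_joint_blocks:
                continue
            counts = MatchCounts()
            for block in joint:
                counts = counts + match_events(
                    annotations[sa][block], annotations[sb][block], min_iou=min_iou
                )
            rows.append({
                "scorer_a": sa, "scorer_b": sb, "n_blocks": len(joint),
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "iou_f1": iou_f1(counts),
            })
    return pd.DataFrame(
        rows, columns=["scorer_a", "scorer_b", "n_blocks", "tp", "fp", "fn",
                       "iou_f1"]
    )


def staging_consensus(hypnograms: Sequence[Hypnogram]) -> Hypnogram:
    """Per-epoch majority vote across scorers (simplified consensus).

    Ties are broken by the stage assigned by the lowest-index scorer among
    the tied stages, which makes the output deterministic.
    """
    if len(hypnograms) < 2:
        raise ParameterError("consensus needs at least two hypnograms")
    n = len(hypnograms[0])
    if any(len(h) != n for h in hypnograms):
        raise ContractError("hypnograms must have equal length")
    labels = []
    for e in range(n):
        votes = [h.labels[e] for h in hypnograms]
        counts = {s: votes.count(s) for s in set(votes)}
        top = max(counts.values())
        tied = {s for s, c in counts.items() if c == top}
        labels.append(next(v for v in votes if v in tied))
    return Hypnogram(labels)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

def compare_cohorts(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per channel × metric two-sample comparison of subject-level values.

    Inputs are long tables with columns ``subject, channel, metric, value``
    (one row per subject per channel per metric).  The default test is
    Welch's two-sided independent t-test; when a Shapiro–Wilk pre-check at
    ``alpha_normality`` rejects normality in either group, a Wilcoxon
    two-sided rank-sum test is used instead.  Returns group means, SDs, the
    test used and the raw (uncorrected) p-value per cell.
    """
    for name, df in (("group_a", group_a), ("group_b", group_b)):
        missing = {"subject", "channel", "metric", "value"} - set(df.columns)
        if missing:
            raise ContractError(f"{name} is missing columns {sorted(missing)}")
    cells = sorted(
        set(map(tuple, group_a[["channel", "metric"]].drop_duplicates().values))
        | set(map(tuple, group_b[["channel", "metric"]].drop_duplicates().values))
    )
    rows = []
    for channel, metric in cells:
        va = group_a.query("channel == @channel and metric == @metric")["value"]
        vb = group_b.query("channel == @channel and metric == @metric")["value"]
        va, vb = va.to_numpy(float), vb.to_numpy(float)
        if len(va) < 2 or len(vb) < 2:
            raise ParameterError(
                f"{channel}/{metric}: need >= 2 subjects per group "
                f"(got {len(va)}, {len(vb)})"
            )
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            raise DegenerateSignalError(
                f"{channel}/{metric}: zero variance in both groups"
            )
        normal = True
        for v in (va, vb):
            if len(v) >= 3 and len(np.unique(v)) > 1:
                if spstats.shapiro(v).pvalue < alpha_normality:
                    normal = False
        if normal:
            test = "welch"
            p = spstats.ttest_ind(va, vb, equal_var=False).pvalue
        else:
            test = "ranksum"
            p = spstats.ranksums(va, vb).pvalue
        rows.append({
            "channel": channel, "metric": metric,
            "mean_a": va.mean(), "sd_a": va.std(ddof=1),
            "mean_b": vb.mean(), "sd_b": vb.std(ddof=1),
            "test": test, "p_value": float(p),
        })
    return pd.DataFrame(rows)
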