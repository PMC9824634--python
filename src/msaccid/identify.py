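"""Leave-one-fixation-out person identification.

For each person, four of the five fixation segments train the model
(feature scaling and, upstream, the weight vector) and the fifth is
held out.  A test-segment x person distance table is built by summing
the learned segment distance from the test segment to each of a
person's training segments.  Segments are then assigned to persons
greedily: pick the globally smallest cell, retire its row and column,
L1-normalize the remaining rows, and repeat.  The first pick uses the
raw table; normalization only enters from the second round on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EmptySegmentError, ParameterError, PersonRecord, Segment
from .features import normalize_features, segment_features
from .metric import d3, get_distance


@dataclass
class DistanceTable:
    """Test segments (rows) vs persons (columns)."""

    values: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("table must be 2-D")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ParameterError("table shape does not match labels")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ParameterError("table entries must be finite and nonnegative")


@dataclass
class Assignment:
    """Greedy assignment outcome, in pick order."""

    pairs: list = field(default_factory=list)  # (row_label, col_label)
    n_correct: int = 0


def build_distance_table(
    train: list, tests: list, w: np.ndarray, d=d3
) -> DistanceTable:
    """cell(r, c) = sum over person c's training segments of d(seg, test r).

    ``train`` holds PersonRecords (held-out fixation already removed);
    ``tests`` the held-out segments.  Feature matrices may be passed in
    place of Segment objects.
    """
    for rec in train:
        if len(rec.segments) == 0:
            raise EmptySegmentError(f"person {rec.person_id} has no train segments")
    values = np.zeros((len(tests), len(train)))
    for r, test in enumerate(tests):
        for c, rec in enumerate(train):
            values[r, c] = sum(d(seg, test, w) for seg in rec.segments)
    row_labels = [
        getattr(t, "fixation_id", "") or f"S{r + 1}" for r, t in enumerate(tests)
    ]
    rows = [getattr(t, "person_id", None) for t in tests]
    col_labels = [rec.person_id for rec in train]
    table = DistanceTable(values=values, row_labels=row_labels, col_labels=col_labels)
    table.row_truth = rows  # true owner of each test segment, if known
    return table


def greedy_assign(table: DistanceTable) -> Assignment:
    """Greedy minimum assignment with L1 row renormalization.

    Round 1 picks the global minimum of the raw table.  Each later
    round divides every remaining row by its remaining row sum before
    taking the global minimum (an all-zero row is left unnormalized).
    Ties break to the lowest row index, then lowest column index.
    """
    V = table.values
    nr, nc = V.shape
    if nr != nc:
        raise ParameterError("greedy assignment expects a square table")
    alive_r = list(range(nr))
    alive_c = list(range(nc))
    pairs = []
    first = True
    while alive_r:
        sub = V[np.ix_(alive_r, alive_c)].astype(float)
        if not first:
            sums = sub.sum(axis=1, keepdims=True)
            safe = np.where(sums == 0, 1.0, sums)  # all-zero row: leave raw
            sub = sub / safe
        # argmin scans row-major, so ties break to lowest row then column
        idx = np.unravel_index(np.argmin(sub), sub.shape)
        r, c = alive_r[idx[0]], alive_c[idx[1]]
        pairs.append((table.row_labels[r], table.col_labels[c], r, c))
        alive_r.remove(r)
        alive_c.remove(c)
        first = False
    truth = getattr(table, "row_truth", [None] * nr)
    n_correct = sum(
        1 for (_, col_label, r, _) in pairs
        if truth[r] is not None and truth[r] == col_label
    )
    return Assignment(
        pairs=[(rl, cl) for (rl, cl, _, _) in pairs], n_correct=n_correct
    )


def _renormalized_segment(seg: Segment, scales: np.ndarray):
    F = segment_features(seg) / scales
    return F


def loo_evaluate(
    cohort: list,
    held_out_fixation: str,
    w: np.ndarray,
    d=d3,
) -> tuple:
    """Split 4-train/1-test per person, build the table, assign, score.

    ``cohort`` is a list of PersonRecords whose segments carry
    ``fixation_id`` labels.  Feature scales are computed from the
    pooled training events only and applied to the test segments.
    Returns (Assignment, accuracy).
    """
    train_recs = []
    tests = []
    train_mats = []  # (person_idx, raw feature matrix) for scaling
    for rec in cohort:
        fix_ids = [s.fixation_id for s in rec.segments]
        if held_out_fixation not in fix_ids:
            raise ParameterError(
                f"person {rec.person_id} has no fixation {held_out_fixation!r}"
            )
        train_segs = [s for s in rec.segments if s.fixation_id != held_out_fixation]
        test_segs = [s for s in rec.segments if s.fixation_id == held_out_fixation]
        train_recs.append((rec.person_id, train_segs))
        tests.extend(test_segs)

    pooled = np.vstack(
        [segment_features(s) for _, segs in train_recs for s in segs]
    )
    _, _, scales = normalize_features(pooled)

    class _Rec:
        def __init__(self, pid, mats):
            self.person_id = pid
            self.segments = mats

    scaled_train = [
        _Rec(pid, [segment_features(s) / scales for s in segs])
        for pid, segs in train_recs
    ]

    class _Test:
        def __init__(self, mat, pid, fid):
            self.mat = mat
            self.person_id = pid
            self.fixation_id = fid

    scaled_tests = [
        _Test(segment_features(s) / scales, s.person_id, s.fixation_id)
        for s in tests
    ]
    table = build_distance_table(
        scaled_train, [t.mat for t in scaled_tests], w, d
    )
    table.row_labels = [f"S{i + 1}" for i in range(len(scaled_tests))]
    table.row_truth = [t.person_id for t in scaled_tests]
    assignment = greedy_assign(table)
    accuracy = assignment.n_correct / len(cohort)
    return assignment, accuracy


def cohort_to_person_records(cohort, detector: str = "velocity", **pp_kwargs):
    """Run preprocessing over a simulated cohort.

    Returns a list of PersonRecords whose segments hold detected
    events; persons/fixations yielding no events are reported as
    errors by Segment itself.
    """
    from .preprocess import build_segments, preprocess_trace

    records = []
    for person in cohort:
        segs = []
        for lt in person.traces:
            clean, intervals, _, _ = preprocess_trace(
                lt.trace, detector=detector, **pp_kwargs
            )
            segs.append(
                build_segments(
                    clean,
                    intervals,
                    person_id=person.person_id,
                    fixation_id=lt.trace.meta.get("fixation_id", ""),
                )
            )
        records.append(PersonRecord(person_id=person.person_id, segments=segs))
    return records
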