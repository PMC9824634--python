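"""Weighted distances between microsaccades, segments and persons.

A microsaccade is its 13-feature vector.  The similarity of two events
A, B is scored by a weighted form in the feature differences
``delta = P^A - P^B``:

* linear:       rho(A, B)   = sum_i w_i * delta_i^2           (13 weights)
* quasilinear:  rho_ql(A,B) = rho(A, B)
                              + sum_{i<j} w_ij * delta_i * delta_j

The full weight vector has N = 13 + C(13, 2) = 91 nonnegative entries
(unit Euclidean norm when produced by the optimizer): entries 0..12 are
the single-feature weights in canonical feature order, entries 13..90
the cross weights for i < j in lexicographic order.

Segment-level distances (a segment is a set of events):

* d1 — minimum pairwise rho over the two segments (optimistic; violates
  the triangle inequality),
* d2 — rho between the segments' feature mass centers,
* d3 — rho between trimmed mass centers (the 10% of events farthest
  from the center are discarded before re-averaging), the robust
  default.

The person distance dP is the minimum segment distance across two
persons' segments.  ``err`` is the within/between-person distance
ratio minimized during weight learning; it is invariant to rescaling
the weight vector.

The quasilinear form is indefinite for general nonnegative weights, so
its raw value can be negative; wherever a value is used *as a
distance* its magnitude is taken.  For positive-semidefinite weight
matrices — the regime in which the form really is a distance — the
magnitude coincides with the raw value.  (Clipping negatives to zero
instead would declare every event pair in the form's negative cone
"identical", an open set the weight optimizer would immediately
exploit to fake zero within-person distances.)
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import EmptySegmentError, ParameterError
from .features import N_FEATURES

N_WEIGHTS = 91
N_CROSS = 78

#: (i, j) pairs, i < j, in lexicographic order — the cross-weight layout
CROSS_PAIRS = tuple(itertools.combinations(range(N_FEATURES), 2))

_ROWS, _COLS = np.array(CROSS_PAIRS).T


def check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (N_WEIGHTS,):
        raise ParameterError(f"weight vector must have {N_WEIGHTS} entries")
    return w


def weight_matrix(w: np.ndarray) -> np.ndarray:
    """Symmetric 13x13 matrix M with rho_ql(delta) = delta' M delta."""
    w = check_weights(w)
    M = np.diag(w[:N_FEATURES]).astype(float)
    M[_ROWS, _COLS] = w[N_FEATURES:] / 2.0
    M[_COLS, _ROWS] = w[N_FEATURES:] / 2.0
    return M


def rho_linear(fA: np.ndarray, fB: np.ndarray, w13: np.ndarray) -> float:
    """Weighted sum of squared feature differences (always >= 0)."""
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    w13 = np.asarray(w13, dtype=float)
    if not (fA.shape == fB.shape == w13.shape == (N_FEATURES,)):
        raise ParameterError("rho_linear expects three 13-vectors")
    d = fA - fB
    return float(np.dot(w13, d * d))


def rho_quasilinear(
    fA: np.ndarray, fB: np.ndarray, w: np.ndarray, raw: bool = False
) -> float:
    """Linear part plus i<j cross terms.

    Returns the magnitude of the quadratic form (a nonnegative
    distance value); ``raw=True`` returns the signed value instead.
    """
    w = check_weights(w)
    d = np.asarray(fA, dtype=float) - np.asarray(fB, dtype=float)
    val = float(d @ weight_matrix(w) @ d)
    return val if raw else abs(val)


def _pairwise_rho(F1: np.ndarray, F2: np.ndarray, M: np.ndarray) -> np.ndarray:
    """|rho_ql| for every row pair of two feature matrices."""
    D = F1[:, None, :] - F2[None, :, :]
    vals = np.einsum("abi,ij,abj->ab", D, M, D)
    return np.abs(vals)


def _as_matrix(T) -> np.ndarray:
    """Accept a Segment, an (n,13) array or a list of 13-vectors."""
    if hasattr(T, "microsaccades"):
        from .features import segment_features

        return segment_features(T)
    F = np.atleast_2d(np.asarray(T, dtype=float))
    if F.shape[0] == 0 or F.shape[1] != N_FEATURES:
        raise EmptySegmentError("segment must be a non-empty (n, 13) matrix")
    return F


def d1(T1, T2, w: np.ndarray) -> float:
    """Minimum pairwise rho_ql over the cross product of events."""
    M = weight_matrix(w)
    return float(np.min(_pairwise_rho(_as_matrix(T1), _as_matrix(T2), M)))


def mass_center(T, trim: float | None = None, w: np.ndarray | None = None) -> np.ndarray:
    """Coordinate-wise mean feature vector; optionally trimmed.

    With ``trim`` in (0, 1], events are ranked by rho_ql distance to the
    untrimmed mean and only the ceil(trim * n) closest are re-averaged.
    Trimming requires the weight vector (the ranking is metric-aware).
    """
    F = _as_matrix(T)
    center = F.mean(axis=0)
    if trim is None or trim >= 1.0:
        return center
    if not 0.0 < trim <= 1.0:
        raise ParameterError("trim must be in (0, 1]")
    if w is None:
        raise ParameterError("trimmed center needs the weight vector")
    M = weight_matrix(w)
    dists = _pairwise_rho(F, center[None, :], M)[:, 0]
    keep = int(np.ceil(trim * F.shape[0]))
    order = np.argsort(dists, kind="stable")[:keep]
    return F[order].mean(axis=0)


def d2(T1, T2, w: np.ndarray) -> float:
    """rho_ql between the two segments' mass centers."""
    return rho_quasilinear(mass_center(T1), mass_center(T2), w)


def d3(T1, T2, w: np.ndarray, trim: float = 0.9) -> float:
    """rho_ql between trimmed mass centers (outlier-robust default)."""
    c1 = mass_center(T1, trim=trim, w=w)
    c2 = mass_center(T2, trim=trim, w=w)
    return rho_quasilinear(c1, c2, w)


SEGMENT_DISTANCES = {"d1": d1, "d2": d2, "d3": d3}


def get_distance(name: str):
    try:
        return SEGMENT_DISTANCES[name]
    except KeyError:
        raise ParameterError(
            f"unknown segment distance {name!r}; choose from d1, d2, d3"
        ) from None


def dP(K1, K2, w: np.ndarray, d=d3) -> float:
    """Person distance: minimum segment distance over the cross product."""
    segs1 = K1.segments if hasattr(K1, "segments") else list(K1)
    segs2 = K2.segments if hasattr(K2, "segments") else list(K2)
    if not segs1 or not segs2:
        raise EmptySegmentError("person records must contain segments")
    return min(d(a, b, w) for a in segs1 for b in segs2)


class ErrFunction:
    """Within/between-person error ratio as a callable of the weights.

    ``Err(w)`` = (sum of segment distances within each person over
    unordered segment pairs) / (sum over ordered pairs of distinct
    persons of all cross-segment distances).  Degree-0 homogeneous in
    ``w``; smaller is better.

    Precomputes the per-segment feature matrices once so repeated
    evaluation (finite-difference gradients) stays cheap.
    """

    def __init__(self, cohort, d_name: str = "d3", trim: float = 0.9):
        if len(cohort) < 2:
            raise ParameterError("Err needs at least 2 persons")
        self.d_name = d_name
        self.trim = trim
        self.persons = []
        for rec in cohort:
            segs = rec.segments if hasattr(rec, "segments") else list(rec)
            mats = [_as_matrix(s) for s in segs]
            if len(mats) < 2:
                raise ParameterError("Err needs >= 2 segments per person")
            self.persons.append(mats)

    def _centers(self, M: np.ndarray) -> list:
        out = []
        for mats in self.persons:
            cs = []
            for F in mats:
                c = F.mean(axis=0)
                if self.d_name == "d3" and self.trim < 1.0:
                    dist = _pairwise_rho(F, c[None, :], M)[:, 0]
                    keep = int(np.ceil(self.trim * F.shape[0]))
                    order = np.argsort(dist, kind="stable")[:keep]
                    c = F[order].mean(axis=0)
                cs.append(c)
            out.append(np.vstack(cs))
        return out

    def __call__(self, w: np.ndarray) -> float:
        M = weight_matrix(w)
        P = len(self.persons)
        if self.d_name in ("d2", "d3"):
            centers = self._centers(M)
            num = 0.0
            den = 0.0
            for i in range(P):
                R = _pairwise_rho(centers[i], centers[i], M)
                num += np.sum(np.triu(R, k=1))
                for k in range(P):
                    if k != i:
                        den += np.sum(_pairwise_rho(centers[i], centers[k], M))
        else:  # d1
            num = 0.0
            den = 0.0
            for i in range(P):
                mats = self.persons[i]
                for j1 in range(len(mats)):
                    for j2 in range(j1 + 1, len(mats)):
                        num += np.min(_pairwise_rho(mats[j1], mats[j2], M))
                for k in range(P):
                    if k == i:
                        continue
                    for F1 in mats:
                        for F2 in self.persons[k]:
                            den += np.min(_pairwise_rho(F1, F2, M))
        if den == 0.0:
            raise ParameterError("degenerate cohort: zero between-person distance")
        return num / den


def err(w: np.ndarray, cohort, d_name: str = "d3", trim: float = 0.9) -> float:
    """One-shot Err evaluation (see :class:`ErrFunction`)."""
    return ErrFunction(cohort, d_name=d_name, trim=trim)(w)


def between_person_matrix(cohort, w: np.ndarray, d=d3) -> np.ndarray:
    """F[i, k]: mean cross-segment distance between persons i and k."""
    recs = list(cohort)
    P = len(recs)
    F = np.zeros((P, P))
    for i in range(P):
        for k in range(P):
            segs_i = recs[i].segments if hasattr(recs[i], "segments") else recs[i]
            segs_k = recs[k].segments if hasattr(recs[k], "segments") else recs[k]
            vals = [d(a, b, w) for a in segs_i for b in segs_k]
            F[i, k] = float(np.mean(vals))
    return F
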