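"""The 13 microsaccade trajectory parameters.

Each detected microsaccade is an ordered run of gaze points (degrees,
fixed 1 ms spacing at 1 kHz).  It is summarised by a fixed-order
13-vector:

====  ===========================  =========
idx   feature                      units
====  ===========================  =========
P1    duration                     ms
P2    height H                     deg
P3    area S                       deg^2
P4    sharpness Sr = H/S           1/deg
P5    base length                  deg
P6    double ratio = base/duration deg/ms
P7    double flag (ratio < 0.01)   0/1
P8    average speed v_av           deg/ms
P9    windowed max speed, W=11     deg/ms
P10   windowed max speed, W=21     deg/ms
P11   average pseudo-acceleration  deg/ms^2
P12   mean of top-10 |accel|       deg/ms^2
P13   maximal diameter D_max       deg
====  ===========================  =========

The area treats the trajectory as an implicitly closed curve; when the
curve crosses itself it is split at the crossing points into simple
loops and the absolute loop areas are summed.

Velocities are first differences of position (deg per sample, i.e.
deg/ms at 1 kHz); pseudo-accelerations are first differences of the
speed magnitude.  The mono/double threshold 0.01 applies to the
base-length/duration ratio in deg/ms.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist

from .core import Microsaccade, ParameterError

FEATURE_NAMES = (
    "duration_ms",
    "height_deg",
    "area_deg2",
    "sharpness",
    "base_length_deg",
    "double_ratio",
    "double_flag",
    "avg_speed",
    "max_speed_w11",
    "max_speed_w21",
    "avg_accel",
    "max_accel_top10",
    "max_diameter_deg",
)

N_FEATURES = 13

#: mono/double threshold on base_length / duration (deg/ms)
DOUBLE_THRESHOLD = 0.01

_EPS_AREA = 1e-12


# ---------------------------------------------------------------------------
# scalar features
# ---------------------------------------------------------------------------

def duration(ms: Microsaccade) -> float:
    """Duration in milliseconds: (n - 1) sample intervals.

    A 50-point event at 1 kHz lasts 49 ms.
    """
    return (ms.n - 1) * ms.dt_ms


def base_length(ms: Microsaccade) -> float:
    """Euclidean distance between the first and last points (deg)."""
    return float(np.linalg.norm(ms.points[-1] - ms.points[0]))


def height(ms: Microsaccade) -> float:
    """Maximum distance of interior points from the chord (deg).

    The chord is the infinite line through the first and last points.
    When the event is a closed loop (zero base length) the chord
    degenerates and the height falls back to the maximum distance of
    interior points from the start point.  Events with no interior
    points (n = 2) have height 0.
    """
    p = ms.points
    if p.shape[0] < 3:
        return 0.0
    a, b = p[0], p[-1]
    interior = p[1:-1]
    base = np.linalg.norm(b - a)
    if base > 0:
        # |cross| / base == 2 * triangle area / base (Heron-equivalent)
        cross = (b[0] - a[0]) * (interior[:, 1] - a[1]) - (b[1] - a[1]) * (
            interior[:, 0] - a[0]
        )
        return float(np.max(np.abs(cross)) / base)
    return float(np.max(np.linalg.norm(interior - a, axis=1)))


def height_heron(ms: Microsaccade) -> float:
    """Height via the triangle-perimeter (Heron) form, 2*area/base.

    Numerically equivalent to :func:`height`; kept as the literal
    semi-perimeter formulation.  Tiny negative radicands from floating
    point are clamped at zero.
    """
    p = ms.points
    if p.shape[0] < 3:
        return 0.0
    a, b = p[0], p[-1]
    interior = p[1:-1]
    base = np.linalg.norm(b - a)
    if base == 0:
        return float(np.max(np.linalg.norm(interior - a, axis=1)))
    da = np.linalg.norm(interior - a, axis=1)
    db = np.linalg.norm(interior - b, axis=1)
    s = (da + db + base) / 2.0
    rad = np.clip(s * (s - da) * (s - db) * (s - base), 0.0, None)
    return float(np.max(2.0 * np.sqrt(rad) / base))


class Crossing(NamedTuple):
    """A self-intersection between edges k->k+1 and l->l+1."""

    k: int
    l: int
    lam: float
    mu: float
    point: tuple


def _segment_pair_crossing(a0, a1, b0, b1):
    """Solve a0 + lam*(a1-a0) = b0 + mu*(b1-b0); None if parallel/outside."""
    d1 = a1 - a0
    d2 = b1 - b0
    det = d1[0] * (-d2[1]) - (-d2[0]) * d1[1]
    if abs(det) < 1e-300:
        return None  # parallel (non-invertible matrix)
    rhs = b0 - a0
    lam = (rhs[0] * (-d2[1]) - (-d2[0]) * rhs[1]) / det
    mu = (d1[0] * rhs[1] - rhs[0] * d1[1]) / det
    if 0.0 <= lam <= 1.0 and 0.0 <= mu <= 1.0:
        pt = a0 + lam * d1
        return lam, mu, (float(pt[0]), float(pt[1]))
    return None


def self_intersections(ms: Microsaccade, closed: bool = False) -> list:
    """All crossings between non-adjacent edges of the polyline.

    Edges k and l qualify when they do not share an endpoint
    (l not in {k-1, k, k+1}; with ``closed`` the wrap-around adjacency
    is excluded too).  For each qualifying pair the 2x2 linear system
    for the edge parameters (lam, mu) is solved; a crossing is reported
    iff the matrix is invertible and both parameters lie in [0, 1].
    """
    pts = ms.points
    if closed and not np.array_equal(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    m = pts.shape[0] - 1  # number of edges
    out = []
    for k in range(m):
        for l in range(k + 2, m):
            if closed and k == 0 and l == m - 1:
                continue  # wrap-around neighbours share a vertex
            hit = _segment_pair_crossing(pts[k], pts[k + 1], pts[l], pts[l + 1])
            if hit is not None:
                lam, mu, pt = hit
                out.append(Crossing(k, l, lam, mu, pt))
    return out


def _shoelace(points: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon (first != last ok)."""
    x = points[:, 0]
    y = points[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def area(ms: Microsaccade) -> float:
    """Trajectory area in deg^2, summing simple loops of the closed curve.

    The trajectory is implicitly closed (an edge from the last point
    back to the first is appended).  A simple curve gets the absolute
    shoelace area.  A self-crossing curve is split at its crossing
    points: walking along the curve, every time a crossing point is met
    for the second time the loop between its two occurrences is a
    simple polygon whose absolute area is accumulated and whose points
    are removed from the walk; the remainder after all loop removals
    contributes its absolute area.

    For the shapes this models (simple curves, out-and-back
    figure-eights, isolated crossings) the result equals the sum of the
    planar-arrangement face areas.  In fully interleaved crossing
    patterns (a pentagram) a region wound several times is counted once
    per covering loop.
    """
    if ms.n < 3:
        return 0.0
    pts = ms.points
    if np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        return 0.0
    closed = Microsaccade(np.vstack([pts, pts[0]]), dt_ms=ms.dt_ms)
    crossings = self_intersections(closed, closed=False)
    # drop crossings created only by the closure-edge adjacency wrap
    m = pts.shape[0]  # edges of the closed polygon: 0..m-1
    crossings = [c for c in crossings if not (c.k == 0 and c.l == m - 1)]
    if not crossings:
        return _shoelace(pts)

    # augment the vertex walk with crossing points (each appears twice)
    on_edge: dict = {}
    for cid, c in enumerate(crossings):
        on_edge.setdefault(c.k, []).append((c.lam, cid))
        on_edge.setdefault(c.l, []).append((c.mu, cid))
    walk_pts = []  # (x, y)
    walk_ids = []  # crossing id or None for original vertices
    for e in range(m):
        walk_pts.append(tuple(pts[e]))
        walk_ids.append(None)
        for t, cid in sorted(on_edge.get(e, [])):
            p = crossings[cid].point
            walk_pts.append(p)
            walk_ids.append(cid)

    total = 0.0
    seen: dict = {}
    i = 0
    while i < len(walk_ids):
        cid = walk_ids[i]
        if cid is not None and cid in seen:
            j = seen[cid]
            loop = np.array(walk_pts[j:i], dtype=float)
            if loop.shape[0] >= 3:
                total += _shoelace(loop)
            # excise the loop, keep one occurrence of the crossing point
            del walk_pts[j + 1 : i + 1]
            del walk_ids[j + 1 : i + 1]
            seen = {c: idx for c, idx in seen.items() if idx <= j}
            i = j + 1
            continue
        if cid is not None:
            seen[cid] = i
        i += 1
    rem = np.array(walk_pts, dtype=float)
    if rem.shape[0] >= 3:
        total += _shoelace(rem)
    return total


def sharpness(H: float, S: float) -> float:
    """Sr = H / S; 0 when the area is degenerate (S below 1e-12)."""
    if H < 0 or S < 0:
        raise ParameterError("height and area must be nonnegative")
    if S < _EPS_AREA:
        return 0.0
    return H / S


def double_classify(base: float, dur: float) -> tuple:
    """(ratio, flag): flag = 1 (double) iff base/duration < 0.01 deg/ms.

    A ratio exactly at the threshold classifies as mono.
    """
    if dur <= 0:
        raise ParameterError("duration must be positive")
    ratio = base / dur
    return ratio, (1 if ratio < DOUBLE_THRESHOLD else 0)


def speed_profile(ms: Microsaccade) -> tuple:
    """(v, v_av, v_max11, v_max21) in deg/ms.

    v_i is the i-th step displacement magnitude per millisecond; v_av
    its mean; v_maxW the maximum over all full W-length sliding windows
    of the window-mean speed, falling back to v_av when fewer than W
    speeds exist.
    """
    steps = np.diff(ms.points, axis=0)
    v = np.linalg.norm(steps, axis=1) / ms.dt_ms
    v_av = float(np.mean(v))

    def windowed_max(w: int) -> float:
        if len(v) < w:
            return v_av
        csum = np.concatenate([[0.0], np.cumsum(v)])
        means = (csum[w:] - csum[:-w]) / w
        return float(np.max(means))

    return v, v_av, windowed_max(11), windowed_max(21)


def accel_profile(v: np.ndarray) -> tuple:
    """(A_av, A_max10) from a speed sequence, in deg/ms^2.

    a_i = v_{i+1} - v_i (signed).  A_av is the signed mean; A_max10 the
    mean of the 10 largest magnitudes (all magnitudes when fewer than
    10 exist).  With fewer than 2 speeds both are 0.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        return 0.0, 0.0
    a = np.diff(v)
    A_av = float(np.mean(a))
    mags = np.sort(np.abs(a))[::-1]
    A_max10 = float(np.mean(mags[: min(10, len(mags))]))
    return A_av, A_max10


def max_diameter(ms: Microsaccade) -> float:
    """Maximum pairwise point distance D_max (deg)."""
    if ms.n == 2:
        return base_length(ms)
    return float(np.max(pdist(ms.points)))


# ---------------------------------------------------------------------------
# assembly and normalization
# ---------------------------------------------------------------------------

def extract_features(ms: Microsaccade) -> np.ndarray:
    """The canonical 13-vector P1..P13 for one microsaccade."""
    dur = duration(ms)
    H = height(ms)
    S = area(ms)
    Sr = sharpness(H, S)
    base = base_length(ms)
    ratio, flag = double_classify(base, dur)
    _v, v_av, v11, v21 = speed_profile(ms)
    A_av, A_max10 = accel_profile(_v)
    dmax = max_diameter(ms)
    return np.array(
        [dur, H, S, Sr, base, ratio, float(flag), v_av, v11, v21, A_av, A_max10, dmax]
    )


def segment_features(segment) -> np.ndarray:
    """(n_events, 13) feature matrix for all events of a segment."""
    return np.vstack([extract_features(m) for m in segment.microsaccades])


def normalize_features(
    train: np.ndarray, others: np.ndarray | None = None
) -> tuple:
    """Unit-vector normalization: scale each column by its Euclidean norm.

    Scales are computed on the training rows only and applied
    unchanged to ``others`` (held-out data must not influence the
    scaling).  An all-zero column keeps scale 1.

    Returns (scaled_train, scaled_others_or_None, scales).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] == 0:
        raise ParameterError("train set must be non-empty")
    scales = np.linalg.norm(train, axis=0)
    scales = np.where(scales == 0, 1.0, scales)
    scaled_train = train / scales
    scaled_others = None
    if others is not None:
        scaled_others = np.atleast_2d(np.asarray(others, dtype=float)) / scales
    return scaled_train, scaled_others, scales
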