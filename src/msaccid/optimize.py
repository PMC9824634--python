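"""Weight learning: projected steepest descent on the error ratio.

The search minimizes the scale-invariant within/between error ratio
over the 91-dimensional weight simplex {w >= 0, ||w|| = 1}.  Because
the objective contains min operators and trimming it is only piecewise
smooth; the numeric gradient (central finite differences, one-sided at
the nonnegativity boundary) combined with a strict-decrease line
search is robust to the kinks.

Two line-search modes are provided:

* ``halving`` — try steps 1, 1/2, 1/4, ... along the negative gradient
  until the objective strictly decreases;
* ``crawl``   — the default: crawl forward in multiples of a small
  adaptive step (capped at ``xi``) while the objective keeps
  decreasing, probing one extra step past the last win.  The small
  capped steps keep each iteration local, matching the "compute the
  gradient rarely, control the step tightly" design, and make far
  fewer gradient evaluations per unit progress than unit-scale jumps.

After every step negative components are zeroed and the vector is
renormalized to unit Euclidean norm (free, since the objective is
degree-0 homogeneous).  The search stops when the iterate displacement
falls below ``tol``.  Multi-start runs the descent from several random
unit vectors and keeps the smallest final objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError
from .metric import N_WEIGHTS


@dataclass
class OptResult:
    """Outcome of one descent run."""

    w_star: np.ndarray
    err_star: float
    trajectory: list = field(default_factory=list)  # (iteration, err)
    seed: int | None = None
    n_gradient_evals: int = 0


def random_start(seed: int) -> np.ndarray:
    """Uniform(0,1)^91 draw scaled to the unit sphere; deterministic per seed."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, N_WEIGHTS)
    return w / np.linalg.norm(w)


def project(w: np.ndarray) -> np.ndarray:
    """Zero the negative components, then renormalize to unit norm."""
    w = np.asarray(w, dtype=float)
    w = np.where(w < 0, 0.0, w)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ParameterError("projection collapsed the vector to zero")
    return w / norm


def numeric_gradient(errfn, w: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite differences; one-sided where a negative probe would
    leave the feasible region (w_i - h < 0)."""
    if h <= 0:
        raise ParameterError("step h must be positive")
    w = np.asarray(w, dtype=float)
    g = np.zeros_like(w)
    f0 = None
    for i in range(len(w)):
        e = np.zeros_like(w)
        e[i] = h
        if w[i] - h < 0:
            if f0 is None:
                f0 = errfn(w)
            g[i] = (errfn(w + e) - f0) / h
        else:
            g[i] = (errfn(w + e) - errfn(w - e)) / (2.0 * h)
    return g


def descend(
    errfn,
    w0: np.ndarray,
    mode: str = "crawl",
    tol: float = 1e-6,
    xi: float = 1e-3,
    max_iter: int = 500,
    h: float = 1e-4,
    max_halvings: int = 40,
    seed: int | None = None,
) -> OptResult:
    """Projected steepest descent from ``w0``; objective non-increasing."""
    if mode not in ("halving", "crawl"):
        raise ParameterError("mode must be 'halving' or 'crawl'")
    if tol <= 0 or xi <= 0:
        raise ParameterError("tol and xi must be positive")
    w = project(np.asarray(w0, dtype=float))
    f = errfn(w)
    traj = [(0, f)]
    n_grad = 0
    crawl_step = xi
    for it in range(1, max_iter + 1):
        g = numeric_gradient(errfn, w, h=h)
        n_grad += 1
        direction = -g
        if not np.any(direction):
            break
        w_new, f_new = None, None
        if mode == "halving":
            k = 1.0
            for _ in range(max_halvings):
                cand = w + k * direction
                try:
                    cand = project(cand)
                except ParameterError:
                    k /= 2.0
                    continue
                fc = errfn(cand)
                if fc < f:
                    w_new, f_new = cand, fc
                    break
                k /= 2.0
        else:  # crawl: small capped steps, crawling forward while decreasing
            unit = direction / max(np.linalg.norm(direction), 1e-300)
            s = crawl_step  # adaptive step length, never exceeding xi
            for _ in range(max_halvings):
                try:
                    cand = project(w + s * unit)
                except ParameterError:
                    s /= 2.0
                    continue
                fc = errfn(cand)
                if fc < f:
                    break
                s /= 2.0
            else:
                cand = None
            if cand is not None:
                best, best_f, l = cand, fc, 1
                while l < 10_000:
                    try:
                        nxt = project(w + (l + 1) * s * unit)
                    except ParameterError:
                        break
                    fn = errfn(nxt)
                    if fn < best_f:  # one extra probe past the last win
                        best, best_f, l = nxt, fn, l + 1
                    else:
                        break
                w_new, f_new = best, best_f
                crawl_step = min(xi, 2.0 * s)
        if w_new is None:
            break  # no decreasing step: local minimum
        displacement = np.linalg.norm(w - w_new)
        w, f = w_new, f_new
        traj.append((it, f))
        if displacement < tol:
            break
    return OptResult(
        w_star=w, err_star=f, trajectory=traj, seed=seed, n_gradient_evals=n_grad
    )


def multi_start(
    errfn,
    n_starts: int = 30,
    base_seed: int = 0,
    mode: str = "crawl",
    **descend_kwargs,
) -> tuple:
    """Run ``descend`` from ``n_starts`` seeded random starts.

    Returns (best OptResult, list of all OptResults); seeds are
    ``base_seed + run_index``.
    """
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    results = []
    for i in range(n_starts):
        seed = base_seed + i
        w0 = random_start(seed)
        results.append(descend(errfn, w0, mode=mode, seed=seed, **descend_kwargs))
    best = min(results, key=lambda r: r.err_star)
    return best, results
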