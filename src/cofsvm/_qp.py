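"""Dual quadratic-programming solvers for the fuzzy SVM family.

All machines in this package reduce to the same dual template:

    minimise    f(a) = 1/2 a' Q a - p' a,      Q = (y y') * K
    subject to  y' a = 0,   0 <= a_k <= c_k,

where ``K`` is a kernel Gram matrix over the constraint rows, ``y`` the
constraint signs, ``p`` the linear margin targets (all ones for a plain
soft-margin machine; mixed-class band constraints contribute rows with
``p = -1``) and ``c`` the per-row box caps (membership times penalty).

:func:`solve_svm_dual` is a sequential-minimal-optimisation solver with
maximal-violating-pair working-set selection — exact pairwise line searches
with an incrementally maintained gradient, terminating on the KKT gap.
:func:`projected_gradient_dual` is a deliberately simple projected-gradient
solver for small problems; it shares nothing with the SMO path beyond the
problem statement and serves as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DualSolution", "solve_svm_dual", "projected_gradient_dual"]


@dataclass
class DualSolution:
    alpha: np.ndarray
    offset: float
    gap: float
    n_iter: int
    converged: bool


def _offset_from_kkt(
    K: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    alpha: np.ndarray,
    ridge: float,
) -> float:
    """Recover the bias: average over margin rows (0 < a < c); if none are
    free, the midpoint of the interval the boundary rows leave feasible."""
    u = K @ (alpha * y)
    free = (alpha > ridge) & (alpha < c - ridge)
    if free.any():
        # y (u + h) = p  =>  h = y p - u  (y in {-1, +1})
        return float(np.mean(y[free] * p[free] - u[free]))
    at_zero = alpha <= ridge
    at_cap = alpha >= c - ridge
    lowers, uppers = [], []
    pos, neg = y > 0, y < 0
    # a = 0 needs y (u + h) >= p ; a = c needs y (u + h) <= p
    lo_mask = (at_zero & pos) | (at_cap & neg)
    hi_mask = (at_zero & neg) | (at_cap & pos)
    if lo_mask.any():
        lowers.append(np.max(y[lo_mask] * p[lo_mask] - u[lo_mask]))
    if hi_mask.any():
        uppers.append(np.min(y[hi_mask] * p[hi_mask] - u[hi_mask]))
    if lowers and uppers:
        return float((max(lowers) + min(uppers)) / 2.0)
    if lowers:
        return float(max(lowers))
    if uppers:
        return float(min(uppers))
    return 0.0


def _refine_free_set(
    Q: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    alpha: np.ndarray,
    g: np.ndarray,
    eps_box: float,
) -> bool:
    """Acceleration step: minimise the quadratic over the currently free
    variables within the equality-constraint null space by projected
    conjugate gradients, truncating any step at the box boundary.  The
    pairwise updates locate the active set quickly but crawl inside a
    nearly singular free block; this subspace jump removes that tail.
    Returns True if alpha moved (the caller must refresh the gradient)."""
    free = (alpha > eps_box) & (alpha < c - eps_box)
    nf = int(free.sum())
    if nf < 2:
        return False
    idx = np.flatnonzero(free)
    Qff = Q[np.ix_(idx, idx)]
    yf = y[idx]
    gf = g[idx]

    def project(v: np.ndarray) -> np.ndarray:
        return v - yf * (float(yf @ v) / nf)

    lo = -alpha[idx]
    hi = c[idx] - alpha[idx]
    x = np.zeros(nf)
    res = project(-gf)
    res_sq = float(res @ res)
    if res_sq < 1e-24:
        return False
    d = res.copy()
    for _ in range(min(2 * nf, 200)):
        Ad = project(Qff @ d)
        curv = float(d @ Ad)
        if curv <= 1e-14 * float(d @ d):
            # flat or negative curvature: ride the ray to the box
            step = _max_feasible(x, d, lo, hi)
            if np.isfinite(step) and step > 0:
                x = x + step * d
            break
        a = res_sq / curv
        step = min(a, _max_feasible(x, d, lo, hi))
        x = x + step * d
        if step < a:
            break
        res = res - a * Ad
        new_sq = float(res @ res)
        if new_sq < 1e-24:
            break
        d = res + (new_sq / res_sq) * d
        res_sq = new_sq
    decrease = float(gf @ x) + 0.5 * float(x @ Qff @ x)
    if decrease >= -1e-15 or not np.all(np.isfinite(x)):
        return False
    alpha[idx] = np.clip(alpha[idx] + x, 0.0, c[idx])
    return True


def _max_feasible(x: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Largest t >= 0 with lo <= x + t d <= hi (x feasible)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        room = np.where(d > 0, (hi - x) / d, np.where(d < 0, (lo - x) / d, np.inf))
    t = float(np.min(room))
    return max(t, 0.0)


def solve_svm_dual(
    K: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500_000,
) -> DualSolution:
    """SMO with second-order working-set selection.

    Starts from the feasible point ``a = 0`` and updates one pair per
    iteration along the equality-constraint manifold, clipping the exact
    line-search step to the box.  Every few hundred iterations a
    Newton-style refinement solves the free-variable subproblem exactly,
    which removes the slow tail of pairwise updates.  Terminates when the
    maximal KKT violation (the ``m - M`` gap) falls below ``tol``.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(y)
    if K.shape != (n, n) or p.shape != (n,) or c.shape != (n,):
        raise ValueError("inconsistent dual problem shapes")
    if np.any(c < 0):
        raise ValueError("box caps must be nonnegative")

    Q = K * np.outer(y, y)
    diagK = np.diag(K).copy()
    alpha = np.zeros(n)
    g = -p.copy()  # gradient of f at alpha
    eps_box = 1e-12 * max(1.0, float(c.max(initial=0.0)))

    gap = np.inf
    converged = False
    refine_period = max(200, n // 2)
    it = 0
    for it in range(1, max_iter + 1):
        if it % refine_period == 0 and _refine_free_set(Q, y, p, c, alpha, g, eps_box):
            g = Q @ alpha - p
        F = -y * g
        up = ((y > 0) & (alpha < c - eps_box)) | ((y < 0) & (alpha > eps_box))
        low = ((y < 0) & (alpha < c - eps_box)) | ((y > 0) & (alpha > eps_box))
        if not up.any() or not low.any():
            gap = 0.0
            converged = True
            break
        Fi = np.where(up, F, -np.inf)
        i = int(Fi.argmax())
        gap = float(F[i] - np.where(low, F, np.inf).min())
        if gap <= tol:
            converged = True
            break
        # second-order selection: partner with the largest objective decrease
        diff = F[i] - F
        cand = low & (diff > 0)
        curv = np.maximum(K[i, i] + diagK - 2.0 * K[i, :], 1e-12)
        score = np.where(cand, diff * diff / curv, -np.inf)
        j = int(score.argmax())
        delta = float(diff[j]) / curv[j]
        # box limits for a step (alpha_i += y_i d, alpha_j -= y_j d, d > 0)
        lim_i = (c[i] - alpha[i]) if y[i] > 0 else alpha[i]
        lim_j = alpha[j] if y[j] > 0 else (c[j] - alpha[j])
        delta = min(delta, lim_i, lim_j)
        if delta <= 0:  # pragma: no cover - numerical corner
            break
        di = y[i] * delta
        dj = -y[j] * delta
        alpha[i] += di
        alpha[j] += dj
        g += Q[:, i] * di + Q[:, j] * dj

    ridge = 1e-8 * max(1.0, float(c.max(initial=0.0)))
    offset = _offset_from_kkt(K, y, p, c, alpha, ridge)
    return DualSolution(alpha=alpha, offset=offset, gap=gap, n_iter=it, converged=converged)


def _project_box_hyperplane(v: np.ndarray, y: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact Euclidean projection of ``v`` onto {0 <= a <= c, y'a = 0}.

    The projection is ``clip(v - nu y, 0, c)`` for the multiplier ``nu``
    solving ``y' clip(v - nu y, 0, c) = 0`` — a monotone piecewise-linear
    equation whose root is located on the sorted clip breakpoints and solved
    linearly within the bracketing segment."""

    def clipped(nu: float) -> np.ndarray:
        return np.clip(v - nu * y, 0.0, c)

    bps = np.sort(np.concatenate([v / y, (v - c) / y]))
    res = np.array([float(y @ clipped(b)) for b in bps])
    if res[0] <= 0.0:
        return clipped(bps[0])
    if res[-1] >= 0.0:
        return clipped(bps[-1])
    k = int(np.searchsorted(-res, 0.0, side="left")) - 1
    k = max(0, min(k, len(bps) - 2))
    r0, r1 = res[k], res[k + 1]
    nu = bps[k] if r0 == r1 else bps[k] + (bps[k + 1] - bps[k]) * r0 / (r0 - r1)
    return clipped(nu)


def projected_gradient_dual(
    K: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    c: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 30_000,
) -> np.ndarray:
    """Accelerated projected gradient on the same dual; reference solver.

    Nesterov momentum with gradient restart, a fixed 1/L step (L the top
    eigenvalue of Q) and the exact projection onto the box-plus-hyperplane
    feasible set.  Intended for small problems (tens of rows) where its
    simplicity makes it a trusted oracle; it is not used on any production
    path.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    Q = K * np.outer(y, y)
    L = float(np.linalg.eigvalsh(Q)[-1])
    step = 1.0 / max(L, 1e-12)
    alpha = np.zeros(len(y))
    mom = alpha.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = Q @ mom - p
        new = _project_box_hyperplane(mom - step * grad, y, c)
        move = new - alpha
        if float(grad @ move) > 0.0:  # restart momentum when it overshoots
            t = 1.0
            mom = new
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            mom = new + ((t - 1.0) / t_next) * move
            t = t_next
        if float(np.abs(move).max()) < tol:
            alpha = new
            break
        alpha = new
    return alpha
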