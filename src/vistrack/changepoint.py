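"""Exact penalised changepoint detection on speed series.

A behavioural transition (freeze, flight, head turn) shows up as a shift
in the mean of one or more speed-quantile channels.  Segmentation
minimises the penalised cost

    sum_{i=1..m+1} C(y_{tau_{i-1}+1 : tau_i}) + beta m

where C is the within-segment sum of squared deviations from the
segment mean and beta the per-changepoint penalty.  The global optimum
is found with the PELT dynamic programme (pruned exact linear time).
Because no single beta suits every dataset, the CROPS recursion
enumerates every optimal segmentation over a penalty interval
[beta_min, beta_max]; the resulting count-vs-penalty curve m(beta) has
an elbow ("knee") marking the transition from under- to over-fitting,
located by fitting the two-line model

    E[m] = a beta + b (beta - psi)_+ + c

with Muggeo's iterative linearisation.  The per-trial knees yield the
study-level penalty (their median).

Changepoint convention: a changepoint is the LAST index of a segment,
0-based; the final index n-1 is never a changepoint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segmentation",
    "PenaltyPath",
    "KneeFit",
    "PooledChangepoints",
    "segment_cost",
    "pelt_segment",
    "exhaustive_segment",
    "crops_path",
    "fit_knee",
    "choose_penalty",
    "pool_changepoints",
    "default_beta_range",
]


@dataclass(frozen=True)
class Segmentation:
    changepoints: tuple[int, ...]  # last index of each non-final segment
    total_cost: float  # value of the penalised objective
    beta: float
    n: int

    @property
    def m(self) -> int:
        return len(self.changepoints)

    @property
    def unpenalised_cost(self) -> float:
        return self.total_cost - self.beta * self.m

    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) index ranges of each segment."""
        bounds = [0, *[c + 1 for c in self.changepoints], self.n]
        return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class PenaltyPath:
    """CROPS output: intervals of beta sharing one optimal segmentation."""

    intervals: list[tuple[float, float, Segmentation]]
    beta_range: tuple[float, float]

    def segmentation_at(self, beta: float) -> Segmentation:
        lo, hi = self.beta_range
        if not lo <= beta <= hi:
            raise ValueError("beta outside the explored range")
        for b0, b1, seg in self.intervals:
            if b0 <= beta < b1 or (beta == b1 == hi):
                return Segmentation(
                    seg.changepoints, seg.unpenalised_cost + beta * seg.m, beta, seg.n
                )
        raise AssertionError("intervals should cover the range")

    def support_points(
        self, n_grid: int = 101, include_boundaries: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(beta, m) support for knee fitting.

        By default m(beta) is evaluated on a uniform penalty grid through
        the path (exact, since the path covers the range), matching how
        the count-vs-penalty curve is drawn.  Sampling at the interval
        boundaries instead (``include_boundaries`` with ``n_grid=0``)
        concentrates the support in the over-fitting arm, where optimal
        segmentations change fastest, and biases the knee fit low.
        """
        betas: list[float] = []
        if n_grid > 0:
            betas.extend(np.linspace(self.beta_range[0], self.beta_range[1], n_grid))
        if include_boundaries or n_grid <= 0:
            for b0, b1, _ in self.intervals:
                betas.extend([b0, 0.5 * (b0 + b1)])
            betas.append(self.beta_range[1])
        betas = np.unique(np.asarray(betas, float))
        ms = np.array([self.segmentation_at(b).m for b in betas], float)
        return betas, ms


@dataclass
class KneeFit:
    a: float  # slope of the left line (changepoints per unit beta)
    b: float  # difference in slopes between right and left line
    c: float  # intercept
    psi: float  # knee location, penalty units
    converged: bool
    iterations: int
    degenerate: bool = False  # no detectable knee (b ~ 0)

    def predict(self, beta: np.ndarray) -> np.ndarray:
        beta = np.asarray(beta, float)
        return self.a * beta + self.b * np.maximum(beta - self.psi, 0.0) + self.c


@dataclass
class PooledChangepoints:
    counts: np.ndarray  # per frame: how many channels change there

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# --------------------------------------------------------------------------
# costs
# --------------------------------------------------------------------------


class _Prefix:
    """Prefix sums of y and y^2 for O(1) segment costs."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, float)
        if y.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if not np.all(np.isfinite(y)):
            raise ValueError("series contains non-finite values")
        self.n = len(y)
        self.s1 = np.concatenate([[0.0], np.cumsum(y)])
        self.s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(self, start, stop):
        """Sum of squared deviations from the mean on [start, stop)."""
        length = stop - start
        s = self.s1[stop] - self.s1[start]
        ss = self.s2[stop] - self.s2[start]
        return np.maximum(ss - s * s / length, 0.0)


def segment_cost(series: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squares over the inclusive range [i, j]."""
    pre = _Prefix(series)
    if not 0 <= i <= j < pre.n:
        raise ValueError("need 0 <= i <= j < n")
    return float(pre.cost(i, j + 1))


# --------------------------------------------------------------------------
# PELT
# --------------------------------------------------------------------------


def pelt_segment(
    series: np.ndarray, beta: float, min_seg: int = 1
) -> Segmentation:
    """Exact minimiser of the penalised cost via the PELT dynamic programme.

    F(t) is the optimal cost of the first t points; candidate previous
    changepoints s are pruned once F(s) + C(s, t) > F(t), which cannot
    exclude the optimum because the within-segment sum of squares is
    subadditive under splitting (pruning constant 0).
    """
    if beta < 0 or not math.isfinite(beta):
        raise ValueError("beta must be finite and >= 0")
    if min_seg < 1:
        raise ValueError("min_seg must be >= 1")
    pre = _Prefix(series)
    n = pre.n
    if n < 2 * min_seg:
        raise ValueError("series shorter than two minimal segments")

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    cands = np.array([0], dtype=int)
    for t in range(min_seg, n + 1):
        adm = cands[cands <= t - min_seg]
        vals = F[adm] + pre.cost(adm, t) + beta
        k = int(np.argmin(vals))
        F[t] = vals[k]
        last[t] = adm[k]
        keep = (F[cands] + pre.cost(cands, t) <= F[t]) | (cands > t - min_seg)
        cands = cands[keep]
        if t >= min_seg and t <= n - min_seg:
            cands = np.append(cands, t)

    cps = []
    s = last[n]
    while s > 0:
        cps.append(s - 1)
        s = last[s]
    cps.reverse()
    return Segmentation(tuple(cps), float(F[n]), float(beta), n)


_EXHAUSTIVE_CACHE: dict[tuple[bytes, int], list[tuple[int, tuple[int, ...], float]]] = {}


def _exhaustive_best_per_m(series: np.ndarray, min_seg: int):
    """For each changepoint count m, the best (unpenalised cost, tau).

    The enumeration does not depend on the penalty, so it is cached per
    series; a given beta then only needs a minimum over m.
    """
    y = np.ascontiguousarray(series, dtype=float)
    key = (y.tobytes(), min_seg)
    hit = _EXHAUSTIVE_CACHE.get(key)
    if hit is not None:
        return hit
    pre = _Prefix(y)
    n = pre.n
    positions = np.arange(min_seg - 1, n - min_seg)
    best: list[tuple[int, tuple[int, ...], float]] = [(0, (), float(pre.cost(0, n)))]
    max_m = (n // min_seg) - 1
    for m in range(1, max(len(positions), 0) + 1):
        if m > max_m:
            break
        combos = np.array(list(itertools.combinations(positions, m)), dtype=int)
        if combos.size == 0:
            continue
        if min_seg > 1 and m > 1:
            ok = (np.diff(combos, axis=1) >= min_seg).all(axis=1)
            combos = combos[ok]
            if len(combos) == 0:
                continue
        starts = np.concatenate([np.zeros((len(combos), 1), int), combos + 1], axis=1)
        stops = np.concatenate([combos + 1, np.full((len(combos), 1), n)], axis=1)
        costs = pre.cost(starts, stops).sum(axis=1)
        k = int(np.argmin(costs))
        # lexicographic tie-break within equal-cost combos of the same m
        ties = np.flatnonzero(np.abs(costs - costs[k]) <= 1e-12)
        if len(ties) > 1:
            k = ties[np.lexsort(combos[ties].T[::-1])[0]]
        best.append((m, tuple(int(c) for c in combos[k]), float(costs[k])))
    if len(_EXHAUSTIVE_CACHE) > 64:
        _EXHAUSTIVE_CACHE.clear()
    _EXHAUSTIVE_CACHE[key] = best
    return best


def exhaustive_segment(series: np.ndarray, beta: float, min_seg: int = 1) -> Segmentation:
    """Brute-force optimum by enumerating every admissible changepoint set.

    Independent test oracle for :func:`pelt_segment`; refuses n > 25.
    Ties are broken toward fewer changepoints, then lexicographically
    smaller changepoint tuples.
    """
    y = np.asarray(series, float)
    n = len(y)
    if n > 25:
        raise ValueError("exhaustive enumeration limited to n <= 25")
    if n < 2 * min_seg:
        raise ValueError("series shorter than two minimal segments")
    best_tau: tuple[int, ...] = ()
    best_cost = np.inf
    for m, tau, cost in _exhaustive_best_per_m(y, min_seg):
        total = cost + beta * m
        if total < best_cost - 1e-12:  # ties resolve toward fewer changepoints
            best_cost, best_tau = total, tau
    return Segmentation(best_tau, float(best_cost), float(beta), n)


# --------------------------------------------------------------------------
# CROPS
# --------------------------------------------------------------------------


def crops_path(
    series: np.ndarray,
    beta_min: float,
    beta_max: float,
    min_seg: int = 1,
) -> PenaltyPath:
    """All optimal segmentations over a penalty interval (CROPS recursion).

    Two penalties are solved at the interval ends; whenever the
    changepoint counts differ by more than one, the interval is split at
    the penalty where the two segmentations' penalised costs cross,

        beta* = (Q(seg_hi) - Q(seg_lo)) / (m_lo - m_hi),

    with Q the unpenalised cost; recursion stops when no intermediate
    segmentation can exist.  The collected segmentations' lower cost
    envelope Q + beta m then yields exact intervals of optimality.
    """
    if not (0 <= beta_min < beta_max) or not math.isfinite(beta_max):
        raise ValueError("need 0 <= beta_min < beta_max, finite")
    found: dict[tuple[int, ...], Segmentation] = {}

    def solve(beta: float) -> Segmentation:
        seg = pelt_segment(series, beta, min_seg)
        prev = found.get(seg.changepoints)
        if prev is None or seg.unpenalised_cost < prev.unpenalised_cost:
            found[seg.changepoints] = seg
        return seg

    def recurse(b0: float, s0: Segmentation, b1: float, s1: Segmentation) -> None:
        if s0.m <= s1.m + 1:
            return
        b_star = (s1.unpenalised_cost - s0.unpenalised_cost) / (s0.m - s1.m)
        if not (b0 < b_star < b1):
            return
        s_mid = solve(b_star)
        if s_mid.m == s1.m:
            return  # b_star is the exact exchange point; nothing in between
        recurse(b0, s0, b_star, s_mid)
        recurse(b_star, s_mid, b1, s1)

    s_lo = solve(beta_min)
    s_hi = solve(beta_max)
    recurse(beta_min, s_lo, beta_max, s_hi)

    # lower envelope of the lines Q + beta*m over [beta_min, beta_max]
    lines: dict[int, Segmentation] = {}
    for seg in found.values():
        cur = lines.get(seg.m)
        if cur is None or seg.unpenalised_cost < cur.unpenalised_cost:
            lines[seg.m] = seg
    segs = sorted(lines.values(), key=lambda s: s.m, reverse=True)

    intervals: list[tuple[float, float, Segmentation]] = []
    beta = beta_min
    # best line at beta: minimal Q + beta*m, ties toward fewer changepoints
    def best_at(b: float) -> Segmentation:
        vals = [(s.unpenalised_cost + b * s.m, s.m) for s in segs]
        k = min(range(len(segs)), key=lambda i: (round_tol(vals[i][0]), vals[i][1]))
        return segs[k]

    def round_tol(v: float) -> float:
        return v  # ties resolved by the m key; exact float compare suffices

    cur = best_at(beta_min)
    while True:
        # next crossing with a line of strictly smaller slope (fewer cps)
        next_beta, next_seg = beta_max, None
        for s in segs:
            if s.m >= cur.m:
                continue
            cross = (s.unpenalised_cost - cur.unpenalised_cost) / (cur.m - s.m)
            if beta < cross < next_beta:
                next_beta, next_seg = cross, s
            elif cross <= beta and (
                s.unpenalised_cost + beta * s.m
                <= cur.unpenalised_cost + beta * cur.m
            ):
                # already dominated at current beta; switch immediately
                next_beta, next_seg = beta, s
        if next_seg is None:
            intervals.append((beta, beta_max, cur))
            break
        if next_beta > beta:
            intervals.append((beta, next_beta, cur))
        beta, cur = next_beta, next_seg
    return PenaltyPath(intervals=intervals, beta_range=(beta_min, beta_max))


def default_beta_range(series: np.ndarray, low_factor: float = 0.1) -> tuple[float, float]:
    """Data-driven penalty interval for CROPS.

    The lower end scales with a robust (median-absolute-deviation based)
    estimate of the noise variance -- well below any meaningful penalty
    -- and the upper end with n times the series variance, above which
    no changepoint survives.
    """
    y = np.asarray(series, float)
    sigma = np.median(np.abs(np.diff(y))) / (0.6745 * math.sqrt(2.0))
    low = max(low_factor * sigma**2, 1e-8)
    high = max(len(y) * float(np.var(y)), low * 10.0)
    return low, high


# --------------------------------------------------------------------------
# knee
# --------------------------------------------------------------------------


def fit_knee(
    path_or_points: PenaltyPath | tuple[np.ndarray, np.ndarray],
    psi0: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> KneeFit:
    """Fit the two-line knee model to (beta, m) by Muggeo's iteration.

    Each iteration fits the linear model with regressors beta,
    (beta - psi)_+ and the indicator -1{beta > psi}; the indicator
    coefficient over the slope-difference coefficient is the first-order
    correction to psi.  Iteration stops when |d psi| < tol.  A
    slope-difference near zero means the data are a single line and is
    flagged degenerate rather than raised.
    """
    if isinstance(path_or_points, PenaltyPath):
        beta, m = path_or_points.support_points()
    else:
        beta, m = (np.asarray(a, float) for a in path_or_points)
    if len(np.unique(beta)) < 4:
        raise ValueError("need >= 4 distinct (beta, m) support points")
    psi = float(np.median(beta)) if psi0 is None else float(psi0)
    lo, hi = float(beta.min()), float(beta.max())
    a_ = b_ = c_ = 0.0
    converged = False
    degenerate = False
    it = 0
    m_scale = max(float(np.ptp(m)), 1.0)
    beta_scale = max(hi - lo, 1e-12)

    def sse_at(p: float) -> float:
        X = np.column_stack([np.ones_like(beta), beta, np.maximum(beta - p, 0.0)])
        r = m - X @ np.linalg.lstsq(X, m, rcond=None)[0]
        return float(r @ r)

    best_psi, best_sse = psi, sse_at(psi)
    stalled = 0
    for it in range(1, max_iter + 1):
        U = np.maximum(beta - psi, 0.0)
        V = -(beta > psi).astype(float)
        X = np.column_stack([np.ones_like(beta), beta, U, V])
        coef, *_ = np.linalg.lstsq(X, m, rcond=None)
        c_, a_, b_, gamma = (float(v) for v in coef)
        if abs(b_) < 1e-8 * m_scale / beta_scale:
            degenerate = True
            break
        step = gamma / b_
        psi_new = float(np.clip(psi + step, lo, hi))
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        sse_new = sse_at(psi_new)
        if sse_new < best_sse - 1e-12:
            best_psi, best_sse = psi_new, sse_new
            stalled = 0
        else:
            # the iteration oscillates around the optimum; settle on the
            # best objective value seen so far
            stalled += 1
            if stalled >= 3:
                psi = best_psi
                converged = True
                break
        psi = psi_new
    if converged or degenerate:
        # final clean fit at the settled psi (drops the indicator column)
        U = np.maximum(beta - psi, 0.0)
        X = np.column_stack([np.ones_like(beta), beta, U])
        coef, *_ = np.linalg.lstsq(X, m, rcond=None)
        c_, a_, b_ = (float(v) for v in coef)
        if degenerate:
            b_ = 0.0
    return KneeFit(
        a=a_, b=b_, c=c_, psi=psi, converged=converged, iterations=it, degenerate=degenerate
    )


def choose_penalty(knees: list[float]) -> float:
    """Study-level penalty: the median of the per-trial knee locations."""
    if len(knees) == 0:
        raise ValueError("need at least one knee value")
    return float(np.median(np.asarray(knees, float)))


def pool_changepoints(per_channel: list[Segmentation], n_frames: int) -> PooledChangepoints:
    """Per-frame count of channels that place a changepoint at that frame."""
    counts = np.zeros(n_frames, dtype=int)
    for seg in per_channel:
        for tau in seg.changepoints:
            if not 0 <= tau < n_frames:
                raise ValueError("changepoint outside [0, n_frames)")
            counts[tau] += 1
    return PooledChangepoints(counts=counts)
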