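"""Change-points in mean by exact penalized least-squares segmentation.

The series is segmented to minimize

    sum over segments of SSE(segment) / sigma^2  +  penalty * (#change points)

subject to a minimum segment length (default 10 years), where SSE is the
segment's sum of squared deviations from its own mean and sigma^2 is a
difference-based robust estimate of the within-segment noise variance (so
the penalty is scale-free).  The optimum is found by an O(n^2) dynamic
programme — exact, not a heuristic — with ties broken in favour of fewer
change points, then lexicographically earliest ones.  A combinatorial
brute-force enumerator over all feasible segmentations serves as an
independent oracle for short series.

Penalty presets: "MBIC" (3 log n, the default), "BIC" (2 log n), or any
nonnegative number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangePointSet",
    "penalty_value",
    "detect_mean_shifts",
    "brute_force_segment",
    "segmentation_cost",
    "changepoints_batch",
]

_TIE_TOL = 1e-9


@dataclass
class ChangePointSet:
    """Optimal mean-shift segmentation of one series.

    ``changepoints`` holds the first year (or index, if no year axis was
    given) of each new segment; every induced segment, including the first
    and last, has length >= ``min_seg_len``.
    """

    series_id: tuple | None
    changepoints: list
    min_seg_len: int
    penalty: str | float
    penalty_value: float
    cost: float

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)


def penalty_value(penalty, n: int) -> float:
    if isinstance(penalty, str):
        name = penalty.upper()
        if name == "MBIC":
            return 3.0 * np.log(n)
        if name == "BIC":
            return 2.0 * np.log(n)
        raise ValueError(f"unknown penalty {penalty!r}; expected 'MBIC', 'BIC' or a number")
    beta = float(penalty)
    if beta < 0:
        raise ValueError("penalty must be nonnegative")
    return beta


def _noise_variance(x: np.ndarray) -> float:
    """Difference-based variance estimate, robust to a few mean shifts:
    MAD of first differences, falling back to their mean square."""
    if len(x) < 2:
        return 1.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    var = (mad / 0.6744897501960817) ** 2 / 2.0
    if var <= 0:
        var = float(np.mean(d**2)) / 2.0
    if var <= 0:
        var = 1.0
    return var


class _SegmentCost:
    """O(1) segment SSE/sigma^2 via prefix sums; segments are [s, e) indices."""

    def __init__(self, x: np.ndarray):
        self.var = _noise_variance(x)
        self.c1 = np.concatenate([[0.0], np.cumsum(x)])
        self.c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def __call__(self, s: int, e: int) -> float:
        n = e - s
        s1 = self.c1[e] - self.c1[s]
        s2 = self.c2[e] - self.c2[s]
        return max(s2 - s1 * s1 / n, 0.0) / self.var


def _validate(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("values contain non-finite entries")
    return x


def _to_years(breaks: list[int], years) -> list:
    if years is None:
        return list(breaks)
    years = np.asarray(years)
    return [int(years[b]) for b in breaks]


def detect_mean_shifts(
    values,
    min_seg_len: int = 10,
    penalty="MBIC",
    years=None,
    series_id=None,
) -> ChangePointSet:
    """Exact optimal mean-shift segmentation (dynamic programme over all
    admissible last-segment starts); deterministic, with ties resolved to
    fewer and earlier change points."""
    x = _validate(values)
    if min_seg_len < 1:
        raise ValueError("min_seg_len must be >= 1")
    n = len(x)
    beta = penalty_value(penalty, n)
    cost = _SegmentCost(x)
    L = min_seg_len

    # best[j]: (cost, n_cp, breaks tuple) for x[0:j]; j ranges over feasible ends
    INF = float("inf")
    best: list[tuple[float, int, tuple]] = [(INF, 0, ())] * (n + 1)
    best[0] = (0.0, -1, ())  # -1 so the first segment adds no penalty
    for j in range(L, n + 1):
        cand = None
        for s in range(0, j - L + 1):
            if s != 0 and best[s][0] == INF:
                continue
            if s != 0 and s < L:
                continue
            prev_cost, prev_ncp, prev_breaks = best[s]
            c = prev_cost + cost(s, j) + beta
            breaks = prev_breaks + (s,) if s != 0 else ()
            trial = (c, prev_ncp + 1, breaks)
            if cand is None or _better(trial, cand):
                cand = trial
        if cand is not None:
            best[j] = cand
    total, _, breaks = best[n]
    if total == INF:  # series shorter than one segment: trivially unsegmented
        penalized, breaks = cost(0, n), ()
    else:
        penalized = total - beta  # the DP charges beta per segment, not per change point
    return ChangePointSet(
        series_id=series_id,
        changepoints=_to_years(list(breaks), years),
        min_seg_len=min_seg_len,
        penalty=penalty,
        penalty_value=beta,
        cost=float(penalized),
    )


def _better(a: tuple[float, int, tuple], b: tuple[float, int, tuple]) -> bool:
    """Cost first (tolerance _TIE_TOL), then fewer change points, then
    lexicographically earliest break positions."""
    if a[0] < b[0] - _TIE_TOL:
        return True
    if a[0] > b[0] + _TIE_TOL:
        return False
    return (a[1], a[2]) < (b[1], b[2])


def brute_force_segment(
    values,
    min_seg_len: int = 10,
    penalty="MBIC",
    years=None,
    series_id=None,
) -> ChangePointSet:
    """Exhaustive enumeration of every feasible segmentation (test oracle);
    refuses series longer than 40 points."""
    x = _validate(values)
    n = len(x)
    if n > 40:
        raise ValueError("brute force capped at length 40")
    if min_seg_len < 1:
        raise ValueError("min_seg_len must be >= 1")
    beta = penalty_value(penalty, n)
    cost = _SegmentCost(x)
    L = min_seg_len

    best: tuple[float, int, tuple] | None = None

    def recurse(start: int, acc_cost: float, breaks: tuple):
        nonlocal best
        if n - start >= L:  # close the final segment here
            trial = (acc_cost + cost(start, n), len(breaks), breaks)
            if best is None or _better(trial, best):
                best = trial
        for b in range(start + L, n - L + 1):
            recurse(b, acc_cost + cost(start, b) + beta, breaks + (b,))

    recurse(0, 0.0, ())
    if best is None:  # infeasible to form even one segment (n < L)
        best = (cost(0, n), 0, ())
    total, _, breaks = best
    return ChangePointSet(
        series_id=series_id,
        changepoints=_to_years(list(breaks), years),
        min_seg_len=min_seg_len,
        penalty=penalty,
        penalty_value=beta,
        cost=float(total),
    )


def segmentation_cost(cps: ChangePointSet, values, years=None) -> float:
    """Penalized cost of an arbitrary ChangePointSet on ``values`` (shared
    normalization), for cross-checking optimality claims."""
    x = _validate(values)
    cost = _SegmentCost(x)
    if years is not None:
        years = np.asarray(years)
        breaks = [int(np.searchsorted(years, y)) for y in cps.changepoints]
    else:
        breaks = list(cps.changepoints)
    edges = [0] + breaks + [len(x)]
    return float(
        sum(cost(s, e) for s, e in zip(edges[:-1], edges[1:]))
        + cps.penalty_value * len(breaks)
    )


def changepoints_batch(
    novelty_series_list,
    min_seg_len: int = 10,
    penalty="MBIC",
) -> list[ChangePointSet]:
    """Apply the same detection settings to every novelty series."""
    out = []
    for series in novelty_series_list:
        out.append(
            detect_mean_shifts(
                series.values,
                min_seg_len=min_seg_len,
                penalty=penalty,
                years=series.years,
                series_id=series.series_id,
            )
        )
    return out
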