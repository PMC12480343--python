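"""Ecological network analysis indices on food-web flow matrices.

Implements the three whole-system information indices used as adaptive-cycle
dimensions — ascendency A (connectedness), development capacity C (potential)
and overhead R (resilience) — plus total system throughput (TST), from a
nonnegative flow matrix T with T[i, j] the flow from compartment i to j.

With log base b (bits when b = 2) and the convention 0*log 0 := 0:

    TST = sum_ij T_ij
    A   = sum_ij T_ij * log_b( T_ij * TST / (T_i. * T_.j) )
    C   = -sum_ij T_ij * log_b( T_ij / TST )
    R   = -sum_ij T_ij * log_b( T_ij^2 / (T_i. * T_.j) )

where T_i. and T_.j are row (donor) and column (recipient) sums.  A is TST
times the mutual information of the flow-normalized joint distribution, C is
TST times its Shannon entropy (the theoretical maximum of A), and the
identity C = A + R holds for every nonnegative matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowNetwork",
    "IndexSeries",
    "total_system_throughput",
    "ascendency",
    "capacity",
    "overhead",
    "smooth_series",
    "index_series",
]


@dataclass
class FlowNetwork:
    """One year's food-web as a square nonnegative flow matrix (t/km2/yr)."""

    compartments: list[str]
    T: np.ndarray
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        n = len(self.compartments)
        if self.T.shape != (n, n):
            raise ValueError(f"flow matrix shape {self.T.shape} does not match {n} compartments")
        if np.any(self.T < 0):
            raise ValueError("flow matrix has negative entries")
        if not self.log_base > 0:
            raise ValueError("log_base must be positive")


def total_system_throughput(net: FlowNetwork) -> float:
    """Sum of all flows (TST)."""
    return float(net.T.sum())


def _prepare(net: FlowNetwork):
    tst = net.T.sum()
    if tst <= 0:
        raise ValueError("all-zero flow matrix: indices are undefined (TST = 0)")
    row = net.T.sum(axis=1)   # donor totals T_i.
    col = net.T.sum(axis=0)   # recipient totals T_.j
    mask = net.T > 0
    return tst, row, col, mask, np.log(net.log_base)


def ascendency(net: FlowNetwork) -> float:
    """A = sum T_ij log(T_ij TST / (T_i. T_.j)): throughput-scaled mutual information."""
    tst, row, col, m, ln_b = _prepare(net)
    t = net.T[m]
    terms = t * np.log(t * tst / (np.outer(row, col)[m])) / ln_b
    total = terms.sum()
    return float(total) if total > 0 else 0.0


def capacity(net: FlowNetwork) -> float:
    """C = -sum T_ij log(T_ij / TST): throughput-scaled flow diversity,
    the theoretical maximum of ascendency."""
    tst, _, _, m, ln_b = _prepare(net)
    t = net.T[m]
    total = -(t * np.log(t / tst)).sum() / ln_b
    return float(total) if total > 0 else 0.0


def overhead(net: FlowNetwork) -> float:
    """R = -sum T_ij log(T_ij^2 / (T_i. T_.j)): unconstrained flow diversity
    (functional redundancy); equals C - A."""
    tst, row, col, m, ln_b = _prepare(net)
    t = net.T[m]
    terms = -t * np.log(t * t / (np.outer(row, col)[m])) / ln_b
    total = terms.sum()
    return float(total) if total > 0 else 0.0


# --------------------------------------------------------------------------
# smoothing


def smooth_series(values, span: float = 0.75, x=None) -> np.ndarray:
    """Local quadratic regression (LOESS, tricube weights) evaluated at the
    observed points.

    ``span`` is the fraction of points in each local window (default 0.75,
    the usual plotting default).  Fewer than 3 points are returned unchanged
    with a warning.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if n < 3:
        warnings.warn("fewer than 3 points: smoothing is an identity pass-through")
        return y.copy()
    xs = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    k = min(n, max(int(np.ceil(span * n)), 4))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xc = xs[idx] - xs[i]
        if np.count_nonzero(w > 0) < 3 or len(np.unique(xc[w > 0])) < 3:
            out[i] = np.average(y[idx], weights=np.maximum(w, 1e-12))
            continue
        coef = np.polyfit(xc, y[idx], 2, w=np.sqrt(w))
        out[i] = coef[-1]  # fitted value at xc = 0
    return out


@dataclass
class IndexSeries:
    """Per-year ENA indices (raw and smoothed) for one scenario."""

    years: np.ndarray
    tst: np.ndarray
    ascendency: np.ndarray
    capacity: np.ndarray
    overhead: np.ndarray
    ascendency_smoothed: np.ndarray
    capacity_smoothed: np.ndarray
    overhead_smoothed: np.ndarray
    scenario: object = None
    log_base: float = 2.0
    span: float = 0.75


def index_series(flows_by_year, scenario=None, log_base: float = 2.0, span: float = 0.75) -> IndexSeries:
    """Compute A, C, R and TST per year from a mapping year -> FlowNetwork
    (or year -> list of member FlowNetworks, averaged entrywise first), with
    LOESS-smoothed companions of each index.
    """
    if not flows_by_year:
        raise ValueError("no flow networks supplied")
    years = np.array(sorted(flows_by_year), dtype=int)
    nets = []
    for year in years:
        item = flows_by_year[year]
        if isinstance(item, FlowNetwork):
            net = FlowNetwork(item.compartments, item.T, log_base)
        else:  # ensemble: average member matrices before index computation
            members = list(item)
            T = np.mean([m.T for m in members], axis=0)
            net = FlowNetwork(members[0].compartments, T, log_base)
        nets.append(net)
    a = np.array([ascendency(n) for n in nets])
    c = np.array([capacity(n) for n in nets])
    r = np.array([overhead(n) for n in nets])
    tst = np.array([total_system_throughput(n) for n in nets])
    if len(years) >= 3:
        sm = lambda v: smooth_series(v, span=span, x=years.astype(float))
    else:
        sm = lambda v: v.copy()
    return IndexSeries(
        years=years, tst=tst, ascendency=a, capacity=c, overhead=r,
        ascendency_smoothed=sm(a), capacity_smoothed=sm(c), overhead_smoothed=sm(r),
        scenario=scenario, log_base=log_base, span=span,
    )
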