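"""Adaptive-cycle phase classification from ENA index trends.

The adaptive cycle describes complex-system dynamics as a loop of growth /
exploitation (r), conservation (K), collapse / release (Omega) and
reorganization (alpha), along the three dimensions connectedness, potential
and resilience — mapped here onto smoothed ascendency, capacity and overhead.

Reorganization onsets are anchored quantitatively at novelty change points
whose local index trends match the reorganization signature (connectedness
falling, potential rising, resilience high); collapse is carved immediately
before each anchor while its signature holds (connectedness and potential
falling, resilience rising); remaining years are growth (r/K merged) when
connectedness and potential rise and resilience falls, else unclassified.
The cycle count is the number of reorganization segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ena import IndexSeries, smooth_series

__all__ = [
    "PHASES",
    "PhaseParams",
    "TrendSignature",
    "PhaseSegment",
    "PhaseSegmentation",
    "trend_signature",
    "anchor_reorganization",
    "classify_phases",
    "phase_durations",
    "phase_schedule_indices",
]

PHASES = ("growth_rK", "collapse", "reorganization", "unclassified")

GROWTH, COLLAPSE, REORG, UNCLASSIFIED = PHASES


@dataclass(frozen=True)
class PhaseParams:
    """Tunables of the phase classifier.

    ``trend_window``: years in the centered slope window (truncated at the
    edges).  ``epsilon_iqr_frac``: a slope flatter than this fraction of the
    index's interquartile range per year counts as zero.  ``resilience_quantile``:
    resilience is "high" at years where smoothed overhead is at or above this
    quantile of its values over the analysis window.  ``min_reorg_years``:
    shortest reorganization segment emitted.
    """

    trend_window: int = 7
    epsilon_iqr_frac: float = 0.01
    resilience_quantile: float = 0.5
    min_reorg_years: int = 3


@dataclass(frozen=True)
class TrendSignature:
    year: int
    connectedness_slope: float   # smoothed ascendency
    potential_slope: float       # smoothed capacity
    resilience_slope: float      # smoothed overhead
    resilience_level: str        # "high" | "low"


def _epsilon(values: np.ndarray, frac: float) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return frac * float(q75 - q25)


def _window_slope(years: np.ndarray, values: np.ndarray, i: int, window: int) -> float:
    half = window // 2
    lo, hi = max(0, i - half), min(len(years), i + half + 1)
    if hi - lo < 2:
        return 0.0
    x = years[lo:hi].astype(float)
    y = values[lo:hi]
    return float(np.polyfit(x, y, 1)[0])


def _zero_if_flat(slope: float, eps: float) -> float:
    return 0.0 if abs(slope) < eps else slope


def _resilience_threshold(indices: IndexSeries, params: PhaseParams, mask=None) -> float:
    r = indices.overhead_smoothed if mask is None else indices.overhead_smoothed[mask]
    return float(np.quantile(r, params.resilience_quantile))


def trend_signature(
    indices: IndexSeries,
    year: int,
    window: int = 7,
    epsilon: float | None = None,
    params: PhaseParams | None = None,
) -> TrendSignature:
    """Local least-squares slopes of the three smoothed indices in a centered
    window around ``year``, with sub-epsilon slopes set to zero, plus the
    resilience level relative to the window median."""
    params = params or PhaseParams(trend_window=window)
    years = indices.years
    pos = np.flatnonzero(years == year)
    if len(pos) == 0:
        raise ValueError(f"year {year} outside index series")
    i = int(pos[0])
    sigs = []
    for values in (indices.ascendency_smoothed, indices.capacity_smoothed, indices.overhead_smoothed):
        eps = _epsilon(values, params.epsilon_iqr_frac) if epsilon is None else epsilon
        sigs.append(_zero_if_flat(_window_slope(years, values, i, params.trend_window), eps))
    high = indices.overhead_smoothed[i] >= _resilience_threshold(indices, params)
    return TrendSignature(
        year=int(year),
        connectedness_slope=sigs[0],
        potential_slope=sigs[1],
        resilience_slope=sigs[2],
        resilience_level="high" if high else "low",
    )


def _signature_arrays(indices: IndexSeries, params: PhaseParams, mask: np.ndarray):
    """Per-year zeroed slopes and resilience level over the analysis window."""
    years = indices.years
    out = []
    for values in (indices.ascendency_smoothed, indices.capacity_smoothed, indices.overhead_smoothed):
        eps = _epsilon(values[mask], params.epsilon_iqr_frac)
        sl = np.array([_window_slope(years, values, i, params.trend_window) for i in range(len(years))])
        sl[np.abs(sl) < eps] = 0.0
        out.append(sl)
    sl_a, sl_c, sl_r = out
    high = indices.overhead_smoothed >= _resilience_threshold(indices, params, mask)
    return sl_a, sl_c, sl_r, high


def anchor_reorganization(
    changepoints,
    indices: IndexSeries,
    params: PhaseParams | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Filter change-point years by the reorganization signature.

    A change point is anchored as a reorganization onset iff at that year the
    connectedness slope is negative, the potential slope positive, and
    resilience high.  Returns (anchored years, [(year, failing condition)]).
    """
    params = params or PhaseParams()
    years = indices.years
    mask = _analysis_mask(years, window)
    sl_a, sl_c, _, high = _signature_arrays(indices, params, mask)
    cp_years = getattr(changepoints, "changepoints", changepoints)
    anchored, rejected = [], []
    for y in cp_years:
        pos = np.flatnonzero(years == y)
        if len(pos) == 0:
            rejected.append((int(y), "outside index series"))
            continue
        i = int(pos[0])
        if sl_a[i] >= 0:
            rejected.append((int(y), "connectedness not falling"))
        elif sl_c[i] <= 0:
            rejected.append((int(y), "potential not rising"))
        elif not high[i]:
            rejected.append((int(y), "resilience not high"))
        else:
            anchored.append(int(y))
    return anchored, rejected


@dataclass(frozen=True)
class PhaseSegment:
    start_year: int
    end_year: int  # inclusive
    phase: str

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass
class PhaseSegmentation:
    scenario: object
    segments: list[PhaseSegment]
    cycle_count: int
    anchors: list[int]
    window: tuple[int, int]


def _analysis_mask(years: np.ndarray, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return np.ones(len(years), dtype=bool)
    mask = (years >= window[0]) & (years <= window[1])
    if not mask.any():
        raise ValueError(f"analysis window {window} contains no index years")
    return mask


def classify_phases(
    indices: IndexSeries,
    anchors,
    params: PhaseParams | None = None,
    window: tuple[int, int] | None = None,
    scenario=None,
) -> PhaseSegmentation:
    """Segment the analysis window into adaptive-cycle phases.

    Each anchor starts a reorganization segment extended forward while its
    signature holds (at least ``min_reorg_years``); collapse is carved
    backward from the anchor while its signature holds; remaining years are
    growth where the growth signature holds, else unclassified.  A final
    repair pass demotes any collapse segment whose nearest preceding
    classified phase is reorganization (the cycle order forbids alpha
    followed directly by Omega).
    """
    params = params or PhaseParams()
    if len(indices.years) == 0:
        raise ValueError("empty index series")
    years = indices.years
    mask = _analysis_mask(years, window)
    idx = np.flatnonzero(mask)
    sl_a, sl_c, sl_r, high = _signature_arrays(indices, params, mask)

    reorg_sig = (sl_a < 0) & (sl_c > 0) & high
    # sub-epsilon (zeroed) potential slopes count as non-rising: a smoothed
    # series passes through a flat inflection right at the collapse/reorg
    # boundary, and the carve-back must cross it to reach the collapse proper
    collapse_sig = (sl_a < 0) & (sl_c <= 0) & (sl_r > 0)
    growth_sig = (sl_a > 0) & (sl_c > 0) & (sl_r < 0)

    labels = {i: UNCLASSIFIED for i in idx}
    anchors = sorted(int(a) for a in anchors)
    anchor_idx = []
    for a in anchors:
        pos = np.flatnonzero(years == a)
        if len(pos) and mask[pos[0]]:
            anchor_idx.append(int(pos[0]))

    first, last = (int(idx[0]), int(idx[-1])) if len(idx) else (0, -1)
    for k, ai in enumerate(anchor_idx):
        stop = anchor_idx[k + 1] if k + 1 < len(anchor_idx) else last + 1
        j = ai
        # while the signature holds, or still under the minimum duration
        while j < stop and (reorg_sig[j] or j - ai < params.min_reorg_years):
            if labels[j] != UNCLASSIFIED:
                break
            labels[j] = REORG
            j += 1
        j = ai - 1
        while j >= first and labels[j] == UNCLASSIFIED and collapse_sig[j]:
            labels[j] = COLLAPSE
            j -= 1
    for i in idx:
        if labels[i] == UNCLASSIFIED and growth_sig[i]:
            labels[i] = GROWTH

    segments = _runs_to_segments(years, idx, labels)
    segments = _repair_order(segments)
    cycle_count = sum(1 for s in segments if s.phase == REORG)
    win = (int(years[idx[0]]), int(years[idx[-1]]))
    return PhaseSegmentation(
        scenario=scenario,
        segments=segments,
        cycle_count=cycle_count,
        anchors=[int(years[i]) for i in anchor_idx],
        window=win,
    )


def _runs_to_segments(years, idx, labels) -> list[PhaseSegment]:
    segments = []
    start = idx[0]
    for prev, cur in zip(idx[:-1], idx[1:]):
        if labels[cur] != labels[prev]:
            segments.append(PhaseSegment(int(years[start]), int(years[prev]), labels[prev]))
            start = cur
    segments.append(PhaseSegment(int(years[start]), int(years[idx[-1]]), labels[idx[-1]]))
    return segments


def _repair_order(segments: list[PhaseSegment]) -> list[PhaseSegment]:
    """Demote a collapse whose last classified predecessor is reorganization."""
    out = []
    last_classified = None
    for seg in segments:
        if seg.phase == COLLAPSE and last_classified == REORG:
            seg = PhaseSegment(seg.start_year, seg.end_year, UNCLASSIFIED)
        if seg.phase != UNCLASSIFIED:
            last_classified = seg.phase
        out.append(seg)
    # merge adjacent same-phase segments created by demotion
    merged: list[PhaseSegment] = []
    for seg in out:
        if merged and merged[-1].phase == seg.phase:
            merged[-1] = PhaseSegment(merged[-1].start_year, seg.end_year, seg.phase)
        else:
            merged.append(seg)
    return merged


def phase_durations(segmentation: PhaseSegmentation) -> pd.DataFrame:
    """Per-segment durations plus per-phase mean duration (years)."""
    rows = [
        {"start_year": s.start_year, "end_year": s.end_year, "phase": s.phase, "duration": s.duration}
        for s in segmentation.segments
    ]
    df = pd.DataFrame(rows)
    df["phase_mean_duration"] = df.groupby("phase")["duration"].transform("mean")
    return df


# --------------------------------------------------------------------------
# planted-schedule index builder (validation fixture generator)

_PHASE_SLOPES = {
    # per-year slopes of (ascendency, capacity, overhead) within each phase,
    # chosen to satisfy the classification signatures with margin; the
    # overhead slope of a collapse is recomputed per segment (see below) so
    # resilience oscillates between fixed low and high levels instead of
    # drifting, as in the adaptive-cycle schematic
    GROWTH: (0.6, 0.9, -0.6),
    COLLAPSE: (-0.9, -0.4, 1.2),
    REORG: (-0.5, 1.2, 0.3),
}


def phase_schedule_indices(
    schedule,
    noise_sd: float = 0.15,
    seed: int = 0,
    span: float = 0.20,
    start_levels=(40.0, 70.0, 30.0),
) -> IndexSeries:
    """Synthesize an IndexSeries realizing a planted phase schedule.

    ``schedule`` is an ordered list of (start_year, end_year, phase) covering
    contiguous years.  Within each phase the three indices follow straight
    lines whose slopes match that phase's trend signature, chained
    continuously across phases, plus Gaussian noise.  The default span (0.20)
    smooths at the decadal scale of the phases themselves.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(schedule[0][0], schedule[-1][1] + 1)
    a = np.empty(len(years))
    c = np.empty(len(years))
    r = np.empty(len(years))
    la, lc, lr = start_levels
    r_high = start_levels[2]
    k = 0
    for start, end, phase in schedule:
        if start != years[k]:
            raise ValueError("schedule segments must be contiguous")
        da, dc, dr = _PHASE_SLOPES[phase]
        if phase == COLLAPSE:
            # release restores the resilience spent during growth: rise back
            # to the running high level so cycles oscillate rather than drift
            dr = max((r_high - lr) / (end - start + 1), 0.8)
        elif phase == REORG:
            r_high = lr + dr * (end - start + 1)
        for _ in range(end - start + 1):
            a[k], c[k], r[k] = la, lc, lr
            la, lc, lr = la + da, lc + dc, lr + dr
            k += 1
    a = np.clip(a + rng.normal(scale=noise_sd, size=len(years)), 0.1, None)
    c = np.clip(c + rng.normal(scale=noise_sd, size=len(years)), 0.1, None)
    r = np.clip(r + rng.normal(scale=noise_sd, size=len(years)), 0.1, None)
    xs = years.astype(float)
    return IndexSeries(
        years=years,
        tst=a + r,
        ascendency=a,
        capacity=c,
        overhead=r,
        ascendency_smoothed=smooth_series(a, span=span, x=xs),
        capacity_smoothed=smooth_series(c, span=span, x=xs),
        overhead_smoothed=smooth_series(r, span=span, x=xs),
        scenario=None,
        span=span,
    )
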