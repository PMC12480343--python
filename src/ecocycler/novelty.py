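"""Ecosystem novelty as minimum dissimilarity to a baseline window.

Novelty(t) = min over baseline states of D(state(t), baseline state), where a
"state" is one year's per-group biomass vector from one ensemble member.  The
baseline pool spans every (year, member) combination in the baseline window —
the full model-uncertainty range — while averaging is over target members
only, yielding one series per measure and scenario.

Three dissimilarity measures are supported:

* ``biomass_euclidean`` — Euclidean distance between raw biomass vectors
  (novelty in biomass);
* ``composition_hellinger`` — Hellinger distance between composition
  (proportion) vectors, bounded by sqrt(2), which downweights the dominant
  groups (novelty in composition);
* ``cumulative_species`` — per-species minimum absolute biomass difference to
  the baseline, summed over species (novelty in individual species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .synthetic_foodweb import ScenarioSpec, scenario_grid

__all__ = [
    "MEASURES",
    "NoveltySeries",
    "euclidean_distance",
    "hellinger_distance",
    "cumulative_species_novelty",
    "novelty_series",
    "novelty_batch",
]

MEASURES = ("biomass_euclidean", "composition_hellinger", "cumulative_species")

SQRT2 = float(np.sqrt(2.0))


def euclidean_distance(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(((x - y) ** 2).sum()))


def _as_composition(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("composition has negative entries")
    s = p.sum()
    if s <= 0:
        raise ValueError("composition sums to zero")
    if abs(s - 1.0) > 1e-9:
        warnings.warn("composition does not sum to 1; normalizing")
        p = p / s
    return p


def hellinger_distance(p, q) -> float:
    """sqrt(sum (sqrt p_g - sqrt q_g)^2), bounded in [0, sqrt(2)]."""
    p = _as_composition(p)
    q = _as_composition(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(((np.sqrt(p) - np.sqrt(q)) ** 2).sum()))


def cumulative_species_novelty(target, baseline_states) -> tuple[float, np.ndarray]:
    """Per-species minimum |biomass difference| over the baseline pool, and
    its sum over species.

    Each species is matched to its own closest baseline state, so the total is
    a lower bound on the L1 distance to any single baseline state.
    """
    target = np.asarray(target, dtype=float)
    B = np.asarray(baseline_states, dtype=float)
    if B.ndim != 2 or B.shape[0] == 0:
        raise ValueError("baseline pool must be a non-empty 2-D array of states")
    if B.shape[1] != target.shape[0]:
        raise ValueError("baseline states and target have different group counts")
    per_species = np.abs(target[None, :] - B).min(axis=0)
    return float(per_species.sum()), per_species


@dataclass
class NoveltySeries:
    """Ensemble-averaged minimum-dissimilarity series for one scenario/measure."""

    measure: str
    scenario: ScenarioSpec | None
    years: np.ndarray
    values: np.ndarray
    baseline_window: tuple[int, int]

    @property
    def series_id(self) -> tuple:
        label = self.scenario.label if self.scenario is not None else None
        return (label, self.measure)


def _window_mask(years: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    mask = (years >= lo) & (years <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains none of the run's years")
    return mask


def novelty_series(
    run,
    measure: str,
    baseline_window: tuple[int, int] = (2000, 2018),
    target_window: tuple[int, int] = (2019, 2090),
    groups=None,
) -> NoveltySeries:
    """Minimum dissimilarity of each target-year state to the baseline pool,
    averaged over ensemble members.

    ``run`` needs ``years`` (1-D int array) and ``biomass`` of shape
    (members, years, groups); ``groups`` optionally restricts the distance to
    a subset of group indices or names.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if max(baseline_window[0], target_window[0]) <= min(baseline_window[1], target_window[1]):
        raise ValueError("baseline and target windows overlap")
    years = np.asarray(run.years)
    bmask = _window_mask(years, baseline_window)
    tmask = _window_mask(years, target_window)

    biomass = run.biomass
    if groups is not None:
        names = list(getattr(run, "group_names", []))
        idx = [names.index(g) if isinstance(g, str) else int(g) for g in groups]
        biomass = biomass[:, :, idx]
    m, _, g = biomass.shape

    # baseline pool: all (member, year) states in the baseline window
    B = biomass[:, bmask, :].reshape(-1, g)
    target_years = years[tmask]
    values = np.empty(len(target_years))
    for k, tix in enumerate(np.flatnonzero(tmask)):
        S = biomass[:, tix, :]                          # (members, groups)
        if measure == "biomass_euclidean":
            novelty = cdist(S, B).min(axis=1)
        elif measure == "composition_hellinger":
            P = np.sqrt(S / S.sum(axis=1, keepdims=True))
            Q = np.sqrt(B / B.sum(axis=1, keepdims=True))
            novelty = cdist(P, Q).min(axis=1)
        else:  # cumulative_species: per-species min |diff|, summed
            novelty = np.abs(S[:, None, :] - B[None, :, :]).min(axis=1).sum(axis=1)
        values[k] = novelty.mean()
    return NoveltySeries(
        measure=measure,
        scenario=getattr(run, "scenario", None),
        years=target_years,
        values=values,
        baseline_window=tuple(baseline_window),
    )


def novelty_batch(
    runs,
    measures=MEASURES,
    baseline_window: tuple[int, int] = (2000, 2018),
    target_window: tuple[int, int] = (2019, 2090),
    groups=None,
    require_full_grid: bool = True,
) -> list[NoveltySeries]:
    """One novelty series per (scenario, measure): |scenarios| x |measures|
    series, e.g. 48 for the full 16-scenario grid."""
    runs = list(runs)
    if require_full_grid:
        have = {run.scenario for run in runs}
        missing = [s.label for s in scenario_grid() if s not in have]
        if missing:
            raise ValueError(f"runs do not cover the scenario grid; missing {missing}")
    out = []
    for run in runs:
        for measure in measures:
            out.append(novelty_series(run, measure, baseline_window, target_window, groups))
    return out
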