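"""Synthetic food-web ensemble generator.

Emulates the *outputs* of a calibrated trophic mass-balance model (annual
per-group biomasses and consumption-flow matrices, with Monte-Carlo ensemble
spread) for a coastal brackish-water ecosystem: 28 biotic groups from primary
producers to fish, seals and birds, seven fishing fleets, and three invasive
species.  Scenarios cross two climate forcings (RCP45/RCP85), two nutrient-load
futures (BSAP/REF) and four fishing regimes (SQ/Dec/Inc/Gil), 16 combinations
in all.

The generative model is deliberately transparent rather than mechanistic:

    B[m, t, g] = baseline[g] * member_perturbation[m, g]
                 * scenario_trend[g](t) * step_factors[g](t) * exp(AR1 noise)

Member perturbations are lognormal (one draw per member per group, emulating
parameter-resampling uncertainty), scenario trends are exponential ramps over
the projection window driven by per-group climate / nutrient / fishing
sensitivities, and the step factors plant known abrupt shifts whose years are
recorded as ground truth so every downstream stage can be validated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScenarioSpec",
    "FoodWebConfig",
    "GroundTruth",
    "EnsembleRun",
    "CLIMATE_LABELS",
    "NUTRIENT_LABELS",
    "FISHING_LABELS",
    "default_config",
    "scenario_grid",
    "simulate_biomass",
    "flows_from_biomass",
]

CLIMATE_LABELS = ("RCP45", "RCP85")
NUTRIENT_LABELS = ("BSAP", "REF")
FISHING_LABELS = ("SQ", "Dec", "Inc", "Gil")

IMPORT_LABEL = "Import"


@dataclass(frozen=True, order=True)
class ScenarioSpec:
    """One point of the climate x nutrient x fishing scenario grid."""

    climate: str
    nutrient: str
    fishing: str

    def __post_init__(self) -> None:
        if self.climate not in CLIMATE_LABELS:
            raise ValueError(f"unknown climate label {self.climate!r}; expected one of {CLIMATE_LABELS}")
        if self.nutrient not in NUTRIENT_LABELS:
            raise ValueError(f"unknown nutrient label {self.nutrient!r}; expected one of {NUTRIENT_LABELS}")
        if self.fishing not in FISHING_LABELS:
            raise ValueError(f"unknown fishing label {self.fishing!r}; expected one of {FISHING_LABELS}")

    @property
    def label(self) -> str:
        return f"{self.climate}_{self.nutrient}_{self.fishing}"

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        parts = label.split("_")
        if len(parts) != 3:
            raise ValueError(f"scenario label {label!r} is not of the form CLIMATE_NUTRIENT_FISHING")
        return cls(*parts)


def scenario_grid() -> list[ScenarioSpec]:
    """Full Cartesian product of the three scenario dimensions (16 specs),
    deterministically ordered climate-major."""
    return [
        ScenarioSpec(c, n, f)
        for c, n, f in itertools.product(CLIMATE_LABELS, NUTRIENT_LABELS, FISHING_LABELS)
    ]


# --------------------------------------------------------------------------
# Default community: 28 biotic groups spanning producers -> apex predators.
# (name, baseline biomass t/km2, Q/B per yr, warming sens., nutrient sens.)
# Warming sensitivity >0 means the group benefits under stronger warming;
# nutrient sensitivity >0 means it benefits under higher nutrient loads.
_GROUPS: list[tuple[str, float, float, float, float]] = [
    ("phytoplankton",      55.0,  0.0,  0.3,  1.0),
    ("filamentous_algae",  30.0,  0.0,  0.8,  1.2),
    ("fucus",              12.0,  0.0, -0.6, -1.0),
    ("other_macrophytes",  10.0,  0.0, -0.2, -0.3),
    ("benthic_microalgae",  8.0,  0.0,  0.1,  0.4),
    ("microzooplankton",    6.0, 40.0,  0.3,  0.6),
    ("mesozooplankton",    10.0, 25.0,  0.1,  0.5),
    ("fishhook_waterflea",  0.8, 30.0,  0.9,  0.4),
    ("mysids",              3.0, 12.0, -0.2,  0.1),
    ("benthic_bivalves",   25.0,  6.0, -0.3,  0.3),
    ("benthic_gastropods",  5.0,  7.0,  0.0,  0.2),
    ("polychaetes",         6.0,  9.0,  0.1,  0.4),
    ("amphipods",           4.0, 10.0, -0.4,  0.0),
    ("harris_mud_crab",     1.5,  8.0,  0.8,  0.2),
    ("saduria",             2.0,  5.0, -0.5, -0.1),
    ("herring",             9.0,  5.5,  0.0,  0.1),
    ("sprat",               5.0,  7.0,  0.3,  0.2),
    ("round_goby",          2.5,  6.5,  0.9,  0.3),
    ("perch",               4.0,  4.5,  0.5,  0.2),
    ("sander",              2.0,  3.8,  0.5,  0.1),
    ("roach",               5.0,  5.0,  0.3,  0.5),
    ("whitefish",           1.5,  4.0, -0.5, -0.2),
    ("flounder",            2.0,  4.2, -0.1,  0.0),
    ("burbot",              0.8,  3.2, -0.7, -0.1),
    ("salmonids",           0.6,  5.0, -0.3,  0.0),
    ("pike",                1.2,  3.0,  0.2, -0.1),
    ("grey_seal",           0.3, 15.0,  0.0,  0.0),
    ("waterbirds",          0.2, 60.0,  0.0,  0.0),
]

_FLEETS = [
    "gillnet",
    "coastal_trawl",
    "trap_net",
    "fyke_net",
    "longline",
    "seine",
    "recreational",
]

_INVASIVES = ["round_goby", "harris_mud_crab", "fishhook_waterflea"]

# consumer -> [(prey, relative weight)]; normalized to column-stochastic DC.
_DIETS: dict[str, list[tuple[str, float]]] = {
    "microzooplankton":   [("phytoplankton", 9), ("benthic_microalgae", 1)],
    "mesozooplankton":    [("phytoplankton", 7), ("microzooplankton", 3)],
    "fishhook_waterflea": [("mesozooplankton", 6), ("microzooplankton", 4)],
    "mysids":             [("mesozooplankton", 5), ("phytoplankton", 3), ("microzooplankton", 2)],
    "benthic_bivalves":   [("phytoplankton", 8), ("benthic_microalgae", 2)],
    "benthic_gastropods": [("filamentous_algae", 5), ("benthic_microalgae", 3), ("fucus", 2)],
    "polychaetes":        [("benthic_microalgae", 5), ("phytoplankton", 5)],
    "amphipods":          [("fucus", 3), ("filamentous_algae", 4), ("benthic_microalgae", 3)],
    "harris_mud_crab":    [("benthic_bivalves", 4), ("benthic_gastropods", 3), ("polychaetes", 3)],
    "saduria":            [("polychaetes", 5), ("amphipods", 5)],
    "herring":            [("mesozooplankton", 6), ("mysids", 2), ("fishhook_waterflea", 2)],
    "sprat":              [("mesozooplankton", 8), ("microzooplankton", 2)],
    "round_goby":         [("benthic_bivalves", 5), ("amphipods", 2), ("benthic_gastropods", 2), ("saduria", 1)],
    "perch":              [("round_goby", 3), ("amphipods", 2), ("mysids", 2), ("sprat", 3)],
    "sander":             [("herring", 4), ("sprat", 3), ("perch", 2), ("round_goby", 1)],
    "roach":              [("filamentous_algae", 4), ("benthic_bivalves", 3), ("amphipods", 3)],
    "whitefish":          [("mysids", 4), ("amphipods", 3), ("polychaetes", 3)],
    "flounder":           [("benthic_bivalves", 6), ("polychaetes", 2), ("saduria", 2)],
    "burbot":             [("herring", 3), ("sprat", 2), ("round_goby", 3), ("mysids", 2)],
    "salmonids":          [("herring", 6), ("sprat", 4)],
    "pike":               [("perch", 4), ("roach", 4), ("whitefish", 2)],
    "grey_seal":          [("herring", 5), ("sprat", 2), ("whitefish", 1), ("salmonids", 1), ("perch", 1)],
    "waterbirds":         [("herring", 3), ("sprat", 3), ("round_goby", 2), ("roach", 2)],
}

# Groups harvested by fleets (fishing scenarios scale their trend); the Gil
# scenario affects only the gillnet-caught subset.
_HARVESTED = ["herring", "sprat", "perch", "sander", "roach", "whitefish",
              "flounder", "burbot", "salmonids", "pike"]
_GILLNET_CAUGHT = ["perch", "sander", "whitefish", "salmonids", "pike"]


@dataclass(frozen=True)
class GroundTruth:
    """Planted features of a simulated run: exact shift events and the nominal
    phase schedule implied by them (reorganization onset at each shift year)."""

    shift_events: tuple[tuple[int, str, float], ...]  # (year, group, factor)

    @property
    def shift_years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _, _ in self.shift_events}))

    def nominal_phase_schedule(self, window: tuple[int, int]) -> list[tuple[int, int, str]]:
        """Phase schedule implied by the planted shifts: each shift year opens
        a nominal reorganization (preceded by a short collapse), the rest is
        growth.  Nominal in the sense that it encodes where abrupt novelty was
        planted, not index-trend dynamics."""
        lo, hi = window
        edges = []
        for y in self.shift_years:
            if lo + 3 <= y <= hi - 4:
                edges.append((y - 3, y - 1, "collapse"))
                edges.append((y, y + 4, "reorganization"))
        schedule: list[tuple[int, int, str]] = []
        cursor = lo
        for start, end, phase in edges:
            if start > cursor:
                schedule.append((cursor, start - 1, "growth_rK"))
            schedule.append((start, end, phase))
            cursor = end + 1
        if cursor <= hi:
            schedule.append((cursor, hi, "growth_rK"))
        return schedule


@dataclass(frozen=True)
class FoodWebConfig:
    group_names: tuple[str, ...]
    fleet_names: tuple[str, ...]
    invasive_names: tuple[str, ...]
    diet_matrix: np.ndarray            # DC[i, j]: fraction of consumer j's diet from prey i
    consumption_rate: np.ndarray       # Q/B per year; 0 for producers
    baseline_biomass: np.ndarray       # t/km2
    warming_sensitivity: np.ndarray
    nutrient_sensitivity: np.ndarray
    fishing_sensitivity: np.ndarray    # 1 for harvested groups, 0 otherwise
    gillnet_sensitivity: np.ndarray
    years: tuple[int, ...] = tuple(range(2000, 2091))
    baseline_end: int = 2018
    ar1_coef: float = 0.4
    noise_sd: float = 0.05
    member_sd: float = 0.10
    # per-year exponential trend rates attached to each scenario label
    climate_rates: dict = field(default_factory=lambda: {"RCP45": 0.004, "RCP85": 0.010})
    nutrient_rates: dict = field(default_factory=lambda: {"BSAP": -0.003, "REF": 0.006})
    fishing_rates: dict = field(default_factory=lambda: {"SQ": 0.0, "Dec": 0.004, "Inc": -0.006, "Gil": 0.0})
    gillnet_rates: dict = field(default_factory=lambda: {"SQ": 0.0, "Dec": 0.0, "Inc": 0.0, "Gil": 0.005})
    # shift schedule: key "all", a climate label, or a full scenario label ->
    # list of (year, {group: multiplicative factor})
    shift_schedule: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def validate(self) -> None:
        n = self.n_groups
        dc = self.diet_matrix
        if dc.shape != (n, n):
            raise ValueError(f"diet matrix shape {dc.shape} does not match {n} groups")
        if np.any(dc < 0):
            raise ValueError("diet matrix has negative entries")
        colsum = dc.sum(axis=0)
        consumers = self.consumption_rate > 0
        bad = consumers & (np.abs(colsum - 1.0) > 1e-9)
        if np.any(bad):
            names = [self.group_names[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"diet columns of consumers do not sum to 1: {names}")
        if np.any(self.consumption_rate < 0) or np.any(self.baseline_biomass < 0):
            raise ValueError("rates and biomasses must be nonnegative")
        if not set(self.invasive_names) <= set(self.group_names):
            raise ValueError("invasive_names must be a subset of group_names")
        lo, hi = self.baseline_end + 1, self.years[-1]
        for events in self.shift_schedule.values():
            for year, _ in events:
                if not lo <= year <= hi:
                    raise ValueError(f"shift year {year} outside projection window {lo}..{hi}")

    def scenario_shift_events(self, scenario: ScenarioSpec) -> list[tuple[int, dict[str, float]]]:
        """Resolve the shift schedule for one scenario: 'all' entries, entries
        keyed by the scenario's climate label, and entries keyed by the full label."""
        events: list[tuple[int, dict[str, float]]] = []
        for key in ("all", scenario.climate, scenario.label):
            events.extend(self.shift_schedule.get(key, []))
        return sorted(events, key=lambda e: e[0])


def default_config() -> FoodWebConfig:
    """Deterministic default community: 28 biotic groups over >=3 trophic
    levels, 7 fleets, 3 invasive species, fixed diet matrix, and planted
    abrupt shifts (all scenarios at 2035; warm-climate scenarios again at 2069)."""
    names = tuple(g[0] for g in _GROUPS)
    index = {g: i for i, g in enumerate(names)}
    n = len(names)
    dc = np.zeros((n, n))
    for consumer, prey in _DIETS.items():
        j = index[consumer]
        total = sum(w for _, w in prey)
        for p, w in prey:
            dc[index[p], j] = w / total
    cfg = FoodWebConfig(
        group_names=names,
        fleet_names=tuple(_FLEETS),
        invasive_names=tuple(_INVASIVES),
        diet_matrix=dc,
        consumption_rate=np.array([g[2] for g in _GROUPS], dtype=float),
        baseline_biomass=np.array([g[1] for g in _GROUPS], dtype=float),
        warming_sensitivity=np.array([g[3] for g in _GROUPS], dtype=float),
        nutrient_sensitivity=np.array([g[4] for g in _GROUPS], dtype=float),
        fishing_sensitivity=np.array([1.0 if g in _HARVESTED else 0.0 for g in names]),
        gillnet_sensitivity=np.array([1.0 if g in _GILLNET_CAUGHT else 0.0 for g in names]),
        shift_schedule={
            "all": [(2035, {"filamentous_algae": 2.5, "fucus": 0.4, "round_goby": 3.0})],
            "RCP85": [(2069, {"benthic_bivalves": 0.4, "herring": 0.6, "sprat": 1.8})],
        },
    )
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class EnsembleRun:
    """Per-scenario Monte-Carlo ensemble of annual biomass states."""

    scenario: ScenarioSpec
    years: np.ndarray                  # strictly increasing, step 1
    members: int
    group_names: tuple[str, ...]
    biomass: np.ndarray                # (members, years, groups), t/km2
    config: FoodWebConfig
    ground_truth: GroundTruth

    def flows(self, member: int, year: int) -> "FlowNetworkLike":
        t = int(np.searchsorted(self.years, year))
        if t >= len(self.years) or self.years[t] != year:
            raise ValueError(f"year {year} not in run")
        return flows_from_biomass(self.biomass[member, t], self.config)

    def mean_flows(self, year: int) -> "FlowNetworkLike":
        """Ensemble-mean flow network; exact because flows are linear in biomass."""
        t = int(np.searchsorted(self.years, year))
        if t >= len(self.years) or self.years[t] != year:
            raise ValueError(f"year {year} not in run")
        return flows_from_biomass(self.biomass[:, t].mean(axis=0), self.config)


def _scenario_index(scenario: ScenarioSpec) -> int:
    return scenario_grid().index(scenario)


def simulate_biomass(
    config: FoodWebConfig,
    scenario: ScenarioSpec,
    members: int,
    seed: int,
) -> EnsembleRun:
    """Simulate an ensemble of annual biomass trajectories for one scenario.

    Bit-identical for identical ``(config, scenario, members, seed)``; the
    stream is keyed on ``(seed, scenario index)`` so the 16 scenarios of a
    grid draw independent noise from one top-level seed.
    """
    if members < 1:
        raise ValueError("members must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    config.validate()

    years = np.asarray(config.years, dtype=int)
    if not np.all(np.diff(years) == 1):
        raise ValueError("years must be consecutive")
    n_t, n_g = len(years), config.n_groups

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _scenario_index(scenario)]))
    pert = rng.lognormal(mean=0.0, sigma=config.member_sd, size=(members, n_g))

    # AR(1) noise on the log scale, stationary initial state
    phi, sd = config.ar1_coef, config.noise_sd
    noise = np.zeros((members, n_t, n_g))
    if sd > 0:
        innov = rng.normal(scale=sd, size=(members, n_t, n_g))
        noise[:, 0] = innov[:, 0] / np.sqrt(max(1.0 - phi**2, 1e-12))
        for t in range(1, n_t):
            noise[:, t] = phi * noise[:, t - 1] + innov[:, t]

    # deterministic scenario trend: flat over the baseline, exponential ramp after
    rate = (
        config.warming_sensitivity * config.climate_rates[scenario.climate]
        + config.nutrient_sensitivity * config.nutrient_rates[scenario.nutrient]
        + config.fishing_sensitivity * config.fishing_rates[scenario.fishing]
        + config.gillnet_sensitivity * config.gillnet_rates[scenario.fishing]
    )
    dt = np.clip(years - config.baseline_end, 0, None)
    trend = np.exp(np.outer(dt, rate))                      # (years, groups)

    # planted multiplicative steps
    steps = np.ones((n_t, n_g))
    events: list[tuple[int, str, float]] = []
    for year, factors in config.scenario_shift_events(scenario):
        mask = years >= year
        for group, factor in factors.items():
            g = config.group_names.index(group)
            steps[mask, g] *= factor
            events.append((year, group, factor))

    biomass = (
        config.baseline_biomass[None, None, :]
        * pert[:, None, :]
        * trend[None, :, :]
        * steps[None, :, :]
        * np.exp(noise)
    )
    return EnsembleRun(
        scenario=scenario,
        years=years,
        members=members,
        group_names=config.group_names,
        biomass=biomass,
        config=config,
        ground_truth=GroundTruth(shift_events=tuple(sorted(events))),
    )


class FlowNetworkLike:
    # placeholder for type hints; the concrete class lives in ecocycler.ena
    pass


def flows_from_biomass(biomass: np.ndarray, config: FoodWebConfig):
    """Build one year's flow network from a biomass vector.

    Internal flow T[i, j] = B_j * (Q/B)_j * DC[i, j]; an extra boundary
    compartment ("Import") supplies each group whose outflow would otherwise
    exceed its inflow (primary producers), so the matrix is a complete
    transfer description.
    """
    from .ena import FlowNetwork  # deferred: ena is downstream of this module

    biomass = np.asarray(biomass, dtype=float)
    if biomass.shape != (config.n_groups,):
        raise ValueError(f"biomass vector length {biomass.shape} != {config.n_groups} groups")
    if np.any(biomass < 0):
        raise ValueError("negative biomass")

    n = config.n_groups
    consumption = biomass * config.consumption_rate        # total inflow of each consumer
    internal = config.diet_matrix * consumption[None, :]   # (prey i, consumer j)

    T = np.zeros((n + 1, n + 1))
    T[:n, :n] = internal
    outflow = internal.sum(axis=1)
    inflow = internal.sum(axis=0)
    needs_import = (outflow > 0) & (inflow == 0)
    T[n, :n] = np.where(needs_import, outflow, 0.0)        # boundary row feeds producers
    return FlowNetwork(compartments=list(config.group_names) + [IMPORT_LABEL], T=T)
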