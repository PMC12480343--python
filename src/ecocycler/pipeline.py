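"""End-to-end pipeline: generate -> flows -> indices -> novelty -> change
points -> phases, for every requested scenario, from one validated config.

All randomness flows from a single top-level seed (split per scenario inside
the generator); all interchange is plain CSV so every intermediate is
inspectable, and a JSON manifest records the config hash, per-stage outputs
and status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptive_cycle import PhaseParams, anchor_reorganization, classify_phases
from .changepoint import changepoints_batch
from .ena import index_series
from .novelty import MEASURES, novelty_series
from .synthetic_foodweb import (
    FoodWebConfig,
    ScenarioSpec,
    default_config,
    flows_from_biomass,
    scenario_grid,
    simulate_biomass,
)

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("ecocycler")


class ConfigError(ValueError):
    """Carries every validation violation found, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


@dataclass
class PipelineConfig:
    foodweb: FoodWebConfig
    scenarios: list[ScenarioSpec]
    baseline_window: tuple[int, int] = (2000, 2018)
    target_window: tuple[int, int] = (2019, 2090)
    members: int = 20
    seed: int = 0
    log_base: float = 2.0
    span: float = 0.75
    min_seg_len: int = 10
    penalty: str | float = "MBIC"
    trend_window: int = 7
    epsilon_iqr_frac: float = 0.01
    resilience_quantile: float = 0.5
    min_reorg_years: int = 3
    out_dir: Path = Path("results")

    def phase_params(self) -> PhaseParams:
        return PhaseParams(
            trend_window=self.trend_window,
            epsilon_iqr_frac=self.epsilon_iqr_frac,
            resilience_quantile=self.resilience_quantile,
            min_reorg_years=self.min_reorg_years,
        )

    def key_dict(self) -> dict:
        d = {
            "scenarios": [s.label for s in self.scenarios],
            "baseline_window": list(self.baseline_window),
            "target_window": list(self.target_window),
            "members": self.members,
            "seed": self.seed,
            "log_base": self.log_base,
            "span": self.span,
            "min_seg_len": self.min_seg_len,
            "penalty": self.penalty,
            "trend_window": self.trend_window,
            "epsilon_iqr_frac": self.epsilon_iqr_frac,
            "resilience_quantile": self.resilience_quantile,
            "min_reorg_years": self.min_reorg_years,
            "groups": list(self.foodweb.group_names),
            "fleets": list(self.foodweb.fleet_names),
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.key_dict(), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping (e.g. parsed YAML/TOML),
    collecting *all* violations before rejecting."""
    violations: list[str] = []
    raw = dict(raw or {})

    scen_field = raw.get("scenarios", "all")
    scenarios: list[ScenarioSpec] = []
    if scen_field == "all":
        scenarios = scenario_grid()
    else:
        for label in scen_field:
            try:
                scenarios.append(ScenarioSpec.from_label(label))
            except ValueError as e:
                violations.append(f"scenarios: {e}")

    def window(name, default):
        value = raw.get(name, default)
        try:
            lo, hi = int(value[0]), int(value[1])
        except (TypeError, ValueError, IndexError):
            violations.append(f"{name}: expected [start_year, end_year], got {value!r}")
            return default
        if lo > hi:
            violations.append(f"{name}: start {lo} after end {hi}")
        return (lo, hi)

    baseline = window("baseline_window", (2000, 2018))
    target = window("target_window", (2019, 2090))
    if max(baseline[0], target[0]) <= min(baseline[1], target[1]):
        violations.append(
            f"baseline_window {baseline} and target_window {target} overlap"
        )

    members = raw.get("members", 20)
    if not (isinstance(members, int) and members >= 1):
        violations.append(f"members: must be a positive integer, got {members!r}")
    seed = raw.get("seed")
    if seed is None:
        violations.append("seed: required (no hidden global randomness)")
    elif not isinstance(seed, int):
        violations.append(f"seed: must be an integer, got {seed!r}")

    span = raw.get("span", 0.75)
    if not 0 < span <= 1:
        violations.append(f"span: must lie in (0, 1], got {span!r}")
    min_seg_len = raw.get("min_seg_len", 10)
    if not (isinstance(min_seg_len, int) and min_seg_len >= 1):
        violations.append(f"min_seg_len: must be a positive integer, got {min_seg_len!r}")
    penalty = raw.get("penalty", "MBIC")
    if isinstance(penalty, str) and penalty.upper() not in ("MBIC", "BIC"):
        violations.append(f"penalty: unknown preset {penalty!r}")
    log_base = raw.get("log_base", 2.0)
    if not log_base > 0:
        violations.append(f"log_base: must be positive, got {log_base!r}")

    if violations:
        raise ConfigError(violations)

    foodweb = raw.get("foodweb") or default_config()
    return PipelineConfig(
        foodweb=foodweb,
        scenarios=scenarios,
        baseline_window=baseline,
        target_window=target,
        members=members,
        seed=seed,
        log_base=float(log_base),
        span=float(span),
        min_seg_len=min_seg_len,
        penalty=penalty,
        trend_window=int(raw.get("trend_window", 7)),
        epsilon_iqr_frac=float(raw.get("epsilon_iqr_frac", 0.01)),
        resilience_quantile=float(raw.get("resilience_quantile", 0.5)),
        min_reorg_years=int(raw.get("min_reorg_years", 3)),
        out_dir=Path(raw.get("out_dir", "results")),
    )


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: list[str], status: str = "ok", seconds: float = 0.0):
        self.stages[stage] = {"outputs": outputs, "status": status, "seconds": round(seconds, 2)}

    def write(self, path: Path):
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def _biomass_frame(run) -> pd.DataFrame:
    m, t, g = run.biomass.shape
    frames = []
    for member in range(m):
        df = pd.DataFrame(run.biomass[member], columns=list(run.group_names))
        df.insert(0, "member", member)
        df.insert(0, "year", run.years)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "scenario", run.scenario.label)
    return out


def _mean_flow_frame(run) -> pd.DataFrame:
    rows = []
    for year in run.years:
        net = run.mean_flows(int(year))
        src, dst = np.nonzero(net.T)
        for i, j in zip(src, dst):
            rows.append(
                (run.scenario.label, int(year), net.compartments[i], net.compartments[j], net.T[i, j])
            )
    return pd.DataFrame(rows, columns=["scenario", "year", "source", "target", "flow_t_km2_yr"])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the five stages for every requested scenario and write tidy
    CSVs plus a manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), version=__version__, seed=config.seed)
    manifest.write(out / "manifest.json")  # provisional; finalized at the end

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        # 1. generate ensembles
        t0 = stage("generate")
        runs = [
            simulate_biomass(config.foodweb, scen, config.members, config.seed)
            for scen in config.scenarios
        ]
        biomass = pd.concat([_biomass_frame(r) for r in runs], ignore_index=True)
        biomass.to_csv(out / "biomass.csv", index=False)
        truth = pd.DataFrame(
            [
                (r.scenario.label, y, g, f)
                for r in runs
                for (y, g, f) in r.ground_truth.shift_events
            ],
            columns=["scenario", "shift_year", "group", "factor"],
        )
        truth.to_csv(out / "ground_truth.csv", index=False)
        manifest.record("generate", ["biomass.csv", "ground_truth.csv"], seconds=time.perf_counter() - t0)

        # 2. flows (ensemble mean per year; exact, flows are linear in biomass)
        t0 = stage("flows")
        flows = pd.concat([_mean_flow_frame(r) for r in runs], ignore_index=True)
        flows.to_csv(out / "flows.csv", index=False)
        manifest.record("flows", ["flows.csv"], seconds=time.perf_counter() - t0)

        # 3. ENA indices on the mean network, smoothed
        t0 = stage("ena")
        index_rows = []
        indices_by_scen = {}
        for run in runs:
            nets = {int(y): run.mean_flows(int(y)) for y in run.years}
            series = index_series(nets, scenario=run.scenario, log_base=config.log_base, span=config.span)
            indices_by_scen[run.scenario] = series
            index_rows.append(
                pd.DataFrame(
                    {
                        "scenario": run.scenario.label,
                        "year": series.years,
                        "tst": series.tst,
                        "ascendency": series.ascendency,
                        "capacity": series.capacity,
                        "overhead": series.overhead,
                        "ascendency_smoothed": series.ascendency_smoothed,
                        "capacity_smoothed": series.capacity_smoothed,
                        "overhead_smoothed": series.overhead_smoothed,
                    }
                )
            )
        pd.concat(index_rows, ignore_index=True).to_csv(out / "indices.csv", index=False)
        manifest.record("ena", ["indices.csv"], seconds=time.perf_counter() - t0)

        # 4. novelty series (3 measures per scenario)
        t0 = stage("novelty")
        novelty_list = []
        for run in runs:
            for measure in MEASURES:
                novelty_list.append(
                    novelty_series(run, measure, config.baseline_window, config.target_window)
                )
        pd.concat(
            [
                pd.DataFrame(
                    {
                        "scenario": s.scenario.label,
                        "measure": s.measure,
                        "year": s.years,
                        "value": s.values,
                    }
                )
                for s in novelty_list
            ],
            ignore_index=True,
        ).to_csv(out / "novelty.csv", index=False)
        manifest.record("novelty", ["novelty.csv"], seconds=time.perf_counter() - t0)

        # 5. change points, then phases anchored at them
        t0 = stage("changepoint")
        cps = changepoints_batch(novelty_list, min_seg_len=config.min_seg_len, penalty=config.penalty)
        cp_rows = [
            (cp.series_id[0], cp.series_id[1], y) for cp in cps for y in cp.changepoints
        ]
        pd.DataFrame(cp_rows, columns=["scenario", "measure", "year"]).to_csv(
            out / "changepoints.csv", index=False
        )
        manifest.record("changepoint", ["changepoints.csv"], seconds=time.perf_counter() - t0)

        t0 = stage("phases")
        params = config.phase_params()
        phase_rows, cycle_rows = [], []
        for run in runs:
            series = indices_by_scen[run.scenario]
            cp_years = sorted(
                {
                    y
                    for cp in cps
                    if cp.series_id[0] == run.scenario.label
                    for y in cp.changepoints
                }
            )
            anchored, _ = anchor_reorganization(cp_years, series, params, window=config.target_window)
            seg = classify_phases(
                series, anchored, params, window=config.target_window, scenario=run.scenario
            )
            for s in seg.segments:
                phase_rows.append((run.scenario.label, s.start_year, s.end_year, s.phase))
            cycle_rows.append((run.scenario.label, seg.cycle_count))
        pd.DataFrame(phase_rows, columns=["scenario", "start_year", "end_year", "phase"]).to_csv(
            out / "phases.csv", index=False
        )
        pd.DataFrame(cycle_rows, columns=["scenario", "cycle_count"]).to_csv(
            out / "cycles.csv", index=False
        )
        manifest.record("phases", ["phases.csv", "cycles.csv"], seconds=time.perf_counter() - t0)
    except Exception as e:
        failed = len(manifest.stages)
        stage_names = ["generate", "flows", "ena", "novelty", "changepoint", "phases"]
        name = stage_names[min(failed, len(stage_names) - 1)]
        manifest.record(name, [], status=f"failed: {e}")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    manifest.write(out / "manifest.json")
    return manifest
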