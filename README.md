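# ecocycler

Ecosystem **novelty**, **change-point detection** and **adaptive-cycle phase
mapping** for food-web model output — with a built-in synthetic generator that
emulates the annual biomass and flow-matrix output of a calibrated trophic
mass-balance model (Ecopath-with-Ecosim style) under crossed
climate × nutrient × fishing scenarios.

The package is for ecosystem modellers and resilience researchers who have
(or want to emulate) multi-decadal food-web projections and ask: *when does
the ecosystem leave its historical range of variation, and how do those
departures line up with the growth (r/K), collapse (Ω) and reorganization (α)
phases of the adaptive cycle?*

## The method

**Novelty** of a projected year is its minimum dissimilarity to any state in a
baseline window:

```
Novelty(t) = min over baseline states b of D(x_t, b)
```

with three choices of `D`: Euclidean distance on raw species biomasses
(novelty in biomass), Hellinger distance on species proportions (novelty in
composition, bounded by √2, downweighting dominant groups), and a cumulative
per-species minimum |biomass difference| summed over species. The baseline
pool spans every (year × ensemble member) state in the baseline window, so the
full model-uncertainty range is honoured; the series is averaged over target
members.

**Change points in mean** of each novelty series are found by exact penalized
least-squares segmentation (an O(n²) dynamic programme, equivalent to PELT's
optimum) with a minimum segment length of 10 years and an MBIC-magnitude
penalty; a combinatorial brute-force enumerator serves as the test oracle.

**Adaptive-cycle phases** are read from three ecological network analysis
indices computed per year from the flow matrix `T` (log base 2, `TST = Σ T_ij`):

| dimension     | index           | formula                                       |
|---------------|-----------------|-----------------------------------------------|
| connectedness | ascendency A    | `Σ T_ij log₂(T_ij·TST / (T_i· · T_·j))`       |
| potential     | capacity C      | `−Σ T_ij log₂(T_ij / TST)`                    |
| resilience    | overhead R      | `−Σ T_ij log₂(T_ij² / (T_i· · T_·j))`         |

with the identity `C = A + R`. The smoothed indices (local quadratic LOESS)
give trend signatures: a change point is anchored as a **reorganization**
onset when connectedness falls, potential rises and resilience is high;
**collapse** is carved immediately before it (both falling, resilience
rising); remaining years are **growth** (rising A and C, falling R). The
cycle count is the number of reorganization segments.

## Worked example

```python
import ecocycler as ec

cfg = ec.default_config()                      # 28 groups, 7 fleets, 3 invaders
run = ec.simulate_biomass(cfg, ec.ScenarioSpec("RCP85", "REF", "SQ"),
                          members=20, seed=7)

series = ec.novelty_series(run, "biomass_euclidean")   # baseline 2000-2018
cp = ec.detect_mean_shifts(series.values, years=series.years)
print("novelty 2019:", round(series.values[0], 2),
      " novelty 2090:", round(series.values[-1], 2))
print("change points:", cp.changepoints)
print("planted shifts:", run.ground_truth.shift_years)

nets = {int(y): run.mean_flows(int(y)) for y in run.years}
idx = ec.index_series(nets)
print(f"ascendency: {idx.ascendency[0]:.1f} -> {idx.ascendency[-1]:.1f}")
```

prints

```
novelty 2019: 2.53  novelty 2090: 199.14
change points: [2035, 2049, 2059, 2071, 2081]
planted shifts: (2035, 2069)
ascendency: 3408.9 -> 4510.7
```

Novelty grows from near-baseline (2.5 t/km²) to a strong departure
(199 t/km²) under the warmest, most eutrophic scenario. The first detected
change point recovers the planted 2035 regime shift exactly; the later ones
track the accelerating scenario trend (the planted 2069 step is flagged at
2071). Ascendency rises ~32% as total throughput grows, in flow-bits
(t/km²/yr · bits).

The same pipeline runs end to end from the shell:

```sh
ecocycler run --seed 7 --out results/        # all 16 scenarios, 20 members
ecocycler generate --scenario RCP45_BSAP_SQ --members 20 --seed 7 --out gen/
ecocycler novelty --biomass gen/biomass.csv --out novelty.csv
ecocycler changepoint --novelty novelty.csv --min-seg-len 10 --out cps.csv
```

A full default run (16 scenarios × 20 members × 91 years × 28 groups) takes
well under a minute on one CPU and writes `biomass.csv`, `flows.csv`,
`indices.csv`, `novelty.csv` (48 series), `changepoints.csv`, `phases.csv`,
`cycles.csv` and a JSON manifest.

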