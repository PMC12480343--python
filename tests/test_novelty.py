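import numpy as np
import pytest

from ecocycler.novelty import (
    MEASURES,
    cumulative_species_novelty,
    euclidean_distance,
    hellinger_distance,
    novelty_batch,
    novelty_series,
)
from ecocycler.synthetic_foodweb import ScenarioSpec, scenario_grid


class _Run:
    """Minimal ensemble-run stand-in: biomass (members, years, groups)."""

    def __init__(self, biomass, years, scenario=None):
        self.biomass = np.asarray(biomass, dtype=float)
        self.years = np.asarray(years)
        self.group_names = tuple(f"g{i}" for i in range(self.biomass.shape[2]))
        self.scenario = scenario


class TestDistances:
    def test_euclidean(self):
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(5), rng.random(5)
            oracle = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
            assert euclidean_distance(x, y) == pytest.approx(oracle, rel=1e-12)
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_hellinger_endpoints(self):
        assert hellinger_distance([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(np.sqrt(2), rel=1e-12)
        assert hellinger_distance([0.5, 0.5], [1, 0]) == pytest.approx(np.sqrt(2 - np.sqrt(2)), rel=1e-12)

    def test_hellinger_normalizes_with_warning(self):
        with pytest.warns(UserWarning, match="normaliz"):
            d = hellinger_distance([2, 2], [1, 0])
        assert d == pytest.approx(np.sqrt(2 - np.sqrt(2)), rel=1e-12)

    def test_hellinger_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            hellinger_distance([1.2, -0.2], [0.5, 0.5])

    def test_hellinger_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert 0 <= hellinger_distance(p, q) <= np.sqrt(2) + 1e-12

    def test_cumulative_species(self):
        total, per = cumulative_species_novelty([1.0, 1.0], [[1.0, 1.0], [2.0, 3.0]])
        assert total == 0.0
        total, per = cumulative_species_novelty([4.0, 1.0], [[1.0, 1.0], [2.0, 3.0]])
        assert per == pytest.approx([2.0, 0.0])
        assert total == pytest.approx(2.0)
        # min over baselines is <= L1 distance to any single baseline
        for b in ([1.0, 1.0], [2.0, 3.0]):
            assert total <= np.abs(np.array([4.0, 1.0]) - np.array(b)).sum() + 1e-12
        with pytest.raises(ValueError):
            cumulative_species_novelty([1.0], np.empty((0, 1)))


class TestNoveltySeries:
    def test_replayed_baseline_gives_zero(self):
        rng = np.random.default_rng(2)
        base = rng.random((1, 5, 4))
        biomass = np.concatenate([base, base[:, ::-1]], axis=1)  # projection replays baseline
        run = _Run(biomass, np.arange(2000, 2010))
        for m in MEASURES:
            s = novelty_series(run, m, baseline_window=(2000, 2004), target_window=(2005, 2009))
            assert np.allclose(s.values, 0.0, atol=1e-12)

    def test_exhaustive_min_euclidean(self):
        biomass = np.zeros((1, 3, 2))
        biomass[0, 0] = [0, 0]
        biomass[0, 1] = [3, 4]
        biomass[0, 2] = [6, 8]
        run = _Run(biomass, [2000, 2001, 2002])
        s = novelty_series(run, "biomass_euclidean", (2000, 2001), (2002, 2002))
        assert s.values[0] == pytest.approx(5.0)  # min(10, 5)

    def test_member_average(self):
        # member 0 at distance 2, member 1 at distance 4 from the only baseline
        biomass = np.zeros((2, 2, 1))
        biomass[:, 0, 0] = [1.0, 1.0]
        biomass[0, 1, 0] = 3.0
        biomass[1, 1, 0] = 5.0
        run = _Run(biomass, [2000, 2001])
        s = novelty_series(run, "biomass_euclidean", (2000, 2000), (2001, 2001))
        assert s.values[0] == pytest.approx(3.0)

    def test_agrees_with_brute_force(self):
        """Tiny-run equivalence with an exhaustive double loop over all
        (baseline year, member) states, plus baseline monotonicity, across
        500 seeded trials."""
        for trial in range(500):
            rng = np.random.default_rng(trial)
            m, ny, g = rng.integers(1, 4), rng.integers(4, 8), rng.integers(2, 6)
            nb = rng.integers(1, min(ny - 1, 5) + 1)
            biomass = rng.random((m, ny, g)) + 0.01
            years = np.arange(2000, 2000 + ny)
            run = _Run(biomass, years)
            bwin, twin = (2000, 2000 + nb - 1), (2000 + nb, 2000 + ny - 1)
            s = novelty_series(run, "biomass_euclidean", bwin, twin)
            # oracle: explicit loops
            baselines = [biomass[mm, tt] for mm in range(m) for tt in range(nb)]
            for k, t in enumerate(range(nb, ny)):
                per_member = [
                    min(np.sqrt(((biomass[mm, t] - b) ** 2).sum()) for b in baselines)
                    for mm in range(m)
                ]
                assert s.values[k] == pytest.approx(np.mean(per_member), rel=1e-12)
            if nb >= 2:
                s_small = novelty_series(run, "biomass_euclidean", (2000, 2000 + nb - 2), twin)
                assert np.all(s.values <= s_small.values + 1e-12)

    def test_scaling_behaviour(self):
        rng = np.random.default_rng(5)
        biomass = rng.random((2, 6, 4)) + 0.1
        run = _Run(biomass, np.arange(2000, 2006))
        run_scaled = _Run(biomass * 7.0, np.arange(2000, 2006))
        wins = dict(baseline_window=(2000, 2002), target_window=(2003, 2005))
        h1 = novelty_series(run, "composition_hellinger", **wins)
        h2 = novelty_series(run_scaled, "composition_hellinger", **wins)
        assert np.allclose(h1.values, h2.values, rtol=1e-9)
        e1 = novelty_series(run, "biomass_euclidean", **wins)
        e2 = novelty_series(run_scaled, "biomass_euclidean", **wins)
        assert np.allclose(e2.values, 7.0 * e1.values, rtol=1e-9)

    def test_rejections(self):
        run = _Run(np.ones((1, 6, 2)), np.arange(2000, 2006))
        with pytest.raises(ValueError, match="measure"):
            novelty_series(run, "manhattan", (2000, 2002), (2003, 2005))
        with pytest.raises(ValueError, match="overlap"):
            novelty_series(run, "biomass_euclidean", (2000, 2003), (2003, 2005))
        with pytest.raises(ValueError, match="window"):
            novelty_series(run, "biomass_euclidean", (1990, 1995), (2003, 2005))


class TestNoveltyBatch:
    @staticmethod
    def _runs(scenarios):
        rng = np.random.default_rng(0)
        return [
            _Run(rng.random((1, 6, 3)) + 0.1, np.arange(2000, 2006), scenario=s)
            for s in scenarios
        ]

    def test_full_grid_yields_48_series(self):
        series = novelty_batch(
            self._runs(scenario_grid()),
            baseline_window=(2000, 2002),
            target_window=(2003, 2005),
        )
        assert len(series) == 48
        assert len({s.series_id for s in series}) == 48

    def test_single_scenario_three_series(self):
        series = novelty_batch(
            self._runs([ScenarioSpec("RCP45", "BSAP", "SQ")]),
            baseline_window=(2000, 2002),
            target_window=(2003, 2005),
            require_full_grid=False,
        )
        assert len(series) == 3

    def test_missing_scenario_rejected(self):
        runs = self._runs(scenario_grid()[:-1])
        with pytest.raises(ValueError, match="missing"):
            novelty_batch(runs, baseline_window=(2000, 2002), target_window=(2003, 2005))
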