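"""Parameter sampling, ensemble statistics and scenario comparison."""

import numpy as np
import pytest

from biapath.monte_carlo import (EnsembleSpec, ParameterRange,
                                 RangeConfigError, compare_scenarios,
                                 run_ensemble, sample_parameters,
                                 summarize_ensemble)
from biapath.synthetic_data import fig2_scenario_grid


class TestParameterRange:
    def test_validation(self):
        with pytest.raises(RangeConfigError):
            ParameterRange("x", 2.0, 1.0)
        with pytest.raises(RangeConfigError):
            ParameterRange("x", 0.0, 1.0, "log")
        with pytest.raises(RangeConfigError):
            ParameterRange("x", 0.0, 1.0, "cubic")

    def test_degenerate_range_is_constant(self, single_dhpaas_spec, rng):
        ranges = [ParameterRange("k_cond", 0.7, 0.7)]
        for _ in range(5):
            spec = sample_parameters(ranges, single_dhpaas_spec, rng)
            assert spec.k_cond == 0.7

    def test_draws_stay_in_bounds(self, single_dhpaas_spec, rng):
        ranges = [ParameterRange("dhpaas.vmax", 1.0, 100.0, "log"),
                  ParameterRange("feed_rate", 0.5, 4.0)]
        for _ in range(200):
            spec = sample_parameters(ranges, single_dhpaas_spec, rng)
            assert 1.0 <= spec.dhpaas.vmax <= 100.0
            assert 0.5 <= spec.feed_rate <= 4.0

    def test_linear_uniform_mean(self, single_dhpaas_spec):
        # law of large numbers at the ensemble's own iteration count
        rng = np.random.default_rng(123)
        ranges = [ParameterRange("phi_aldehyde", 0.0, 1.0)]
        draws = [sample_parameters(ranges, single_dhpaas_spec, rng).phi_aldehyde
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_seeded_determinism(self, single_dhpaas_spec):
        ranges = [ParameterRange("dhpaas.km", 0.01, 1.0, "log"),
                  ParameterRange("k_cond", 0.1, 10.0, "log")]
        a = [sample_parameters(ranges, single_dhpaas_spec,
                               np.random.default_rng(7)).to_dict()
             for _ in range(1)]
        b = [sample_parameters(ranges, single_dhpaas_spec,
                               np.random.default_rng(7)).to_dict()
             for _ in range(1)]
        assert a == b

    def test_unresolvable_path_raises(self, single_dhpaas_spec, rng):
        with pytest.raises(RangeConfigError):
            sample_parameters([ParameterRange("mao.vmax", 0, 1)],
                              single_dhpaas_spec, rng)
        with pytest.raises(RangeConfigError):
            sample_parameters([ParameterRange("topology", 0, 1)],
                              single_dhpaas_spec, rng)


class TestSummarize:
    def test_single_value(self):
        s = summarize_ensemble([10.0])
        assert (s.median, s.q1, s.q3, s.mean, s.min, s.max) == (10,) * 6

    def test_linear_interpolation_convention(self):
        s = summarize_ensemble([1, 2, 3, 4])
        assert s.median == pytest.approx(2.5)
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(3.25)

    def test_permutation_invariance(self, rng):
        y = rng.uniform(0, 100, 51)
        a = summarize_ensemble(y)
        b = summarize_ensemble(rng.permutation(y))
        for f in ("median", "q1", "q3", "min", "max"):
            assert getattr(a, f) == getattr(b, f)
        # the mean is summed in input order: equal up to round-off only
        assert a.mean == pytest.approx(b.mean, rel=1e-12)

    def test_sort_and_interpolate_oracle(self, rng):
        """Quartiles match a hand-rolled sort-and-interpolate definition."""
        def oracle(xs, q):
            s = sorted(xs)
            h = (len(s) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (h - lo) * (s[hi] - s[lo])

        for _ in range(100):
            y = rng.uniform(0, 100, rng.integers(1, 40))
            s = summarize_ensemble(y)
            assert s.q1 == pytest.approx(oracle(y, 25))
            assert s.median == pytest.approx(oracle(y, 50))
            assert s.q3 == pytest.approx(oracle(y, 75))

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            summarize_ensemble([])


class TestEnsemble:
    def test_degenerate_ranges_give_zero_iqr(self, single_dhpaas_spec):
        es = EnsembleSpec(base=single_dhpaas_spec,
                          ranges=[ParameterRange("k_cond", 0.1, 0.1)],
                          n_iter=5, t_end=10.0, seed=1)
        s = run_ensemble(es)
        assert s.q3 - s.q1 == pytest.approx(0.0, abs=1e-12)
        assert len(s.yields) == 5 and s.n_failed == 0

    def test_bit_identical_reproducibility(self, single_dhpaas_spec):
        es = lambda: EnsembleSpec(
            base=single_dhpaas_spec,
            ranges=[ParameterRange("dhpaas.vmax", 1.0, 100.0, "log"),
                    ParameterRange("k_cond", 0.01, 1.0, "log")],
            n_iter=10, t_end=10.0, seed=99)
        a, b = run_ensemble(es()), run_ensemble(es())
        assert np.array_equal(a.yields, b.yields)

    def test_feed_cap_respected_in_all_iterations(self, single_dhpaas_spec):
        capped = single_dhpaas_spec.copy()
        capped.feed_cap = 50.0
        capped.feed_rate = 3.0
        es = EnsembleSpec(base=capped,
                          ranges=[ParameterRange("feed_rate", 1.0, 4.0)],
                          n_iter=8, t_end=50.0, seed=3)
        s = run_ensemble(es)
        assert np.all(s.yields >= 0) and np.all(s.yields <= 100)


class TestCompareScenarios:
    def test_duplicate_labels_rejected(self, single_dhpaas_spec):
        es = EnsembleSpec(base=single_dhpaas_spec, ranges=[], n_iter=1)
        with pytest.raises(ValueError, match="duplicate"):
            compare_scenarios([("a", es), ("a", es)], master_seed=1)

    def test_identical_scenarios_identical_streams(self, single_dhpaas_spec):
        ranges = [ParameterRange("dhpaas.vmax", 1.0, 10.0, "log")]
        mk = lambda: EnsembleSpec(base=single_dhpaas_spec, ranges=ranges,
                                  n_iter=6, t_end=10.0)
        t1 = compare_scenarios([("a", mk()), ("b", mk())], master_seed=5)
        t2 = compare_scenarios([("a", mk()), ("b", mk())], master_seed=5)
        assert t1.equals(t2)

    def test_fig2_grid_runs_and_has_8_rows(self):
        grid = fig2_scenario_grid(n_iter=3)
        table = compare_scenarios(grid, master_seed=2)
        assert len(table) == 8
        assert set(table.columns) >= {"label", "median", "q1", "q3",
                                      "mean", "min", "max", "n_failed"}
        assert table["n_failed"].sum() == 0
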