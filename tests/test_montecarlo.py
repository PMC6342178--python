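import numpy as np
import pytest

from habsuit.curves import ResponseCurve, curve_to_lookup, validate_curve
from habsuit.fitting import GridSearchConfig
from habsuit.montecarlo import (
    EnvNoise,
    MCConfig,
    NoiseSpec,
    aggregate_maps,
    perturb_curve,
    perturb_occurrences,
    perturb_raster,
    run_monte_carlo,
    running_stats,
    split_train_test,
)
from habsuit.raster import OccurrenceSet, Raster

ARCH = ResponseCurve([(0, 0), (25, 1), (75, 1), (100, 0)], 0, 100)


class TestPerturbOccurrences:
    def test_zero_sd_is_identity(self, rng):
        occ = OccurrenceSet([[1.0, 2.0], [3.0, 4.0]])
        out = perturb_occurrences(occ, 0.0, rng)
        np.testing.assert_array_equal(out.xy, occ.xy)

    def test_same_seed_reproduces(self):
        occ = OccurrenceSet(np.random.default_rng(0).uniform(0, 10, (50, 2)))
        a = perturb_occurrences(occ, 3.0, np.random.default_rng(42))
        b = perturb_occurrences(occ, 3.0, np.random.default_rng(42))
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_mean_displacement_matches_rayleigh(self, rng):
        occ = OccurrenceSet(np.zeros((10000, 2)))
        out = perturb_occurrences(occ, 10.0, rng)
        d = np.hypot(out.x, out.y).mean()
        assert d == pytest.approx(10 * np.sqrt(np.pi / 2), rel=0.02)


class TestPerturbRaster:
    def _r(self):
        return Raster(np.tile(np.linspace(0, 100, 50), (50, 1)), origin_y=50.0)

    def test_zero_noise_is_identity(self, rng):
        r = self._r()
        out = perturb_raster(r, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out.values, r.values)

    def test_mean_shift_without_sd(self, rng):
        r = Raster(np.full((5, 5), 10.0), origin_y=5.0)
        # constant raster: clamping to the original range [10, 10] would
        # cancel the shift, so embed the constant in a wider-range raster
        wide = Raster(np.vstack([np.full((4, 5), 10.0), np.linspace(0, 100, 5)[None, :]]), origin_y=5.0)
        out = perturb_raster(wide, 5.0, 0.0, rng)
        np.testing.assert_allclose(out.values[:4], 15.0)

    def test_result_clamped_to_original_range(self, rng):
        r = self._r()
        out = perturb_raster(r, 0.0, 50.0, rng)
        assert out.values.min() >= r.vmin and out.values.max() <= r.vmax

    def test_nodata_untouched(self, rng):
        vals = np.tile(np.linspace(0, 9, 10), (3, 1))
        vals[1, 1] = np.nan
        r = Raster(vals, origin_y=3.0)
        out = perturb_raster(r, 0.0, 5.0, rng)
        assert np.isnan(out.values[1, 1])

    def test_sd_raster_controls_noise_spatially(self):
        r = self._r()
        sd_vals = np.full(r.values.shape, 10.0)
        sd_vals[0, 0] = 0.0
        sd = r.with_values(sd_vals)
        draws = np.stack(
            [
                perturb_raster(r, 0.0, sd, np.random.default_rng(i)).values
                for i in range(50)
            ]
        )
        assert np.all(draws[:, 0, 0] == r.values[0, 0])
        interior_sd = draws[:, 25, 25].std()
        assert interior_sd == pytest.approx(10.0, rel=0.15)

    def test_misaligned_sd_raster_raises(self, rng):
        r = self._r()
        bad = Raster(np.ones((10, 10)), origin_y=10.0)
        with pytest.raises(ValueError, match="aligned"):
            perturb_raster(r, 0.0, bad, rng)


class TestPerturbCurve:
    def test_zero_sd_is_identity(self, rng):
        out = perturb_curve(ARCH, 0.0, 0.0, rng)
        assert out == ARCH

    def test_always_valid_after_repair(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            out = perturb_curve(ARCH, 15.0, 0.4, rng)
            assert validate_curve(out) == []

    def test_x_only_noise_keeps_y(self, rng):
        out = perturb_curve(ARCH, 10.0, 0.0, rng)
        assert sorted(out.ys) == sorted(ARCH.ys)


class TestSplit:
    def test_sizes_disjoint_and_complete(self, rng):
        occ = OccurrenceSet(np.arange(200, dtype=float).reshape(100, 2))
        train, test = split_train_test(occ, 0.7, rng)
        assert train.n == 70 and test.n == 30
        joined = np.vstack([train.xy, test.xy])
        assert {tuple(p) for p in joined} == {tuple(p) for p in occ.xy}

    def test_same_seed_same_partition(self):
        occ = OccurrenceSet(np.random.default_rng(3).uniform(size=(40, 2)))
        a = split_train_test(occ, 0.7, np.random.default_rng(5))
        b = split_train_test(occ, 0.7, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].xy, b[0].xy)

    def test_rounding_rule_n3_half(self, rng):
        occ = OccurrenceSet(np.arange(6, dtype=float).reshape(3, 2))
        train, test = split_train_test(occ, 0.5, rng)
        assert (train.n, test.n) == (2, 1)

    def test_too_few_points_raise(self, rng):
        with pytest.raises(ValueError):
            split_train_test(OccurrenceSet([[0.0, 0.0]]), 0.7, rng)


class TestAggregates:
    def test_identical_maps_have_zero_sd(self):
        r = Raster(np.arange(9, dtype=float).reshape(3, 3), origin_y=3.0)
        agg = aggregate_maps([r, r, r])
        np.testing.assert_array_equal(agg["sd"].values, 0.0)
        np.testing.assert_array_equal(agg["mean"].values, r.values)
        np.testing.assert_array_equal(agg["min"].values, agg["max"].values)

    def test_two_point_population_sd(self):
        a = Raster(np.zeros((2, 2)), origin_y=2.0)
        b = Raster(np.ones((2, 2)), origin_y=2.0)
        agg = aggregate_maps([a, b])
        np.testing.assert_allclose(agg["mean"].values, 0.5)
        np.testing.assert_allclose(agg["sd"].values, 0.5)

    def test_single_map_sd_zero(self):
        r = Raster(np.ones((2, 2)), origin_y=2.0)
        assert np.all(aggregate_maps([r])["sd"].values == 0)

    def test_running_stats_closed_forms(self):
        mean, sd = running_stats([0.0, 1.0])
        np.testing.assert_allclose(mean, [0.0, 0.5])
        np.testing.assert_allclose(sd, [0.0, 0.5])
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        mean, sd = running_stats(x)
        assert mean[-1] == pytest.approx(x.mean())
        assert sd[-1] == pytest.approx(x.std())
        const_mean, const_sd = running_stats(np.full(5, 2.5))
        np.testing.assert_allclose(const_mean, 2.5)
        np.testing.assert_allclose(const_sd, 0.0, atol=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            running_stats([])


class TestRunMonteCarlo:
    GRID = GridSearchConfig(5, 5, 1)

    def test_single_noiseless_iteration_matches_deterministic_fit(self, gradient_small):
        from habsuit.model import fit_hs_model, predict_map

        cfg = MCConfig(iterations=1, seed=9, grid=self.GRID)
        res = run_monte_carlo(
            gradient_small.rasters, gradient_small.occurrences, cfg
        )
        det = predict_map(
            fit_hs_model(gradient_small.rasters, gradient_small.occurrences, self.GRID)
        )
        np.testing.assert_allclose(res.maps["mean"].values, det.values)
        np.testing.assert_array_equal(res.maps["sd"].values, 0.0)
        np.testing.assert_array_equal(res.maps["min"].values, res.maps["max"].values)

    def test_repeat_run_is_bit_identical(self, gradient_small):
        cfg = MCConfig(
            iterations=3, seed=4, split=True,
            noise=NoiseSpec(occurrence_sd=1.0),
            grid=self.GRID,
        )
        a = run_monte_carlo(gradient_small.rasters, gradient_small.occurrences, cfg)
        b = run_monte_carlo(gradient_small.rasters, gradient_small.occurrences, cfg)
        assert a.stats.equals(b.stats)
        for k in a.maps:
            np.testing.assert_array_equal(a.maps[k].values, b.maps[k].values)

    def test_map_ordering_and_envelope_containment(self, gradient_small):
        cfg = MCConfig(
            iterations=4, seed=2,
            noise=NoiseSpec(occurrence_sd=2.0,
                            environment={"BottomToTop": EnvNoise(0.0, 5.0)}),
            grid=self.GRID,
        )
        res = run_monte_carlo(gradient_small.rasters, gradient_small.occurrences, cfg)
        lo, mid, hi = (res.maps[k].values for k in ("min", "mean", "max"))
        assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)
        assert np.all(res.maps["sd"].values >= 0)
        for name, env in res.envelopes.items():
            for c in res.curves[name]:
                lut = curve_to_lookup(c)
                assert np.all(lut >= env["min"].to_numpy() - 1e-9)
                assert np.all(lut <= env["max"].to_numpy() + 1e-9)

    def test_stats_columns_and_lengths(self, gradient_small):
        cfg = MCConfig(iterations=2, seed=1, split=True, grid=self.GRID)
        res = run_monte_carlo(gradient_small.rasters, gradient_small.occurrences, cfg)
        assert len(res.stats) == 2
        assert {"loglik", "aic", "auc", "dropped"} <= set(res.stats.columns)
        assert len(res.running) == 2
        n = gradient_small.occurrences.n
        assert res.stats.loc[0, "n_train"] == round(0.7 * n)
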