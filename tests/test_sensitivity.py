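"""Triangular sampling and Monte Carlo propagation."""

import math

import numpy as np
import pytest

import insomnia_cea as ic
from insomnia_cea.sensitivity import SimulationSpec, TriangularParam


class TestDefaultRange:
    def test_quarter_spread(self):
        p = ic.make_default_range(100.0)
        assert (p.low, p.mode, p.high) == (75.0, 100.0, 125.0)

    def test_transport_base(self):
        p = ic.make_default_range(16.71)
        assert math.isclose(p.low, 12.5325) and math.isclose(p.high, 20.8875)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_fraction_outside_open_interval_rejected(self, fraction):
        with pytest.raises(ValueError):
            ic.make_default_range(100.0, fraction)

    def test_zero_base_signalled(self):
        with pytest.raises(ValueError, match="degenerate"):
            ic.make_default_range(0.0)

    def test_misordered_param_rejected(self):
        with pytest.raises(ValueError):
            TriangularParam(low=1.0, mode=0.5, high=2.0)


class TestSampler:
    SYM = TriangularParam(75.0, 100.0, 125.0, "x")

    def test_boundaries_and_median_of_symmetric(self):
        assert ic.sample_triangular(self.SYM, 0.0) == 75.0
        assert ic.sample_triangular(self.SYM, 1.0) == 125.0
        assert math.isclose(ic.sample_triangular(self.SYM, 0.5), 100.0)

    def test_deviate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ic.sample_triangular(self.SYM, 1.5)

    def test_degenerate_param_returns_point(self):
        p = TriangularParam(5.0, 5.0, 5.0, "x")
        assert ic.sample_triangular(p, 0.3) == 5.0

    @pytest.mark.parametrize(
        "param",
        [SYM, TriangularParam(0.0, 0.157, 0.373, "q"),
         TriangularParam(1.0, 1.0, 4.0, "skew")],
    )
    def test_empirical_mean_matches_analytic(self, param):
        """Sample mean over 1e5 draws sits within 3 SE of (lo+mode+hi)/3."""
        rng = np.random.default_rng(12345)
        n = 100_000
        draws = np.array(
            [ic.sample_triangular(param, u) for u in rng.uniform(size=n)]
        )
        assert draws.min() >= param.low and draws.max() <= param.high
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - ic.triangular_mean(param)) < 3 * se

    def test_matches_numpy_triangular_quantiles(self):
        """Cross-check the inverse CDF against numpy's triangular sampler."""
        rng = np.random.default_rng(7)
        ours = np.array(
            [ic.sample_triangular(self.SYM, u) for u in rng.uniform(size=20_000)]
        )
        theirs = np.random.default_rng(8).triangular(75, 100, 125, 20_000)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert abs(np.quantile(ours, q) - np.quantile(theirs, q)) < 1.0


class TestMonteCarlo:
    @staticmethod
    def linear_model(drawn):
        return {"y": 2.0 * drawn["a"] + drawn["b"]}

    def test_degenerate_params_reproduce_base_case(self):
        spec = SimulationSpec(
            params=[TriangularParam(3.0, 3.0, 3.0, "a"),
                    TriangularParam(1.0, 1.0, 1.0, "b")],
            n_iterations=50, seed=0,
        )
        res = ic.run_monte_carlo(self.linear_model, spec)
        assert np.all(res.samples["y"] == 7.0)

    def test_same_seed_same_result(self):
        spec = SimulationSpec(
            params=[ic.make_default_range(3.0, target="a"),
                    ic.make_default_range(1.0, target="b")],
            n_iterations=500, seed=42,
        )
        r1 = ic.run_monte_carlo(self.linear_model, spec)
        r2 = ic.run_monte_carlo(self.linear_model, spec)
        assert np.array_equal(r1.samples["y"], r2.samples["y"])
        assert r1.summary(0.90) == r2.summary(0.90)

    def test_mean_converges_to_base_for_linear_symmetric_model(self):
        spec = SimulationSpec(
            params=[ic.make_default_range(3.0, target="a"),
                    ic.make_default_range(1.0, target="b")],
            n_iterations=20_000, seed=3,
        )
        res = ic.run_monte_carlo(self.linear_model, spec)
        y = res.samples["y"]
        se = y.std(ddof=1) / math.sqrt(y.size)
        assert abs(y.mean() - 7.0) < 3 * se

    def test_invalid_iterations_counted_not_dropped_silently(self):
        def flaky(drawn):
            if drawn["a"] > 3.0:
                raise ValueError("over the edge")
            return {"y": drawn["a"]}

        spec = SimulationSpec(
            params=[ic.make_default_range(3.0, target="a")],
            n_iterations=400, seed=0,
        )
        res = ic.run_monte_carlo(flaky, spec)
        assert res.n_invalid > 0
        assert res.n_invalid + res.samples["y"].size == 400
        assert "over the edge" in res.invalid_messages[0]

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SimulationSpec(
                params=[ic.make_default_range(1.0, target="a"),
                        ic.make_default_range(2.0, target="a")],
            )


class TestSummarize:
    def test_hand_computed_quantiles(self):
        lo, hi, mean = ic.summarize(np.arange(1.0, 101.0), interval=0.90)
        assert math.isclose(lo, 5.95) and math.isclose(hi, 95.05)
        assert mean == 50.5

    def test_constant_samples(self):
        lo, hi, mean = ic.summarize(np.full(10, 3.0))
        assert lo == hi == mean == 3.0

    def test_full_interval_gives_min_max(self):
        lo, hi, _ = ic.summarize(np.array([2.0, 9.0, 4.0]), interval=1.0)
        assert (lo, hi) == (2.0, 9.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ic.summarize(np.array([]))

    def test_percentiles_monotone_in_probability(self):
        rng = np.random.default_rng(0)
        res = ic.SimulationResult(
            samples={"y": rng.normal(size=1000)}, n_iterations=1000
        )
        qs = [res.percentile("y", q) for q in (0.05, 0.25, 0.5, 0.75, 0.95)]
        assert qs == sorted(qs)


class TestPackagedModelPsa:
    def test_zero_variance_psa_equals_deterministic_run(self):
        """With every range collapsed to its mode, all samples equal the
        base case bitwise."""
        spec = ic.default_psa_spec(n_iterations=20, seed=0)
        degenerate = SimulationSpec(
            params=[TriangularParam(p.mode, p.mode, p.mode, p.target)
                    for p in spec.params],
            n_iterations=20, seed=0,
        )
        model = ic.make_psa_model()
        res = ic.run_monte_carlo(model, degenerate)
        base = model(ic.base_values(spec))
        for out, arr in res.samples.items():
            assert np.all(arr == base[out])

    def test_costs_only_psa_mean_matches_deterministic(self):
        """Net benefit is linear in unit costs, so with symmetric ranges on
        costs alone the Monte Carlo mean converges on the base case."""
        spec = ic.default_psa_spec(
            n_iterations=4000, seed=11,
            vary_volumes=False, vary_probabilities=False,
            vary_population=False, vary_utility=False,
        )
        assert all(p.target.startswith("cost:") for p in spec.params)
        model = ic.make_psa_model()
        res = ic.run_monte_carlo(model, spec)
        base = model(ic.base_values(spec))
        y = res.samples["net_benefit_per_person"]
        se = y.std(ddof=1) / math.sqrt(y.size)
        assert abs(y.mean() - base["net_benefit_per_person"]) < 3 * se

    def test_wider_ranges_never_narrow_the_interval(self):
        model = ic.make_psa_model()
        widths = []
        for fraction in (0.10, 0.25, 0.40):
            spec = ic.default_psa_spec(n_iterations=2000, seed=5, fraction=fraction)
            lo, hi, _ = ic.summarize(
                ic.run_monte_carlo(model, spec), 0.90,
                output="net_benefit_per_person",
            )
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_base_case_inside_90pct_interval(self):
        spec = ic.default_psa_spec(n_iterations=2000, seed=9)
        model = ic.make_psa_model()
        res = ic.run_monte_carlo(model, spec)
        base = model(ic.base_values(spec))
        for out in res.outputs:
            lo, hi, _ = ic.summarize(res, 0.90, output=out)
            assert lo <= base[out] <= hi
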