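import math

import numpy as np
import pytest

from leafcarbon import CostSpec, SampledSeries, cost, fit, report_cost_table
from leafcarbon.fitting import FitResult, _BoxTransform, particle_swarm, pattern_search
from leafcarbon.model import MASS_ACTION_NAMES, VARIANTS, SimulationError
from leafcarbon.synthetic import initial_state, observed_pools, truth_forcings


@pytest.fixture(scope="module")
def ler_setup(ler_noise_free):
    ds = ler_noise_free
    variant = VARIANTS["07"]
    return {
        "ds": ds,
        "variant": variant,
        "forcings": truth_forcings(ds.preset, variant),
        "initial": initial_state(ds, variant),
        "observed": observed_pools(ds),
        "truth": ds.ground_truth_params,
    }


class TestCost:
    def test_self_consistency_on_noise_free_data(self, ler_setup):
        spec = CostSpec(observed=ler_setup["observed"])
        value = cost(ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"],
                     spec, variant=ler_setup["variant"], rtol=1e-8, atol=1e-10)
        assert value <= 1e-10

    def test_hand_summed_residuals(self, ler_setup):
        # displace two starch observations by 0.1 and 0.2 at unit scale
        starch = ler_setup["observed"]["Starch"].as_mean_series()
        shifted = starch.mean.copy()
        shifted[3] += 0.1
        shifted[8] -= 0.2
        spec = CostSpec(observed={"Starch": SampledSeries(starch.times, shifted)},
                        scales={"Starch": 1.0})
        value = cost(ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"],
                     spec, variant=ler_setup["variant"], rtol=1e-8, atol=1e-10)
        assert value == pytest.approx(0.05, abs=1e-6)

    def test_invariant_under_pool_permutation(self, ler_setup):
        obs = ler_setup["observed"]
        spec_a = CostSpec(observed=dict(obs))
        spec_b = CostSpec(observed=dict(reversed(list(obs.items()))))
        args = (ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"])
        assert cost(*args, spec_a, variant=ler_setup["variant"]) == pytest.approx(
            cost(*args, spec_b, variant=ler_setup["variant"]), rel=1e-12
        )

    def test_sc_penalty_vanishes_at_target(self, ler_setup):
        from leafcarbon import simulate

        traj = simulate(ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"],
                        np.arange(0.0, 24.01, 2.0), variant=VARIANTS["08"])
        sc24 = traj.gain("SC", 0.0, 24.0)
        spec = CostSpec(observed=ler_setup["observed"], sc_target=sc24,
                        sc_penalty_weight=50.0)
        with_penalty = cost(ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"],
                            spec, variant=VARIANTS["08"], rtol=1e-8, atol=1e-10)
        assert with_penalty <= 1e-9

    def test_simulation_failure_maps_to_inf(self, ler_setup, monkeypatch):
        import leafcarbon.fitting as fitting

        def boom(*args, **kwargs):
            raise SimulationError("forced failure")

        monkeypatch.setattr(fitting, "simulate", boom)
        spec = CostSpec(observed=ler_setup["observed"])
        value = cost(ler_setup["truth"], ler_setup["forcings"], ler_setup["initial"],
                     spec, variant=ler_setup["variant"])
        assert math.isinf(value)

    def test_rejects_empty_observations(self):
        with pytest.raises(ValueError):
            CostSpec(observed={})


class TestOptimiser:
    def test_quadratic_bowl_minimum_located(self):
        argmin = np.array([0.31, 0.68])

        def bowl(x):
            return float((x[0] - argmin[0]) ** 2 + 2.0 * (x[1] - argmin[1]) ** 2)

        rng = np.random.default_rng(0)
        lo, hi = np.zeros(2), np.ones(2)
        sw = particle_swarm(bowl, lo, hi, rng, swarm_size=20, iterations=60)
        px, pf, _ = pattern_search(bowl, sw.x, sw.f, lo, hi, max_evals=800)
        assert np.max(np.abs(px - argmin)) < 1e-4

    def test_iterates_never_leave_the_box(self):
        seen = []

        def recording(x):
            seen.append(x.copy())
            return float(np.sum((x - 0.2) ** 2))

        rng = np.random.default_rng(1)
        lo, hi = np.zeros(3), np.ones(3)
        sw = particle_swarm(recording, lo, hi, rng, swarm_size=10, iterations=25)
        pattern_search(recording, sw.x, sw.f, lo, hi, max_evals=200)
        pts = np.array(seen)
        assert np.all(pts >= lo - 1e-15) and np.all(pts <= hi + 1e-15)

    def test_box_transform_round_trip(self):
        lo = np.array([0.01, 0.0, 1e-4])
        hi = np.array([100.0, 1.0, 10.0])
        box = _BoxTransform(lo, hi)
        x = np.array([0.9, 0.25, 0.05])
        assert np.allclose(box.to_params(box.from_params(x)), x, rtol=1e-12)
        assert np.allclose(box.to_params(np.zeros(3)), lo, rtol=1e-12)
        assert np.allclose(box.to_params(np.ones(3)), hi, rtol=1e-12)


class TestFit:
    def test_same_seed_reproduces_result(self, ler_setup):
        spec = CostSpec(observed={"Starch": ler_setup["observed"]["Starch"],
                                  "HP": ler_setup["observed"]["HP"]})
        kwargs = dict(
            variant=ler_setup["variant"], params_base=ler_setup["truth"],
            free=("a_e", "ab_hp"), n_runs=2, seed=5, swarm_size=6, iterations=4,
            pattern_max_evals=30,
        )
        a = fit(ler_setup["forcings"], ler_setup["initial"], spec, **kwargs)
        b = fit(ler_setup["forcings"], ler_setup["initial"], spec, **kwargs)
        assert a.per_run_costs == b.per_run_costs
        assert a.best_params == b.best_params
        assert a.cost == min(a.per_run_costs)

    def test_unbounded_free_parameter_rejected(self, ler_setup):
        spec = CostSpec(observed=ler_setup["observed"])
        bad = ler_setup["truth"].with_values(bounds={})
        with pytest.raises(ValueError):
            fit(ler_setup["forcings"], ler_setup["initial"], spec,
                params_base=bad, free=MASS_ACTION_NAMES, n_runs=1)


class TestReporting:
    def test_mean_and_sd_of_repeated_runs(self, ler_setup):
        def result(costs):
            return FitResult(best_params=ler_setup["truth"], cost=min(costs),
                             per_run_costs=list(costs), per_run_params=[],
                             free_names=(), seed=0, n_evaluations=0)

        table = report_cost_table({"a": result([0.1, 0.1, 0.1]), "b": result([0.1, 0.2])})
        assert table.loc["a", "cost_mean"] == pytest.approx(0.1)
        assert table.loc["a", "cost_sd"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["b", "cost_mean"] == pytest.approx(0.15)
        assert table.loc["b", "cost_sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            report_cost_table({})

    def test_best_cost_invariant_enforced(self, ler_setup):
        with pytest.raises(ValueError):
            FitResult(best_params=ler_setup["truth"], cost=0.5,
                      per_run_costs=[0.1, 0.2], per_run_params=[],
                      free_names=(), seed=0, n_evaluations=0)
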