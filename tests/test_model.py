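import numpy as np
import pytest
import sympy
from hypothesis import given, strategies as st

from conftest import brute_force_rates, random_positive_states
from leafcarbon import (
    MERGED_POOLS,
    POOLS,
    VARIANTS,
    ForcingSet,
    ParameterSet,
    SimulationError,
    carbon_balance_residual,
    derivatives_from_rates,
    evaluate_rates,
    ode_rhs,
    simulate,
    table_bounds,
)
from leafcarbon.model import make_rhs, state_from_dict

#: carbon weight of each pool in C6 equivalents (sucrose is a C12 body)
C6_WEIGHTS = np.array([2.0 if n == "Suc" else 1.0 for n in POOLS])


def zero_forcings(r2=0.0, vm_profiles=None):
    zero = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    return ForcingSet(r1=zero, r2=r2, r3=zero, r4=zero, vm_profiles=vm_profiles or {})


def params_with(**values) -> ParameterSet:
    base = {n: 0.0 for n in (
        "r_ca", "a_ba", "ab_hp", "aa_e", "a_e", "hp_c", "hp_mf", "cit_mf", "mf_cit",
        "Vm5", "Vm6", "Vm7", "Vm8",
    )}
    base.update({"km5": 0.5, "km6": 9.0, "km7": 0.15, "km8": 0.6,
                 "Ki6a": 2.0, "Ki6b": 0.5, "Ki7": 1.0, "Ki8": 1.5})
    base.update(values)
    return ParameterSet(**base)


class TestParameterSet:
    def test_midpoint_inside_bounds_validates(self):
        for genotype in ("Ler", "gin2-1"):
            ParameterSet.from_midpoint(table_bounds(genotype)).validate()

    def test_out_of_bounds_value_rejected(self):
        p = ParameterSet.from_midpoint(table_bounds("Ler"))
        with pytest.raises(ValueError, match="km6"):
            p.with_values(km6=200.0).validate()

    def test_bounds_are_well_formed(self):
        for genotype in ("Ler", "gin2-1"):
            for name, (lo, hi) in table_bounds(genotype).items():
                assert 0 <= lo < hi, name

    def test_dict_round_trip_is_lossless(self):
        p = ParameterSet.from_midpoint(table_bounds("gin2-1"))
        assert ParameterSet.from_dict(p.to_dict()) == p


class TestRateLaws:
    def test_plain_michaelis_menten_when_no_inhibitors(self):
        # with zero inhibitors the invertase law collapses to V*S/(Km+S)
        p = params_with(Vm6=80.0, km6=10.0, Ki6a=5.0, Ki6b=5.0)
        state = state_from_dict(dict(HP=0, Starch=0, SC=0, Export=0, Suc=1.0,
                                     Glc=0, Frc=0, Aa=0, Cit=0, MF=0))
        r = evaluate_rates(1.0, state, p, zero_forcings())
        assert r[5] == pytest.approx(80.0 * 1.0 / 11.0, rel=1e-12)  # ≈ 7.2727

    def test_glucokinase_competitive_inhibition(self):
        p = params_with(Vm7=3.0, km7=0.15, Ki7=1.0)
        state = state_from_dict(dict(HP=0, Starch=0, SC=0, Export=0, Suc=0,
                                     Glc=0.5, Frc=0.3, Aa=0, Cit=0, MF=0))
        r = evaluate_rates(1.0, state, p, zero_forcings())
        assert r[6] == pytest.approx(3.0 * 0.5 / (0.15 * 1.3 + 0.5), rel=1e-12)  # ≈ 2.1583

    def test_empty_system_has_no_fluxes(self):
        p = ParameterSet.from_midpoint(table_bounds("Ler"))
        r = evaluate_rates(3.0, np.zeros(10), p, zero_forcings(r2=-28.6))
        assert np.all(r[2:] == 0.0)
        assert r[1] == -28.6  # the scenario constant

    def test_negative_pool_rejected_when_strict(self):
        p = ParameterSet.from_midpoint(table_bounds("Ler"))
        state = np.zeros(10)
        state[4] = -0.5
        with pytest.raises(ValueError, match="Suc"):
            evaluate_rates(0.0, state, p, zero_forcings())

    def test_vm_profile_overrides_constant(self):
        p = params_with(Vm5=10.0, km5=1.0)
        f = zero_forcings(vm_profiles={"SPS": lambda t: 20.0})
        state = state_from_dict(dict(HP=1.0, Starch=0, SC=0, Export=0, Suc=0,
                                     Glc=0, Frc=0, Aa=0, Cit=0, MF=0))
        r = evaluate_rates(0.0, state, p, f)
        assert r[4] == pytest.approx(20.0 * 1.0 / 2.0)

    def test_agrees_with_brute_force_oracle(self, ler_preset, ler_forcings):
        p = ler_preset.truth_params()
        rng = np.random.default_rng(42)
        for state in random_positive_states(rng, 200):
            t = float(rng.random() * 24)
            fast = evaluate_rates(t, state, p, ler_forcings)
            slow = brute_force_rates(t, state, p, ler_forcings)
            np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=0)

    @given(
        suc=st.floats(0.01, 5.0),
        glc=st.floats(0.0, 5.0),
        frc=st.floats(0.0, 5.0),
        extra=st.floats(0.05, 2.0),
    )
    def test_invertase_rate_decreases_with_inhibitors(self, suc, glc, frc, extra):
        p = params_with(Vm6=80.0, km6=10.0, Ki6a=2.0, Ki6b=0.5)
        def r6(g, f):
            state = state_from_dict(dict(HP=0, Starch=0, SC=0, Export=0, Suc=suc,
                                         Glc=g, Frc=f, Aa=0, Cit=0, MF=0))
            return evaluate_rates(0.0, state, p, zero_forcings())[5]
        assert r6(glc + extra, frc) < r6(glc, frc)
        assert r6(glc, frc + extra) < r6(glc, frc)
        # hexokinase laws reduce to plain MM without their inhibitor
        p2 = params_with(Vm7=3.0, km7=0.15, Ki7=1.0, Vm8=7.0, km8=0.6, Ki8=1.5)
        state = state_from_dict(dict(HP=0, Starch=0, SC=0, Export=0, Suc=0,
                                     Glc=glc, Frc=0, Aa=0, Cit=0, MF=0))
        r = evaluate_rates(0.0, state, p2, zero_forcings())
        assert r[6] == pytest.approx(3.0 * glc / (0.15 + glc), rel=1e-12, abs=1e-300)


class TestOdeListing:
    def test_zero_rates_give_zero_derivatives(self):
        assert np.all(derivatives_from_rates(np.zeros(17)) == 0.0)
        assert np.all(derivatives_from_rates(np.zeros(13), VARIANTS["01"]) == 0.0)

    def test_photosynthesis_stoichiometry(self):
        rates = np.zeros(17)
        rates[0] = 600.0  # C1 units
        d = derivatives_from_rates(rates)
        assert d[POOLS.index("HP")] == pytest.approx(100.0)  # 600/6 C6
        others = np.delete(d, POOLS.index("HP"))
        assert np.all(others == 0.0)

    def test_carbon_conservation_symbolic(self):
        r = sympy.symbols("r1:18", positive=True)
        d = derivatives_from_rates(list(r))
        total = sum(sympy.Integer(2) * di if POOLS[i] == "Suc" else di
                    for i, di in enumerate(d))
        assert sympy.simplify(total - (r[0] + r[1]) / 6) == 0

    def test_carbon_conservation_symbolic_merged(self):
        r = sympy.symbols("q1:14", positive=True)
        d = derivatives_from_rates(list(r), VARIANTS["01"])
        total = sum(sympy.Integer(2) * di if MERGED_POOLS[i] == "Suc" else di
                    for i, di in enumerate(d))
        assert sympy.simplify(total - (r[0] + r[1]) / 6) == 0

    def test_carbon_conservation_numeric_random_rates(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            rates = rng.random(17) * 50
            d = derivatives_from_rates(rates)
            assert float(C6_WEIGHTS @ d) == pytest.approx((rates[0] + rates[1]) / 6, rel=1e-12)

    def test_rhs_matches_rate_listing(self, ler_preset, ler_forcings):
        # the solver right-hand side must equal the printed linear
        # combination of the rate laws wherever no depletion guard engages
        p = ler_preset.truth_params()
        rhs = make_rhs(p, ler_forcings, VARIANTS["08"], fast_forcings=False)
        rng = np.random.default_rng(11)
        for state in random_positive_states(rng, 50):
            t = float(rng.random() * 24)
            expected = derivatives_from_rates(evaluate_rates(t, state, p, ler_forcings))
            got = np.array(rhs(t, np.append(state, 0.0)))[:-1]
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_public_ode_rhs_wrapper(self, ler_preset, ler_forcings):
        p = ler_preset.truth_params()
        state = random_positive_states(np.random.default_rng(1), 1)[0]
        d = ode_rhs(8.0, state, p, ler_forcings)
        assert d.shape == (10,)


class TestSimulate:
    def test_closed_system_stays_constant(self):
        p = params_with()
        initial = dict.fromkeys(POOLS, 0.0)
        initial["Starch"] = 50.0
        traj = simulate(p, zero_forcings(), initial, np.linspace(0, 24, 13))
        assert np.allclose(traj.states, traj.states[0], atol=1e-9)
        assert np.allclose(carbon_balance_residual(traj), 0.0, atol=1e-9)

    def test_constant_input_grows_hp_linearly(self):
        p = params_with()
        f = ForcingSet(r1=lambda t: np.full_like(np.asarray(t, float), 600.0),
                       r2=0.0, r3=lambda t: 0.0, r4=lambda t: 0.0)
        initial = dict.fromkeys(POOLS, 0.0)
        traj = simulate(p, f, initial, np.linspace(0, 12, 7), fast_forcings=False)
        assert np.allclose(traj.pool("HP"), 100.0 * traj.t, rtol=1e-6)

    def test_sucrose_cleavage_preserves_carbon(self):
        # invertase only: sucrose (C12) splits into Glc + Frc, total C6 fixed
        p = params_with(Vm6=50.0, km6=9.0, Ki6a=10.0, Ki6b=10.0)
        initial = dict.fromkeys(POOLS, 0.0)
        initial["Suc"] = 2.0
        traj = simulate(p, zero_forcings(), initial, np.linspace(0, 8, 9))
        assert traj.pool("Glc")[-1] > 1.0
        assert np.max(np.abs(carbon_balance_residual(traj))) < 1e-8

    def test_calibrated_preset_outputs_are_monotone(self, ler_truth_trajectory):
        for pool in ("SC", "Export"):
            y = ler_truth_trajectory.pool(pool)
            assert np.all(np.diff(y) >= -1e-9), pool

    def test_negative_initial_pool_rejected(self, ler_preset, ler_forcings):
        initial = dict(ler_preset.initial_pools)
        initial["Suc"] = -1.0
        with pytest.raises(SimulationError, match="Suc"):
            simulate(ler_preset.truth_params(), ler_forcings, initial, np.linspace(0, 24, 5))

    def test_grid_outside_horizon_rejected(self, ler_preset, ler_forcings):
        initial = dict(ler_preset.initial_pools)
        with pytest.raises(ValueError):
            simulate(ler_preset.truth_params(), ler_forcings, initial, np.linspace(0, 30, 5))

    def test_trajectory_frame_is_tidy(self, ler_truth_trajectory):
        frame = ler_truth_trajectory.to_frame()
        assert list(frame.columns) == ["time_h", "pool", "value", "units", "scenario_id"]
        assert set(frame["pool"]) == set(POOLS)
        assert (frame.loc[frame["pool"] == "Suc", "units"] == "umol_C12_per_gFW").all()

    def test_solver_settings_recorded(self, ler_truth_trajectory):
        assert ler_truth_trajectory.rtol == 1e-8
        assert ler_truth_trajectory.atol == 1e-10


class TestVariantLadder:
    def test_preset_flags_follow_the_ladder(self):
        v = VARIANTS
        assert v["01"].starch_switch == "smooth" and v["02"].starch_switch == "strict"
        assert v["02"].respiration_mode == "night_only" and v["03"].respiration_mode == "constant"
        assert v["03"].organic_acid_pools == "merged" and v["04"].organic_acid_pools == "split"
        assert not v["04"].cit_mf_interconversion and v["05"].cit_mf_interconversion
        assert v["06"].vm_splines == ("SPS", "Inv", "GlcK", "FrcK")
        assert v["07"].vm_splines == ("SPS", "Inv")
        assert not v["07"].sc_constraint and v["08"].sc_constraint

    def test_variant_dict_round_trip(self):
        from leafcarbon.model import VariantConfig

        for v in VARIANTS.values():
            assert VariantConfig.from_dict(v.to_dict()) == v

    def test_merged_variant_conserves_carbon(self, ler_preset):
        from leafcarbon.synthetic import truth_forcings

        variant = VARIANTS["03"]
        f = truth_forcings(ler_preset, variant)
        initial = dict(ler_preset.initial_pools)
        initial["CaAa"] = initial.pop("Aa") + initial.pop("Cit") + initial.pop("MF")
        traj = simulate(ler_preset.truth_params(), f, initial,
                        np.linspace(0, 24, 25), variant=variant)
        assert np.max(np.abs(carbon_balance_residual(traj))) < 1e-6
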