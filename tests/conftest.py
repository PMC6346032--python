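import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from leafcarbon import PRESETS, generate  # noqa: E402
from leafcarbon.synthetic import truth_forcings  # noqa: E402


@pytest.fixture(scope="session")
def ler_preset():
    return PRESETS["Ler-control"]


@pytest.fixture(scope="session")
def ler_forcings(ler_preset):
    return truth_forcings(ler_preset)


@pytest.fixture(scope="session")
def ler_noise_free():
    """Noise-free Ler-control dataset (shared; treat as read-only)."""
    return generate("Ler-control", noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def ler_truth_trajectory(ler_noise_free):
    return ler_noise_free.trajectory


def brute_force_rates(t, state, p, forcings):
    """Deliberately naive re-implementation of the printed rate laws.

    Used as the independent oracle for the fast evaluator: every formula is
    written out long-hand from its printed form, one rate per statement.
    """
    HP, Starch, SC, Export, Suc, Glc, Frc, Aa, Cit, MF = [float(x) for x in state]
    cf = p.conc_factor
    hp, suc, glc, frc = HP * cf, Suc * cf, Glc * cf, Frc * cf
    vm = forcings.vm_profiles

    def vmax(enzyme, fallback):
        return float(vm[enzyme](t)) if enzyme in vm else fallback

    Vm5 = vmax("SPS", p.Vm5)
    Vm6 = vmax("Inv", p.Vm6)
    Vm7 = vmax("GlcK", p.Vm7)
    Vm8 = vmax("FrcK", p.Vm8)

    r1 = float(forcings.r1(t))
    r2 = float(forcings.r2)
    r3 = float(forcings.r3(t))
    r4 = float(forcings.r4(t))
    r5 = (Vm5 * hp) / (p.km5 + hp)
    r6 = (Vm6 * suc) / ((p.km6 * (1 + frc / p.Ki6a) + suc) * (1 + glc / p.Ki6b))
    r7 = (Vm7 * glc) / (p.km7 * (1 + frc / p.Ki7) + glc)
    r8 = (Vm8 * frc) / (p.km8 * (1 + glc / p.Ki8) + frc)
    r9 = p.r_ca * Cit
    r10 = p.a_ba * Aa
    r11 = p.ab_hp * HP
    r12 = p.aa_e * Aa
    r13 = p.a_e * Suc
    r14 = p.hp_c * HP
    r15 = p.hp_mf * HP
    r16 = p.cit_mf * Cit
    r17 = p.mf_cit * MF
    return np.array([r1, r2, r3, r4, r5, r6, r7, r8, r9, r10, r11, r12, r13, r14, r15, r16, r17])


def random_positive_states(rng, n):
    """Random admissible states spanning the realistic pool magnitudes.

    Pools are kept above the solver's source-depletion gate thresholds so
    that the guarded right-hand side coincides with the pure rate laws.
    """
    scales = np.array([2.0, 100.0, 50.0, 100.0, 2.0, 3.0, 2.0, 10.0, 8.0, 60.0])
    mins = np.array([0.06, 1.5, 0.0, 0.0, 1e-3, 1e-3, 1e-3, 1e-3, 1e-3, 0.6])
    return rng.random((n, 10)) * scales + mins
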