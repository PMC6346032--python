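"""Synthetic diurnal datasets with known ground truth.

The measured inputs of the study design — whole-rosette net CO2 exchange,
nine metabolite pools sampled every 2 h over 24 h in six replicates, and
maximal activities of the sucrose-cycling enzymes — are emulated here for
the four scenario presets (genotype Ler or gin2-1 × control or high
light). The generator draws a noise-free truth by simulating the final
model under preset forcings and calibrated ground-truth parameters, then
adds multiplicative lognormal replicate noise. Because the truth is known
by construction, every downstream stage (forcing construction, fitting,
allocation analysis) can be tested for recovery.

Preset plateaus, respiration constants and daily structural-carbon
targets carry the study's printed values: net photosynthesis ≈130 µmol
CO2 gFW⁻¹ h⁻¹ under control light for both genotypes, rising to ≈310
(Ler) and ≈330 (gin2-1) under high light; dark respiration −28.6 / −37.5
/ −44.0 / −47.5; daily structural-carbon gains 120 / 100 / 135 / 85 µmol
C6 gFW⁻¹. Ground-truth parameters are calibrated once per preset so the
truth reproduces the study conditions: structural carbon forms almost
exclusively in the light, assimilate export continues day and night, and
daytime export runs higher in the hexokinase-null mutant than in the wild
type (the mutant's sucrose cycling being cut several-fold). The day-2
gas-exchange trace is the day-1 trace scaled so the growth calculator
returns exactly the preset daily target.

The generator aims at structural realism and a known truth, not at
reproducing the unpublished measurements.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from . import growth
from .forcings import (
    DAY_LENGTH_H,
    PERIOD_H,
    ForcingSet,
    SampledSeries,
    build_smoothing_spline,
    photosynthesis_forcing,
    starch_forcings,
)
from .model import (
    POOLS,
    VARIANTS,
    ParameterSet,
    Trajectory,
    VariantConfig,
    simulate,
    table_bounds,
)

#: species written to the metabolite table; the model's malate+fumarate
#: pool is reported as separate malate and fumarate series, as measured
MEASURED_SPECIES = ("Starch", "HP", "Glc", "Frc", "Suc", "Aa", "Cit", "Mal", "Fum")
#: fixed malate share of the combined MF pool used when splitting the truth
MALATE_FRACTION = 0.35
#: model pools with a measured counterpart (SC and Export are unobserved)
OBSERVED_POOLS = ("Starch", "HP", "Glc", "Frc", "Suc", "Aa", "Cit", "MF")

_T13 = np.arange(0.0, 24.1, 2.0)          # the 2-h sampling grid
_T_FINE = np.arange(0.0, 24.001, 0.25)    # truth-trajectory grid
_T_GAS = np.arange(0.0, 24.001, 0.1)      # gas-exchange trace grid


@dataclasses.dataclass(frozen=True)
class ScenarioPreset:
    """One genotype × light-condition bundle of study constants."""

    name: str
    genotype: str                 # "Ler" | "gin2-1"
    light: str                    # "control" | "high_light"
    nps_plateau: float            # µmol CO2 gFW⁻¹ h⁻¹ (net, light phase)
    r2: float                     # µmol CO2 gFW⁻¹ h⁻¹ (dark respiration, ≤0)
    sc_daily_target: float        # µmol C6 gFW⁻¹ per 24 h
    rgt_double: bool              # high-light temperature doubling applied
    starch0: float                # pre-dawn starch, µmol C6 gFW⁻¹
    starch_day_slopes: tuple      # (slope at t=0, slope at t=16), µmol h⁻¹
    starch_night_slopes: tuple    # (slope at t=16, slope at t=24), negative
    initial_pools: Mapping[str, float]
    truth_values: Mapping[str, float]
    gfw2: float = 0.5             # rosette fresh weight after day 2, g
    ramp_h: float = 0.5           # light-on/off ramp of the net CO2 trace

    def bounds(self) -> dict:
        b = table_bounds(self.genotype)
        if self.rgt_double:
            from .model import MASS_ACTION_NAMES, VM_NAMES

            scaled = set(VM_NAMES) | set(MASS_ACTION_NAMES)
            b = {n: ((2 * lo, 2 * hi) if n in scaled else (lo, hi)) for n, (lo, hi) in b.items()}
        return b

    def truth_params(self) -> ParameterSet:
        p = ParameterSet(**self.truth_values, bounds=self.bounds(), rgt_doubled=self.rgt_double)
        p.validate()
        return p

    def midpoint_params(self, rng: np.random.Generator | None = None) -> ParameterSet:
        """Bounds-midpoint parameters, optionally jittered by ±10 %."""
        b = self.bounds()
        p = ParameterSet.from_midpoint(b, rgt_doubled=self.rgt_double)
        if rng is not None:
            values = {}
            for n, (lo, hi) in b.items():
                mid = 0.5 * (lo + hi)
                values[n] = float(np.clip(mid * (1.0 + 0.1 * (2 * rng.random() - 1)), lo, hi))
            p = p.with_values(**values)
        return p


# ---------------------------------------------------------------------------
# calibrated ground-truth parameters (see docs/methods.md for the budget
# analysis behind these values; all lie inside the preset bounds)
# ---------------------------------------------------------------------------

_KINETIC_LER = {
    "km5": 0.1, "km6": 12.9, "km7": 0.2, "km8": 0.6,
    "Ki6a": 2.0, "Ki6b": 0.03, "Ki7": 0.5, "Ki8": 1.5,
    "Vm5": 15.0, "Vm6": 80.0, "Vm7": 3.4, "Vm8": 8.5,
}
_KINETIC_GIN = {
    "km5": 0.1, "km6": 12.5, "km7": 0.3, "km8": 0.8,
    "Ki6a": 2.0, "Ki6b": 0.1, "Ki7": 1.0, "Ki8": 1.5,
    "Vm5": 15.0, "Vm6": 95.0, "Vm7": 0.3, "Vm8": 3.5,
}
_MASS_ACTION_LER_N = {
    "r_ca": 0.45, "a_ba": 0.02, "ab_hp": 10.256, "aa_e": 0.8,
    "a_e": 8.9, "hp_c": 3.0, "hp_mf": 7.9, "cit_mf": 0.15, "mf_cit": 0.03,
}
_MASS_ACTION_GIN_N = {
    "r_ca": 0.45, "a_ba": 0.05, "ab_hp": 6.010, "aa_e": 0.75,
    "a_e": 9.9, "hp_c": 3.0, "hp_mf": 5.8, "cit_mf": 0.15, "mf_cit": 0.03,
}
# high-light ground truths: enzyme capacities follow the temperature
# doubling; the fitted-like mass-action constants are calibrated to the
# high-light carbon budget (daily SC targets 135 / 85) rather than doubled
_MASS_ACTION_LER_HL = {
    "r_ca": 0.9, "a_ba": 0.1, "ab_hp": 6.849, "aa_e": 0.9,
    "a_e": 19.0, "hp_c": 6.0, "hp_mf": 9.0, "cit_mf": 0.3, "mf_cit": 0.06,
}
_MASS_ACTION_GIN_HL = {
    "r_ca": 0.9, "a_ba": 0.12, "ab_hp": 3.327, "aa_e": 1.0,
    "a_e": 19.0, "hp_c": 6.0, "hp_mf": 10.0, "cit_mf": 0.3, "mf_cit": 0.06,
}

_POOLS0_LER_N = {
    "HP": 0.035, "Starch": 30.0, "SC": 0.0, "Export": 0.0,
    "Suc": 0.25, "Glc": 0.1, "Frc": 0.08, "Aa": 0.6, "Cit": 0.1, "MF": 30.0,
}
_POOLS0_GIN_N = {
    "HP": 0.03, "Starch": 30.0, "SC": 0.0, "Export": 0.0,
    "Suc": 0.3, "Glc": 1.5, "Frc": 0.6, "Aa": 0.6, "Cit": 0.1, "MF": 60.0,
}


def _doubled(values: Mapping[str, float]) -> dict:
    from .model import MASS_ACTION_NAMES, VM_NAMES

    scaled = set(VM_NAMES) | set(MASS_ACTION_NAMES)
    return {n: (2 * v if n in scaled else v) for n, v in values.items()}


PRESETS: dict[str, ScenarioPreset] = {
    "Ler-control": ScenarioPreset(
        name="Ler-control", genotype="Ler", light="control",
        nps_plateau=130.0, r2=-28.6, sc_daily_target=120.0, rgt_double=False,
        starch0=30.0, starch_day_slopes=(1.0, 1.4), starch_night_slopes=(-4.1, -4.0),
        initial_pools=_POOLS0_LER_N,
        truth_values={**_KINETIC_LER, **_MASS_ACTION_LER_N},
    ),
    "gin2-control": ScenarioPreset(
        name="gin2-control", genotype="gin2-1", light="control",
        nps_plateau=130.0, r2=-37.5, sc_daily_target=100.0, rgt_double=False,
        starch0=30.0, starch_day_slopes=(1.0, 1.8), starch_night_slopes=(-4.3, -4.0),
        initial_pools=_POOLS0_GIN_N,
        truth_values={**_KINETIC_GIN, **_MASS_ACTION_GIN_N},
    ),
    "Ler-highlight": ScenarioPreset(
        name="Ler-highlight", genotype="Ler", light="high_light",
        nps_plateau=310.0, r2=-44.0, sc_daily_target=135.0, rgt_double=True,
        starch0=30.0, starch_day_slopes=(6.0, 18.0), starch_night_slopes=(-14.0, -10.0),
        initial_pools=_POOLS0_LER_N,
        truth_values={**_doubled(_KINETIC_LER), **_MASS_ACTION_LER_HL},
    ),
    "gin2-highlight": ScenarioPreset(
        name="gin2-highlight", genotype="gin2-1", light="high_light",
        nps_plateau=330.0, r2=-47.5, sc_daily_target=85.0, rgt_double=True,
        starch0=30.0, starch_day_slopes=(6.0, 20.0), starch_night_slopes=(-15.0, -11.0),
        initial_pools=_POOLS0_GIN_N,
        truth_values={**_doubled(_KINETIC_GIN), **_MASS_ACTION_GIN_HL},
    ),
}


# ---------------------------------------------------------------------------
# design curves
# ---------------------------------------------------------------------------

def net_co2_trace(preset: ScenarioPreset, t: np.ndarray) -> np.ndarray:
    """Design net CO2-exchange trace: dark value r2, trapezoidal light phase."""
    t = np.asarray(t, float) % PERIOD_H
    ramp = preset.ramp_h
    plateau, r2 = preset.nps_plateau, preset.r2
    up = r2 + (plateau - r2) * np.clip(t / ramp, 0.0, 1.0)
    down = r2 + (plateau - r2) * np.clip((DAY_LENGTH_H - t) / ramp, 0.0, 1.0)
    trace = np.minimum(up, down)
    return np.where(t < DAY_LENGTH_H, trace, r2)


def starch_design(preset: ScenarioPreset, t: np.ndarray) -> np.ndarray:
    """Design starch course with smooth, photoperiod-bounded turnover.

    The light-phase synthesis rate follows a half-sine profile between the
    edge rate ``starch_day_slopes[0]`` (at dawn and dusk, when
    photosynthesis ramps) and the midday peak ``starch_day_slopes[1]``;
    the dark-phase degradation rate runs linearly from
    ``starch_night_slopes[0]`` at dusk to ``starch_night_slopes[1]`` at
    dawn. All rates stay within the measured slope ranges of the scenario.
    """
    t_raw = np.asarray(t, float)
    t = t_raw % PERIOD_H
    t = np.where((t == 0) & (t_raw > 0), PERIOD_H, t)  # 24 h is dawn-eve, not dawn
    edge, peak = preset.starch_day_slopes
    n0, n1 = preset.starch_night_slopes
    # ∫ edge + (peak-edge)·sin(πt/16) dt
    day_val = preset.starch0 + edge * t + (peak - edge) * (DAY_LENGTH_H / np.pi) * (
        1.0 - np.cos(np.pi * np.minimum(t, DAY_LENGTH_H) / DAY_LENGTH_H)
    )
    s16 = preset.starch0 + edge * DAY_LENGTH_H + (peak - edge) * 2 * DAY_LENGTH_H / np.pi
    tn = t - DAY_LENGTH_H
    night_len = PERIOD_H - DAY_LENGTH_H
    night_val = s16 + n0 * tn - (n0 - n1) * tn**2 / (2 * night_len)
    return np.where(t < DAY_LENGTH_H, day_val, night_val)


def vm_design(preset: ScenarioPreset, enzyme: str, t: np.ndarray) -> np.ndarray:
    """Design diurnal V_m profile: sinusoid inside the measured band.

    Centred on the ground-truth constant for the hexokinase activities so
    that spline-free variants are consistent with the measured series.
    """
    t = np.asarray(t, float)
    p = dict(preset.truth_values)
    centre_amp_phase = {
        # SPS capacity peaks in the night: it is the absorber that keeps the
        # hexose-phosphate pool pinned low while starch is being mobilised
        "SPS": (p["Vm5"], 0.33 * p["Vm5"], 14.0),
        # invertase capacity peaks around midday
        "Inv": (p["Vm6"], 0.24 * p["Vm6"], 8.0),
        "GlcK": (p["Vm7"], 0.15 * p["Vm7"], 4.0),
        "FrcK": (p["Vm8"], 0.15 * p["Vm8"], 4.0),
    }
    centre, amp, phase = centre_amp_phase[enzyme]
    return centre + amp * np.sin(2 * np.pi * (t - phase) / PERIOD_H)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    preset: ScenarioPreset
    ground_truth_params: ParameterSet
    trajectory: Trajectory                  # noise-free truth on a fine grid
    samples: dict                           # species → SampledSeries (replicated)
    vm_series: dict                         # enzyme → SampledSeries (replicated)
    gas_day1: SampledSeries                 # net CO2 trace, replicate mean
    gas_day2: SampledSeries
    seed: int
    noise_cv: float
    n_replicates: int

    @property
    def sc_target(self) -> float:
        return self.preset.sc_daily_target


def truth_forcings(preset: ScenarioPreset, variant: VariantConfig = VARIANTS["08"]) -> ForcingSet:
    """Forcings built from the noise-free design curves of a preset."""
    gas = SampledSeries(_T_GAS, net_co2_trace(preset, _T_GAS), units="umol_CO2/gFW/h", name="net_co2")
    starch = SampledSeries(_T13, starch_design(preset, _T13), units="umol_C6/gFW", name="Starch")
    r1 = photosynthesis_forcing(gas, preset.r2, smoothing=0.0)
    r3, r4 = starch_forcings(starch, mode=variant.starch_switch)
    vm_profiles = {
        enz: build_smoothing_spline((_T13, vm_design(preset, enz, _T13)), smoothing=0.0)
        for enz in variant.vm_splines
    }
    return ForcingSet(r1=r1, r2=preset.r2, r3=r3, r4=r4, vm_profiles=vm_profiles,
                      rgt_doubled=preset.rgt_double)


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.standard_normal(shape) * sigma - sigma**2 / 2)


def generate(
    preset: ScenarioPreset | str,
    params: ParameterSet | str | None = None,
    n_replicates: int = 6,
    noise_cv: float = 0.05,
    seed: int = 0,
    gas_replicates: int = 11,
) -> SyntheticDataset:
    """Generate one scenario's full synthetic dataset.

    ``params=None`` uses the preset's calibrated ground truth (the study
    conditions); ``params="auto"`` draws a bounds-midpoint set jittered by
    the seed; an explicit :class:`ParameterSet` must lie inside the preset
    bounds. Metabolite and V_m series get ``n_replicates`` replicates with
    mean-preserving multiplicative lognormal noise of the given CV; the
    gas-exchange traces are stored as replicate means (their replicate
    count only being metadata here), and day 2 is day 1 uniformly scaled
    so the growth calculator returns the preset's daily structural-carbon
    target exactly.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    if params is None:
        params = preset.truth_params()
    elif isinstance(params, str):
        if params != "auto":
            raise ValueError(f"unknown params mode {params!r}")
        params = preset.midpoint_params(rng)
    else:
        params = dataclasses.replace(params, bounds=preset.bounds())
        params.validate()

    variant = VARIANTS["08"]
    forcings = truth_forcings(preset, variant)
    initial = dict(preset.initial_pools)
    initial["Starch"] = preset.starch0
    traj = simulate(params, forcings, initial, _T_FINE, variant=variant,
                    rtol=1e-8, atol=1e-10, scenario_id=preset.name)

    # replicate metabolite samples on the 2-h grid (9 measured species;
    # the combined MF pool is reported as separate malate and fumarate)
    idx = np.searchsorted(traj.t, _T13)
    samples: dict[str, SampledSeries] = {}
    for species in MEASURED_SPECIES:
        if species == "Mal":
            mean = MALATE_FRACTION * traj.pool("MF")[idx]
        elif species == "Fum":
            mean = (1 - MALATE_FRACTION) * traj.pool("MF")[idx]
        else:
            mean = traj.pool(species)[idx]
        noise = _lognormal_factors(rng, noise_cv, (n_replicates, _T13.size))
        samples[species] = SampledSeries(
            _T13, mean[None, :] * noise,
            units="umol_C12/gFW" if species == "Suc" else "umol_C6/gFW",
            name=species,
        )

    vm_series: dict[str, SampledSeries] = {}
    for enz in ("SPS", "Inv", "GlcK", "FrcK"):
        mean = vm_design(preset, enz, _T13)
        noise = _lognormal_factors(rng, noise_cv, (n_replicates, _T13.size))
        vm_series[enz] = SampledSeries(_T13, mean[None, :] * noise,
                                       units="umol/gFW/h", name=enz)

    day1 = net_co2_trace(preset, _T_GAS)
    scale = 1.0 / (1.0 - preset.sc_daily_target / growth.fw_to_umol_c6(1.0))
    gas_day1 = SampledSeries(_T_GAS, day1, units="umol_CO2/gFW/h", name="net_co2_day1")
    gas_day2 = SampledSeries(_T_GAS, day1 * scale, units="umol_CO2/gFW/h", name="net_co2_day2")

    return SyntheticDataset(
        preset=preset,
        ground_truth_params=params,
        trajectory=traj,
        samples=samples,
        vm_series=vm_series,
        gas_day1=gas_day1,
        gas_day2=gas_day2,
        seed=seed,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
    )


def export_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write a dataset as plain-text files that round-trip losslessly.

    Produces the metabolite table (13 time points × replicates × 9
    species), the two-day gas-exchange table, the V_m table, the preset
    as YAML and the ground-truth parameters as JSON.
    """
    import json
    from pathlib import Path

    import yaml

    from . import io as lcio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": lcio.write_timeseries(ds.samples, directory / "metabolites.tsv"),
        "vm": lcio.write_timeseries(ds.vm_series, directory / "vm.tsv"),
        "gas_exchange": lcio.write_gas_exchange(ds.gas_day1, ds.gas_day2,
                                                directory / "gas_exchange.tsv"),
    }
    preset_payload = dataclasses.asdict(ds.preset)
    preset_payload.update(seed=ds.seed, noise_cv=ds.noise_cv, n_replicates=ds.n_replicates)
    (directory / "preset.yaml").write_text(yaml.safe_dump(preset_payload, sort_keys=True))
    (directory / "ground_truth.json").write_text(
        json.dumps(ds.ground_truth_params.to_dict(), indent=2, sort_keys=True)
    )
    paths["preset"] = directory / "preset.yaml"
    paths["ground_truth"] = directory / "ground_truth.json"
    return paths


# ---------------------------------------------------------------------------
# estimation-side views of a dataset (what the fitting pipeline consumes)
# ---------------------------------------------------------------------------

def observed_pools(ds_or_samples) -> dict:
    """Model-pool series from the measured species (Mal + Fum → MF)."""
    samples = ds_or_samples.samples if isinstance(ds_or_samples, SyntheticDataset) else ds_or_samples
    out = {}
    for pool in OBSERVED_POOLS:
        if pool == "MF":
            mal, fum = samples["Mal"], samples["Fum"]
            if not np.array_equal(mal.times, fum.times):
                raise ValueError("malate and fumarate series on different grids")
            out["MF"] = SampledSeries(mal.times, mal.values + fum.values,
                                      units=mal.units, name="MF")
        else:
            out[pool] = samples[pool]
    return out


def fit_forcings(ds: SyntheticDataset, variant: VariantConfig = VARIANTS["08"]) -> ForcingSet:
    """Forcings as the estimation pipeline would build them from the data:
    gas-exchange spline for r1, gated starch-derivative rates, V_m splines
    through the replicate means of the enzymes the variant pins."""
    r1 = photosynthesis_forcing(ds.gas_day1, ds.preset.r2, smoothing=0.0)
    obs = observed_pools(ds)
    r3, r4 = starch_forcings(obs["Starch"].as_mean_series(), mode=variant.starch_switch)
    vm_profiles = {
        enz: build_smoothing_spline(ds.vm_series[enz], smoothing=0.0)
        for enz in variant.vm_splines
    }
    return ForcingSet(r1=r1, r2=ds.preset.r2, r3=r3, r4=r4, vm_profiles=vm_profiles,
                      rgt_doubled=ds.preset.rgt_double)


def initial_state(ds: SyntheticDataset, variant: VariantConfig = VARIANTS["08"]) -> dict:
    """Pre-dawn initial pools from the t = 0 sample means; the cumulative
    outputs SC and Export start at zero by convention."""
    obs = observed_pools(ds)
    pools = {name: float(obs[name].mean[0]) for name in OBSERVED_POOLS}
    pools["SC"] = 0.0
    pools["Export"] = 0.0
    if variant.organic_acid_pools == "merged":
        pools["CaAa"] = pools.pop("Aa") + pools.pop("Cit") + pools.pop("MF")
    return pools
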