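"""Kinetic core of the diurnal leaf carbon-allocation model.

The final model tracks ten pools, all in carbon-equivalent units per gram
fresh weight (µmol gFW⁻¹): hexose phosphates (HP, the central hub), starch
(glucosyl C6 units), shoot structural carbon (SC, cumulative), assimilate
export to the sink (Export, cumulative), sucrose (counted as C12
molecules), glucose, fructose, amino acids, citrate, and a combined
malate + fumarate pool (MF). Seventeen reaction rates connect them:

* r1, r2 — photosynthesis and respiration (C1 units, from forcings);
* r3, r4 — starch synthesis/degradation (C6, from forcings);
* r5–r8  — Michaelis–Menten rate laws for SPS, invertase (competitive
  fructose and noncompetitive glucose inhibition), glucokinase and
  fructokinase (mutual competitive hexose inhibition);
* r9–r17 — first-order mass-action interconversions (Cit→Aa, Aa→SC,
  HP→SC, Aa→Export, Suc→Export, HP→Cit, HP→MF, Cit→MF, MF→Cit).

Stoichiometric factors translate between carbon bodies: 1/6 on r1 and r2
(C1→C6), 1/2 on r5 (two C6 per sucrose) and 2 on r13 (two C6 export bodies
per sucrose). Summing all pool derivatives (sucrose counted twice) leaves
only (r1 + r2)/6 — total carbon changes solely through gas exchange, which
is the conservation diagnostic checked by :func:`carbon_balance_residual`.

The model ladder of increasing complexity (variants 01–08) is encoded by
:class:`VariantConfig`: early variants merge the organic-acid and
amino-acid pools into one CaAa pool, use a gradual starch switch or
night-only respiration; later variants split citrate from malate/fumarate,
add their interconversion, pin sucrose-cycling V_m values to measured
spline profiles, and finally constrain the daily structural-carbon gain.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

from .forcings import DAY_LENGTH_H, PERIOD_H, ForcingSet

logger = logging.getLogger("leafcarbon")

#: pool order of the final (split-pool) model state vector
POOLS = ("HP", "Starch", "SC", "Export", "Suc", "Glc", "Frc", "Aa", "Cit", "MF")
#: pool order of the reduced early-variant state vector
MERGED_POOLS = ("HP", "Starch", "SC", "Export", "Suc", "Glc", "Frc", "CaAa")
#: units per pool (sucrose is counted as C12 molecules)
POOL_UNITS = {name: "umol_C6_per_gFW" for name in POOLS + MERGED_POOLS}
POOL_UNITS["Suc"] = "umol_C12_per_gFW"

#: the nine first-order rate constants fitted in the mass-balance part
MASS_ACTION_NAMES = (
    "r_ca", "a_ba", "ab_hp", "aa_e", "a_e", "hp_c", "hp_mf", "cit_mf", "mf_cit",
)
#: maximal-rate parameter per sucrose-cycling enzyme
ENZYME_VM = {"SPS": "Vm5", "Inv": "Vm6", "GlcK": "Vm7", "FrcK": "Vm8"}
KM_KI_NAMES = ("km5", "km6", "km7", "km8", "Ki6a", "Ki6b", "Ki7", "Ki8")
VM_NAMES = ("Vm5", "Vm6", "Vm7", "Vm8")
KINETIC_NAMES = KM_KI_NAMES + VM_NAMES + MASS_ACTION_NAMES


class SimulationError(RuntimeError):
    """Integration failure, carrying the last accepted time and pool name."""

    def __init__(self, message: str, t_last: float | None = None, pool: str | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.pool = pool


def table_bounds(genotype: str = "Ler") -> dict[str, tuple[float, float]]:
    """Box constraints for every free parameter of the kinetic model.

    Michaelis/inhibition constants are in mM, maximal rates in
    µmol h⁻¹ gFW⁻¹, mass-action constants in h⁻¹. The hexokinase-null
    mutant gin2-1 has wider hexokinase K_M ranges, a near-zero glucokinase
    capacity and a higher invertase capacity than the Ler wild type.
    """
    if genotype not in ("Ler", "gin2-1"):
        raise ValueError(f"unknown genotype {genotype!r}")
    gin = genotype == "gin2-1"
    return {
        "km5": (0.1, 2.0),
        "km6": (7.0, 13.0),
        "km7": (0.01, 2.0) if gin else (0.1, 0.2),
        "km8": (0.1, 5.0) if gin else (0.1, 3.0),
        "Ki6a": (0.001, 10.0),
        "Ki6b": (0.001, 10.0),
        "Ki7": (0.01, 10.0),
        "Ki8": (0.001, 10.0),
        "Vm5": (10.0, 20.0),
        "Vm6": (70.0, 120.0) if gin else (60.0, 100.0),
        "Vm7": (0.0, 1.0) if gin else (2.0, 4.0),
        "Vm8": (2.0, 5.0) if gin else (5.0, 10.0),
        "r_ca": (0.01, 100.0),
        "a_ba": (0.0, 1.0),
        "ab_hp": (0.0001, 100.0),
        "aa_e": (0.0001, 10.0),
        "a_e": (0.0001, 10.0),
        "hp_c": (0.01, 10.0),
        "hp_mf": (0.01, 10.0),
        "cit_mf": (0.01, 10.0),
        "mf_cit": (0.01, 10.0),
    }


@dataclasses.dataclass
class ParameterSet:
    """Kinetic constants of the model with their box constraints.

    Concentrations in the rate laws are obtained from pool sizes
    (µmol gFW⁻¹) via ``conc_factor`` (mM per µmol gFW⁻¹); the default of
    1.0 corresponds to ≈1 mL of aqueous phase per gram fresh weight.
    """

    km5: float
    km6: float
    km7: float
    km8: float
    Ki6a: float
    Ki6b: float
    Ki7: float
    Ki8: float
    Vm5: float
    Vm6: float
    Vm7: float
    Vm8: float
    r_ca: float
    a_ba: float
    ab_hp: float
    aa_e: float
    a_e: float
    hp_c: float
    hp_mf: float
    cit_mf: float
    mf_cit: float
    conc_factor: float = 1.0
    bounds: dict = dataclasses.field(default_factory=dict)
    rgt_doubled: bool = False

    # -- construction -----------------------------------------------------
    @classmethod
    def from_midpoint(cls, bounds: Mapping[str, tuple[float, float]], **extra) -> "ParameterSet":
        """Parameter set at the midpoint of every bound interval."""
        values = {k: 0.5 * (lo + hi) for k, (lo, hi) in bounds.items()}
        return cls(**values, bounds=dict(bounds), **extra)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise if any value lies outside its bound interval or is negative."""
        for name in KINETIC_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} is not finite")
            if value < 0:
                raise ValueError(f"parameter {name} = {value} is negative")
            if name in self.bounds:
                lo, hi = self.bounds[name]
                if not (lo - 1e-12 <= value <= hi + 1e-12):
                    raise ValueError(
                        f"parameter {name} = {value} outside bounds [{lo}, {hi}]"
                    )

    # -- vector access (for the optimiser) --------------------------------
    def get_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_values(self, **updates) -> "ParameterSet":
        return dataclasses.replace(self, **updates)

    def with_vector(self, names: Sequence[str], values: Sequence[float]) -> "ParameterSet":
        return dataclasses.replace(self, **{n: float(v) for n, v in zip(names, values)})

    def bounds_arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in names], dtype=float)
        hi = np.array([self.bounds[n][1] for n in names], dtype=float)
        return lo, hi

    # -- temperature scaling ----------------------------------------------
    def with_rgt_doubling(self) -> "ParameterSet":
        """Double maximal rates and mass-action constants (Q10 ≈ 2 rule)."""
        if self.rgt_doubled:
            raise ValueError("temperature doubling already applied; reset before re-applying")
        scaled_names = VM_NAMES + MASS_ACTION_NAMES
        updates = {n: 2.0 * getattr(self, n) for n in scaled_names}
        new_bounds = {
            n: ((2.0 * lo, 2.0 * hi) if n in scaled_names else (lo, hi))
            for n, (lo, hi) in self.bounds.items()
        }
        return dataclasses.replace(self, **updates, bounds=new_bounds, rgt_doubled=True)

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "values": {n: float(getattr(self, n)) for n in KINETIC_NAMES},
            "conc_factor": float(self.conc_factor),
            "bounds": {n: [float(lo), float(hi)] for n, (lo, hi) in self.bounds.items()},
            "rgt_doubled": bool(self.rgt_doubled),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterSet":
        return cls(
            **{n: float(v) for n, v in payload["values"].items()},
            conc_factor=float(payload.get("conc_factor", 1.0)),
            bounds={n: (float(lo), float(hi)) for n, (lo, hi) in payload.get("bounds", {}).items()},
            rgt_doubled=bool(payload.get("rgt_doubled", False)),
        )


@dataclasses.dataclass(frozen=True)
class VariantConfig:
    """Flags selecting one rung of the model-complexity ladder (01–08)."""

    variant_id: str
    starch_switch: str = "strict"          # "smooth" | "strict"
    respiration_mode: str = "constant"     # "night_only" | "constant"
    organic_acid_pools: str = "split"      # "merged" | "split"
    cit_mf_interconversion: bool = True
    vm_splines: tuple = ("SPS", "Inv")
    sc_constraint: bool = False

    def __post_init__(self):
        if self.starch_switch not in ("smooth", "strict"):
            raise ValueError(f"bad starch_switch {self.starch_switch!r}")
        if self.respiration_mode not in ("night_only", "constant"):
            raise ValueError(f"bad respiration_mode {self.respiration_mode!r}")
        if self.organic_acid_pools not in ("merged", "split"):
            raise ValueError(f"bad organic_acid_pools {self.organic_acid_pools!r}")

    @property
    def pools(self) -> tuple:
        return MERGED_POOLS if self.organic_acid_pools == "merged" else POOLS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vm_splines"] = list(self.vm_splines)
        return d

    @classmethod
    def from_dict(cls, payload: Mapping) -> "VariantConfig":
        payload = dict(payload)
        payload["vm_splines"] = tuple(payload.get("vm_splines", ()))
        return cls(**payload)


#: the model ladder: each step adds one refinement over its predecessor
VARIANTS: dict[str, VariantConfig] = {
    # 01 basic: merged CaAa pool, gradual starch switch, night respiration
    "01": VariantConfig("01", "smooth", "night_only", "merged", False, (), False),
    # 02 strict on/off starch switch at the light/dark transitions
    "02": VariantConfig("02", "strict", "night_only", "merged", False, (), False),
    # 03 respiration runs at the dark rate throughout the cycle
    "03": VariantConfig("03", "strict", "constant", "merged", False, (), False),
    # 04 CaAa split into citrate and malate/fumarate (plus amino acids)
    "04": VariantConfig("04", "strict", "constant", "split", False, (), False),
    # 05 TCA-like interconversion between Cit and MF
    "05": VariantConfig("05", "strict", "constant", "split", True, (), False),
    # 06 measured V_m spline profiles for all four sucrose-cycling enzymes
    "06": VariantConfig("06", "strict", "constant", "split", True, ("SPS", "Inv", "GlcK", "FrcK"), False),
    # 07 V_m splines for SPS and invertase only (hexokinase kept free)
    "07": VariantConfig("07", "strict", "constant", "split", True, ("SPS", "Inv"), False),
    # 08 final: daily structural-carbon gain constrains the fit
    "08": VariantConfig("08", "strict", "constant", "split", True, ("SPS", "Inv"), True),
}


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def evaluate_rates(t, state, params: ParameterSet, forcings: ForcingSet, strict: bool = True):
    """All seventeen reaction rates at one time and state (final model).

    Returns an array ``r`` with ``r[0]`` = r1 … ``r[16]`` = r17, each in
    µmol h⁻¹ gFW⁻¹ of its carbon unit (r1/r2: C1, r6/r13: C12 sucrose,
    the rest C6). Enzymes listed in ``forcings.vm_profiles`` take their
    maximal rate from the measured spline profile, the others from the
    constant in ``params``. With ``strict=True`` a meaningfully negative
    pool raises; otherwise negative substrates are clamped to zero (the
    guard used inside the solver).
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError("forcings undefined: t is not finite")
    state = np.asarray(state, dtype=float)
    if state.shape != (len(POOLS),):
        raise ValueError(f"state must have {len(POOLS)} pools {POOLS}")
    if strict and state.min() < -1e-9:
        pool = POOLS[int(state.argmin())]
        raise ValueError(f"negative pool {pool} = {state.min()} at t = {t}")
    HP, _starch, _sc, _exp, Suc, Glc, Frc, Aa, Cit, MF = np.maximum(state, 0.0)

    p = params
    cf = p.conc_factor
    hp, suc, glc, frc = HP * cf, Suc * cf, Glc * cf, Frc * cf
    vm = forcings.vm_profiles
    Vm5 = float(vm["SPS"](t)) if "SPS" in vm else p.Vm5
    Vm6 = float(vm["Inv"](t)) if "Inv" in vm else p.Vm6
    Vm7 = float(vm["GlcK"](t)) if "GlcK" in vm else p.Vm7
    Vm8 = float(vm["FrcK"](t)) if "FrcK" in vm else p.Vm8

    r = np.empty(17)
    r[0] = float(forcings.r1(t))
    r[1] = forcings.r2
    r[2] = float(forcings.r3(t))
    r[3] = float(forcings.r4(t))
    # SPS: plain Michaelis-Menten in HP
    r[4] = Vm5 * hp / (p.km5 + hp)
    # invertase: fructose competitive, glucose noncompetitive
    r[5] = Vm6 * suc / ((p.km6 * (1.0 + frc / p.Ki6a) + suc) * (1.0 + glc / p.Ki6b))
    # glucokinase: fructose competitive
    r[6] = Vm7 * glc / (p.km7 * (1.0 + frc / p.Ki7) + glc)
    # fructokinase: glucose competitive
    r[7] = Vm8 * frc / (p.km8 * (1.0 + glc / p.Ki8) + frc)
    # first-order mass balances
    r[8] = p.r_ca * Cit
    r[9] = p.a_ba * Aa
    r[10] = p.ab_hp * HP
    r[11] = p.aa_e * Aa
    r[12] = p.a_e * Suc
    r[13] = p.hp_c * HP
    r[14] = p.hp_mf * HP
    r[15] = p.cit_mf * Cit
    r[16] = p.mf_cit * MF
    return r


def derivatives_from_rates(rates, variant: VariantConfig | None = None):
    """Pool derivatives as the exact linear combination of the rates.

    Accepts numeric or symbolic rate entries; ``rates[i]`` is r(i+1). For
    the merged early variants the reduced topology uses indices 8–13 for
    (CaAa→SC, HP→SC, CaAa→Export, Suc→Export, HP→CaAa) in the order
    r10, r11, r12, r13, r14 of the full model.
    """
    r = list(rates)
    merged = variant is not None and variant.organic_acid_pools == "merged"
    if merged:
        (r1, r2, r3, r4, r5, r6, r7, r8, r10, r11, r12, r13, r14) = r
        return np.array(
            [
                r1 / 6 - r3 - r4 - r5 + r7 + r8 - r14 - r11,   # HP
                r3 + r4,                                        # Starch
                r10 + r11,                                      # SC
                2 * r13 + r12,                                  # Export
                r5 / 2 - r6 - r13,                              # Suc (C12)
                r6 - r7,                                        # Glc
                r6 - r8,                                        # Frc
                r14 + r2 / 6 - r10 - r12,                       # CaAa
            ],
            dtype=object if not _numeric(r) else float,
        )
    (r1, r2, r3, r4, r5, r6, r7, r8, r9, r10, r11, r12, r13, r14, r15, r16, r17) = r
    return np.array(
        [
            r1 / 6 - r3 - r4 - r5 + r7 + r8 - r15 - r14 - r11,  # HP
            r3 + r4,                                             # Starch
            r10 + r11,                                           # SC ("BM")
            2 * r13 + r12,                                       # Export
            r5 / 2 - r6 - r13,                                   # Suc (C12)
            r6 - r7,                                             # Glc
            r6 - r8,                                             # Frc
            r9 - r10 - r12,                                      # Aa
            r14 - r9 - r16 + r17,                                # Cit
            r15 + r2 / 6 + r16 - r17,                            # MF
        ],
        dtype=object if not _numeric(r) else float,
    )


def _numeric(seq) -> bool:
    return all(isinstance(x, (int, float, np.floating, np.integer)) for x in seq)


def ode_rhs(t, state, params: ParameterSet, forcings: ForcingSet,
            variant: VariantConfig = VARIANTS["08"]):
    """Pool derivatives d(state)/dt at one (t, state) under a variant."""
    rhs = make_rhs(params, forcings, variant, fast_forcings=False)
    return np.asarray(rhs(t, np.append(np.asarray(state, dtype=float), 0.0)))[:-1]


# ---------------------------------------------------------------------------
# fast right-hand side used by the solver
# ---------------------------------------------------------------------------

_FAST_DT = 0.005  # h; forcing lookup-table resolution inside the solver

# source-pool thresholds (µmol gFW⁻¹) below which the data-driven sink
# rates are smoothly throttled; above the threshold the rates are exact
_GATE_HP = 0.05      # starch synthesis draws on hexose phosphates
_GATE_STARCH = 1.0   # starch degradation draws on the starch pool
_GATE_RESP = 0.5     # respiration draws on the malate/fumarate (or CaAa) pool


def _smoothstep(x: float, delta: float) -> float:
    """C¹ ramp: 0 at x ≤ 0, 1 at x ≥ delta (exact outside the ramp)."""
    if x >= delta:
        return 1.0
    if x <= 0.0:
        return 0.0
    u = x / delta
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d(x: float, delta: float) -> float:
    """Derivative of :func:`_smoothstep` with respect to x."""
    if x >= delta or x <= 0.0:
        return 0.0
    u = x / delta
    return 6.0 * u * (1.0 - u) / delta


class _Table:
    """Linear-interpolation table for one forcing on [0, 24] h."""

    __slots__ = ("vals", "inv_dt", "n")

    def __init__(self, fn, dt: float = _FAST_DT):
        grid = np.arange(0.0, PERIOD_H + dt / 2, dt)
        self.vals = np.asarray(fn(grid), dtype=float)
        self.inv_dt = 1.0 / dt
        self.n = self.vals.size - 1

    def __call__(self, t: float) -> float:
        x = (t % PERIOD_H) * self.inv_dt
        i = int(x)
        if i >= self.n:
            return self.vals[self.n]
        frac = x - i
        v = self.vals
        return v[i] * (1.0 - frac) + v[i + 1] * frac


def make_rhs(params: ParameterSet, forcings: ForcingSet, variant: VariantConfig,
             fast_forcings: bool = True):
    """Build the ODE right-hand side for the solver.

    The returned function maps ``(t, y)`` to derivatives, where ``y``
    stacks the pool vector and one auxiliary quadrature state accumulating
    the gross carbon input ∫(r1 + r2)/6 dt (used by the conservation
    diagnostic). Substrates of a rate are clamped at zero when the pool has
    been driven negative, and the data-driven starch rates stop when their
    source pool (HP for synthesis, starch for degradation) is exhausted;
    clamping events are counted on the function's ``clamps`` attribute and
    logged after integration.

    With ``fast_forcings=True`` the forcing callables are pre-sampled on a
    0.005-h grid and evaluated by linear interpolation, which keeps the
    per-step cost low during optimisation.
    """
    p = params
    cf = p.conc_factor
    vm = {k: v for k, v in forcings.vm_profiles.items() if k in variant.vm_splines}

    if fast_forcings:
        # lookup tables are immutable once built, so cache them on the
        # forcing set: repeated simulations during optimisation reuse them
        cache = forcings.__dict__.setdefault("_table_cache", {})

        def table(name, fn):
            if name not in cache:
                cache[name] = _Table(fn)
            return cache[name]

        r1f = table("r1", forcings.r1)
        r3f = table("r3", forcings.r3)
        r4f = table("r4", forcings.r4)
        vm = {k: table(f"vm:{k}", v) for k, v in vm.items()}
    else:
        r1f, r3f, r4f = forcings.r1, forcings.r3, forcings.r4
    r2 = forcings.r2
    night_only = variant.respiration_mode == "night_only"
    vm5f, vm6f = vm.get("SPS"), vm.get("Inv")
    vm7f, vm8f = vm.get("GlcK"), vm.get("FrcK")
    km5, km6, km7, km8 = p.km5, p.km6, p.km7, p.km8
    Ki6a, Ki6b, Ki7, Ki8 = p.Ki6a, p.Ki6b, p.Ki7, p.Ki8
    r_ca, a_ba, ab_hp = p.r_ca, p.a_ba, p.ab_hp
    aa_e, a_e, hp_c = p.aa_e, p.a_e, p.hp_c
    hp_mf, cit_mf, mf_cit = p.hp_mf, p.cit_mf, p.mf_cit
    merged = variant.organic_acid_pools == "merged"
    interconv = variant.cit_mf_interconversion

    counter = {"clamps": 0}

    def common_sugars(t, HP, St, Suc, Glc, Frc):
        if HP < 0.0 or St < 0.0 or Suc < 0.0 or Glc < 0.0 or Frc < 0.0:
            counter["clamps"] += 1
            HP = HP if HP > 0.0 else 0.0
            St = St if St > 0.0 else 0.0
            Suc = Suc if Suc > 0.0 else 0.0
            Glc = Glc if Glc > 0.0 else 0.0
            Frc = Frc if Frc > 0.0 else 0.0
        # data-driven starch rates stop smoothly when their source pool runs
        # out (HP for synthesis, starch for degradation); the C1 smoothstep
        # keeps the RHS integrable when a pool is driven towards zero
        r3 = float(r3f(t)) * _smoothstep(HP, _GATE_HP)
        r4 = float(r4f(t)) * _smoothstep(St, _GATE_STARCH)
        r1 = float(r1f(t))
        hp, suc, glc, frc = HP * cf, Suc * cf, Glc * cf, Frc * cf
        Vm5 = float(vm5f(t)) if vm5f is not None else p.Vm5
        Vm6 = float(vm6f(t)) if vm6f is not None else p.Vm6
        Vm7 = float(vm7f(t)) if vm7f is not None else p.Vm7
        Vm8 = float(vm8f(t)) if vm8f is not None else p.Vm8
        r5 = Vm5 * hp / (km5 + hp)
        r6 = Vm6 * suc / ((km6 * (1.0 + frc / Ki6a) + suc) * (1.0 + glc / Ki6b))
        r7 = Vm7 * glc / (km7 * (1.0 + frc / Ki7) + glc)
        r8 = Vm8 * frc / (km8 * (1.0 + glc / Ki8) + frc)
        return HP, Suc, Glc, Frc, r1, r3, r4, r5, r6, r7, r8

    if merged:

        def rhs(t, y):
            HP, St, _SC, _Exp, Suc, Glc, Frc, CaAa = y[:8]
            HP, Suc, Glc, Frc, r1, r3, r4, r5, r6, r7, r8 = common_sugars(
                t, HP, St, Suc, Glc, Frc
            )
            CaAa = CaAa if CaAa > 0.0 else 0.0
            r2_eff = 0.0 if (night_only and (t % PERIOD_H) < DAY_LENGTH_H) else r2
            r2_eff *= _smoothstep(CaAa, _GATE_RESP)
            r10 = a_ba * CaAa
            r11 = ab_hp * HP
            r12 = aa_e * CaAa
            r13 = a_e * Suc
            r14 = hp_c * HP
            return (
                r1 / 6.0 - r3 - r4 - r5 + r7 + r8 - r14 - r11,
                r3 + r4,
                r10 + r11,
                2.0 * r13 + r12,
                r5 / 2.0 - r6 - r13,
                r6 - r7,
                r6 - r8,
                r14 + r2_eff / 6.0 - r10 - r12,
                (r1 + r2_eff) / 6.0,
            )

    else:

        def rhs(t, y):
            HP, St, _SC, _Exp, Suc, Glc, Frc, Aa, Cit, MF = y[:10]
            HP, Suc, Glc, Frc, r1, r3, r4, r5, r6, r7, r8 = common_sugars(
                t, HP, St, Suc, Glc, Frc
            )
            Aa = Aa if Aa > 0.0 else 0.0
            Cit = Cit if Cit > 0.0 else 0.0
            MF = MF if MF > 0.0 else 0.0
            r2_eff = 0.0 if (night_only and (t % PERIOD_H) < DAY_LENGTH_H) else r2
            r2_eff *= _smoothstep(MF, _GATE_RESP)
            r9 = r_ca * Cit
            r10 = a_ba * Aa
            r11 = ab_hp * HP
            r12 = aa_e * Aa
            r13 = a_e * Suc
            r14 = hp_c * HP
            r15 = hp_mf * HP
            if interconv:
                r16 = cit_mf * Cit
                r17 = mf_cit * MF
            else:
                r16 = r17 = 0.0
            return (
                r1 / 6.0 - r3 - r4 - r5 + r7 + r8 - r15 - r14 - r11,
                r3 + r4,
                r10 + r11,
                2.0 * r13 + r12,
                r5 / 2.0 - r6 - r13,
                r6 - r7,
                r6 - r8,
                r9 - r10 - r12,
                r14 - r9 - r16 + r17,
                r15 + r2_eff / 6.0 + r16 - r17,
                (r1 + r2_eff) / 6.0,
            )

    def _sugar_partials(t, HP, St, Suc, Glc, Frc):
        """Partial derivatives of r3–r8 wrt their substrate pools."""
        hp, suc, glc, frc = HP * cf, Suc * cf, Glc * cf, Frc * cf
        Vm5 = float(vm5f(t)) if vm5f is not None else p.Vm5
        Vm6 = float(vm6f(t)) if vm6f is not None else p.Vm6
        Vm7 = float(vm7f(t)) if vm7f is not None else p.Vm7
        Vm8 = float(vm8f(t)) if vm8f is not None else p.Vm8
        d3 = float(r3f(t)) * _smoothstep_d(HP, _GATE_HP)
        d4 = float(r4f(t)) * _smoothstep_d(St, _GATE_STARCH)
        d5 = cf * Vm5 * km5 / (km5 + hp) ** 2
        D1 = km6 * (1.0 + frc / Ki6a) + suc
        D2 = 1.0 + glc / Ki6b
        r6 = Vm6 * suc / (D1 * D2)
        d6s = cf * Vm6 * (D1 - suc) / (D1 * D1 * D2)
        d6f = -r6 * cf * (km6 / Ki6a) / D1
        d6g = -r6 * cf / (Ki6b * D2)
        den7 = km7 * (1.0 + frc / Ki7) + glc
        r7 = Vm7 * glc / den7
        d7g = cf * Vm7 * km7 * (1.0 + frc / Ki7) / den7 ** 2
        d7f = -r7 * cf * (km7 / Ki7) / den7
        den8 = km8 * (1.0 + glc / Ki8) + frc
        r8 = Vm8 * frc / den8
        d8f = cf * Vm8 * km8 * (1.0 + glc / Ki8) / den8 ** 2
        d8g = -r8 * cf * (km8 / Ki8) / den8
        return d3, d4, d5, d6s, d6f, d6g, d7g, d7f, d8f, d8g

    if merged:

        def jac(t, y):
            HP, St, _SC, _Exp, Suc, Glc, Frc, CaAa = (max(v, 0.0) for v in y[:8])
            d3, d4, d5, d6s, d6f, d6g, d7g, d7f, d8f, d8g = _sugar_partials(
                t, HP, St, Suc, Glc, Frc
            )
            r2g = 0.0 if (night_only and (t % PERIOD_H) < DAY_LENGTH_H) else r2
            d2 = r2g * _smoothstep_d(CaAa, _GATE_RESP)
            J = np.zeros((9, 9))
            J[0, 0] = -d3 - d5 - (hp_c + ab_hp)
            J[0, 1] = -d4
            J[0, 5] = d7g + d8g
            J[0, 6] = d7f + d8f
            J[1, 0] = d3
            J[1, 1] = d4
            J[2, 0] = ab_hp
            J[2, 7] = a_ba
            J[3, 4] = 2.0 * a_e
            J[3, 7] = aa_e
            J[4, 0] = d5 / 2.0
            J[4, 4] = -d6s - a_e
            J[4, 5] = -d6g
            J[4, 6] = -d6f
            J[5, 4] = d6s
            J[5, 5] = d6g - d7g
            J[5, 6] = d6f - d7f
            J[6, 4] = d6s
            J[6, 5] = d6g - d8g
            J[6, 6] = d6f - d8f
            J[7, 0] = hp_c
            J[7, 7] = -(a_ba + aa_e) + d2 / 6.0
            J[8, 7] = d2 / 6.0
            return J

    else:

        def jac(t, y):
            HP, St, _SC, _Exp, Suc, Glc, Frc, Aa, Cit, MF = (max(v, 0.0) for v in y[:10])
            d3, d4, d5, d6s, d6f, d6g, d7g, d7f, d8f, d8g = _sugar_partials(
                t, HP, St, Suc, Glc, Frc
            )
            r2g = 0.0 if (night_only and (t % PERIOD_H) < DAY_LENGTH_H) else r2
            d2 = r2g * _smoothstep_d(MF, _GATE_RESP)
            cmf = cit_mf if interconv else 0.0
            mfc = mf_cit if interconv else 0.0
            J = np.zeros((11, 11))
            J[0, 0] = -d3 - d5 - (ab_hp + hp_c + hp_mf)
            J[0, 1] = -d4
            J[0, 5] = d7g + d8g
            J[0, 6] = d7f + d8f
            J[1, 0] = d3
            J[1, 1] = d4
            J[2, 0] = ab_hp
            J[2, 7] = a_ba
            J[3, 4] = 2.0 * a_e
            J[3, 7] = aa_e
            J[4, 0] = d5 / 2.0
            J[4, 4] = -d6s - a_e
            J[4, 5] = -d6g
            J[4, 6] = -d6f
            J[5, 4] = d6s
            J[5, 5] = d6g - d7g
            J[5, 6] = d6f - d7f
            J[6, 4] = d6s
            J[6, 5] = d6g - d8g
            J[6, 6] = d6f - d8f
            J[7, 7] = -(a_ba + aa_e)
            J[7, 8] = r_ca
            J[8, 0] = hp_c
            J[8, 8] = -(r_ca + cmf)
            J[8, 9] = mfc
            J[9, 0] = hp_mf
            J[9, 8] = cmf
            J[9, 9] = -mfc + d2 / 6.0
            J[10, 9] = d2 / 6.0
            return J

    rhs.clamps = counter
    rhs.jac = jac
    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Trajectory:
    """Simulated pool values on a time grid, with solver provenance."""

    t: np.ndarray
    states: np.ndarray          # (n_times, n_pools)
    gross_input: np.ndarray     # cumulative ∫(r1 + r2_applied)/6 dt, µmol C6
    pool_names: tuple
    variant: VariantConfig
    rtol: float
    atol: float
    scenario_id: str | None = None
    clamp_count: int = 0

    def pool(self, name: str) -> np.ndarray:
        return self.states[:, self.pool_names.index(name)]

    def total_carbon(self) -> np.ndarray:
        """Total C6-equivalents (sucrose counted twice, being C12)."""
        weights = np.array([2.0 if n == "Suc" else 1.0 for n in self.pool_names])
        return self.states @ weights

    def gain(self, name: str, t0: float, t1: float) -> float:
        """Increase of a (cumulative) pool between two grid times."""
        y = self.pool(name)
        return float(np.interp(t1, self.t, y) - np.interp(t0, self.t, y))

    def to_frame(self):
        """Tidy table: time_h, pool, value, units, scenario_id."""
        import pandas as pd

        rows = []
        for j, name in enumerate(self.pool_names):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.t,
                        "pool": name,
                        "value": self.states[:, j],
                        "units": POOL_UNITS[name],
                        "scenario_id": self.scenario_id or "",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def state_from_dict(pools: Mapping[str, float], variant: VariantConfig = VARIANTS["08"]) -> np.ndarray:
    """State vector in canonical pool order from a name→value mapping."""
    names = variant.pools
    missing = set(names) - set(pools)
    if missing:
        raise ValueError(f"missing pools: {sorted(missing)}")
    return np.array([float(pools[n]) for n in names])


def simulate(
    params: ParameterSet,
    forcings: ForcingSet,
    initial,
    t_grid,
    variant: VariantConfig = VARIANTS["08"],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    scenario_id: str | None = None,
    fast_forcings: bool = True,
    neg_tol: float = 1e-3,
) -> Trajectory:
    """Integrate the model over one diurnal cycle.

    The stiff-capable LSODA solver is restarted at the light/dark
    transition (the forcings are non-smooth there). ``initial`` is a pool
    mapping or a vector in canonical order; cumulative pools (SC, Export)
    conventionally start at zero. Raises :class:`SimulationError` on solver
    failure or when a pool is driven below ``-neg_tol``.
    """
    if isinstance(initial, Mapping):
        y0 = state_from_dict(initial, variant)
    else:
        y0 = np.asarray(initial, dtype=float).copy()
    names = variant.pools
    if y0.shape != (len(names),):
        raise ValueError(f"initial state must have {len(names)} pools {names}")
    if y0.min() < 0:
        raise SimulationError(
            f"negative initial pool {names[int(y0.argmin())]}", pool=names[int(y0.argmin())]
        )
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be an increasing 1-d array")
    if t_grid[0] < -1e-9 or t_grid[-1] > PERIOD_H + 1e-9:
        raise ValueError("t_grid must lie within the 0-24 h forcing horizon")

    rhs = make_rhs(params, forcings, variant, fast_forcings=fast_forcings)
    breaks = [t_grid[0]]
    if t_grid[0] < DAY_LENGTH_H < t_grid[-1]:
        breaks.append(DAY_LENGTH_H)
    breaks.append(t_grid[-1])

    y = np.append(y0, 0.0)  # auxiliary gross-input quadrature state
    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        pts = t_grid[(t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)]
        t_eval = np.unique(np.concatenate([pts, [a, b]]))
        sol, info = odeint(
            rhs, y, t_eval, Dfun=rhs.jac, tfirst=True, rtol=rtol, atol=atol,
            full_output=True, printmessg=False, mxstep=100000,
        )
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"solver failed in [{a}, {b}]: {info['message']}",
                t_last=float(info["tcur"][-1]) if len(info.get("tcur", [])) else a,
            )
        y = sol[-1]
        keep = np.isin(t_eval, pts)
        for tt, yy in zip(t_eval[keep], sol[keep]):
            if not out_t or tt > out_t[-1] + 1e-12:
                out_t.append(float(tt))
                out_y.append(yy)

    states = np.array(out_y)
    clamp_count = rhs.clamps["clamps"]
    if clamp_count:
        logger.info("simulate: %d negative-pool clamping events in the RHS", clamp_count)
    body = states[:, :-1]
    if body.min() < -neg_tol:
        idx = np.unravel_index(int(body.argmin()), body.shape)
        raise SimulationError(
            f"pool {names[idx[1]]} driven to {body.min():.3g} at t = {out_t[idx[0]]:.2f} h",
            t_last=out_t[idx[0]],
            pool=names[idx[1]],
        )
    return Trajectory(
        t=np.array(out_t),
        states=body,
        gross_input=states[:, -1],
        pool_names=names,
        variant=variant,
        rtol=rtol,
        atol=atol,
        scenario_id=scenario_id,
        clamp_count=clamp_count,
    )


def carbon_balance_residual(traj: Trajectory) -> np.ndarray:
    """Closed-budget diagnostic: totalC6(t) − totalC6(0) − ∫(r1+r2)/6 dt.

    Every interconversion rate cancels from the total-carbon balance, so
    the residual is zero up to solver tolerance for any admissible run.
    """
    total = traj.total_carbon()
    return total - total[0] - (traj.gross_input - traj.gross_input[0])
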