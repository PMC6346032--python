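"""Time-dependent inputs of the diurnal leaf-carbon model.

All forcings live on a 24-h clock with light-on at t = 0 h: the leaf is
illuminated for t in [0, 16) h and dark for t in [16, 24) h, matching a
16 h / 8 h long-day regime with sampling starting immediately before
light-on.

Four kinds of forcing are built here:

* the gross photosynthesis rate ``r1(t)`` (µmol CO2 gFW⁻¹ h⁻¹, ≥ 0, zero in
  the dark), recovered from a measured *net* CO2-exchange trace by
  subtracting the constant dark respiration ``r2`` during the light phase;
* the constant respiration rate ``r2`` (≤ 0, a scenario constant);
* the starch synthesis/degradation rates ``r3(t)`` / ``r4(t)``, obtained as
  the first derivative of a (monotone, shape-preserving) interpolation of
  the measured starch time course — synthesis gated to the light phase with
  positive sign, degradation gated to the dark phase with negative sign;
* smoothing-spline profiles of maximal enzyme reaction rates (V_m) for the
  sucrose-cycling enzymes SPS, invertase, glucokinase and fructokinase.

The high-light scenarios double all enzymatic capacities following the
Q10 ≈ 2 temperature rule (:func:`apply_rgt_doubling`).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator, make_smoothing_spline

logger = logging.getLogger("leafcarbon")

#: hours of light per 24-h cycle (light-on at t = 0)
DAY_LENGTH_H = 16.0
#: length of the diurnal cycle in hours
PERIOD_H = 24.0
#: enzymes of the sucrose cycle whose V_m may be supplied as a time profile
SUCROSE_ENZYMES = ("SPS", "Inv", "GlcK", "FrcK")


def is_light(t):
    """Light schedule: True during the 16-h photoperiod, False in the dark."""
    return np.asarray(t) % PERIOD_H < DAY_LENGTH_H


@dataclasses.dataclass
class SampledSeries:
    """Replicated diurnal measurements on a common time grid.

    Parameters
    ----------
    times
        Sampling times in hours, strictly increasing (typically 13 points on
        a 2-h grid covering one diurnal cycle).
    values
        Measurements, shape ``(n_replicates, n_times)`` or ``(n_times,)``
        for a single (or already averaged) series.
    units, name
        Metadata carried through I/O.
    """

    times: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError(f"series {self.name!r}: need a 1-d time grid with >=2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"series {self.name!r}: times must be strictly increasing")
        if self.values.ndim == 1:
            self.values = self.values[None, :]
        if self.values.shape[1] != self.times.size:
            raise ValueError(
                f"series {self.name!r}: values shape {self.values.shape} does not "
                f"match {self.times.size} time points"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.name!r}: non-finite entries")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Replicate mean at each time point."""
        return self.values.mean(axis=0)

    def as_mean_series(self) -> "SampledSeries":
        return SampledSeries(self.times, self.mean, units=self.units, name=self.name)


def build_smoothing_spline(series, smoothing: float | None = None) -> Callable:
    """Smoothing spline through the replicate means of a diurnal series.

    Parameters
    ----------
    series
        A :class:`SampledSeries` or a ``(times, values)`` pair.
    smoothing
        Regularisation weight ``lam`` of the penalised spline. ``None``
        selects it by generalised cross-validation; ``0`` returns the
        interpolating natural cubic spline through the means.

    Returns
    -------
    callable
        A C²-smooth function of time on the sampled interval. Identical
        inputs produce identical splines (the construction is deterministic).
    """
    if isinstance(series, SampledSeries):
        t, y = series.times, series.mean
    else:
        t, y = series
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim > 1:
            y = y.mean(axis=0)
    if t.size < 4:
        raise ValueError("smoothing spline needs at least 4 time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("smoothing spline input contains non-finite values")
    lam = None if smoothing is None else float(smoothing)
    return make_smoothing_spline(t, y, lam=lam)


def starch_forcings(
    starch_series: SampledSeries,
    mode: str = "strict",
) -> tuple[Callable, Callable]:
    """Starch synthesis and degradation rates from a measured starch course.

    The light-phase and dark-phase samples are interpolated *separately*
    with a shape-preserving (PCHIP) interpolant; its first derivative gives
    the synthesis rate r3 (positive, light only) and the degradation rate r4
    (negative, dark only). Synthesis during the night and degradation during
    the day are zero.

    Parameters
    ----------
    starch_series
        Starch pool (µmol C6 glucosyl units gFW⁻¹) covering [0, 24] h.
    mode
        ``"strict"`` (final model): the light-phase and dark-phase samples
        are interpolated separately and hard-gated at the transitions, so
        r3(t)·r4(t) = 0 for every t and the switch between synthesis and
        degradation is instantaneous. ``"smooth"`` (basic model variant):
        one interpolant through all samples, split by the sign of its
        derivative only — the turnover then glides through zero around the
        light/dark transition, which starves the hexose-phosphate pool of
        carbon right after lights-off and produces the strong HP deflection
        that motivated the strict switch.
    """
    if mode not in ("strict", "smooth"):
        raise ValueError(f"unknown starch switch mode {mode!r}")
    t = starch_series.times
    y = starch_series.mean
    if t[0] > 1e-9 or t[-1] < PERIOD_H - 1e-9:
        raise ValueError("starch series must cover the full 0-24 h horizon")
    full = PchipInterpolator(t, y)
    t_off = DAY_LENGTH_H

    if mode == "smooth":
        d_full = full.derivative()

        def r3(tt):
            tt = np.asarray(tt, dtype=float) % PERIOD_H
            return np.maximum(d_full(tt), 0.0)

        def r4(tt):
            tt = np.asarray(tt, dtype=float) % PERIOD_H
            return np.minimum(d_full(tt), 0.0)

        return r3, r4

    day_mask = t <= t_off + 1e-9
    night_mask = t >= t_off - 1e-9
    td, yd = t[day_mask], y[day_mask]
    tn, yn = t[night_mask], y[night_mask]
    if abs(td[-1] - t_off) > 1e-9:  # ensure the transition knot exists
        td = np.append(td, t_off)
        yd = np.append(yd, full(t_off))
    if abs(tn[0] - t_off) > 1e-9:
        tn = np.insert(tn, 0, t_off)
        yn = np.insert(yn, 0, full(t_off))
    d_day = PchipInterpolator(td, yd).derivative()
    d_night = PchipInterpolator(tn, yn).derivative()

    def r3(tt):
        tt = np.asarray(tt, dtype=float) % PERIOD_H
        val = np.maximum(d_day(np.clip(tt, 0.0, t_off)), 0.0)
        return np.where(tt < t_off, val, 0.0)

    def r4(tt):
        tt = np.asarray(tt, dtype=float) % PERIOD_H
        val = np.minimum(d_night(np.clip(tt, t_off, PERIOD_H)), 0.0)
        return np.where(tt >= t_off, val, 0.0)

    return r3, r4


def photosynthesis_forcing(
    net_series: SampledSeries, r2: float, smoothing: float | None = None
) -> Callable:
    """Gross photosynthesis r1(t) from a measured net CO2-exchange trace.

    The measured net flux in the dark equals the respiration r2, so the
    gross input is defined as net − r2 during the light phase and 0 in the
    dark; r1 + r2 then reproduces the measured net exchange throughout.
    The trace is smoothed with a spline before the split, and the result is
    clipped at zero (net flux transiently below r2 carries no gross input).
    """
    if r2 > 0:
        raise ValueError("respiration constant r2 must be <= 0 (carbon sink)")
    spline = build_smoothing_spline(net_series, smoothing=smoothing)

    def r1(tt):
        tt = np.asarray(tt, dtype=float) % PERIOD_H
        gross = np.maximum(spline(tt) - r2, 0.0)
        return np.where(is_light(tt), gross, 0.0)

    return r1


def vm_profile(series: SampledSeries, smoothing: float | None = None) -> Callable:
    """Smoothing-spline profile of a measured maximal reaction rate (V_m)."""
    return build_smoothing_spline(series, smoothing=smoothing)


@dataclasses.dataclass
class ForcingSet:
    """Bundle of all time-dependent inputs needed by the rate laws.

    Attributes
    ----------
    r1
        Gross photosynthesis, µmol CO2 gFW⁻¹ h⁻¹ (C1 units), ≥ 0, 0 in dark.
    r2
        Constant respiration, µmol CO2 gFW⁻¹ h⁻¹, ≤ 0.
    r3, r4
        Starch synthesis (≥ 0, light only) and degradation (≤ 0, dark only),
        µmol C6 gFW⁻¹ h⁻¹.
    vm_profiles
        Optional per-enzyme time profiles for V_m (splined "measured"
        activities); enzymes not present fall back to the constant V_m of
        the parameter set.
    light
        Photoperiod schedule.
    """

    r1: Callable
    r2: float
    r3: Callable
    r4: Callable
    vm_profiles: Mapping[str, Callable] = dataclasses.field(default_factory=dict)
    light: Callable = is_light
    rgt_doubled: bool = False

    def __post_init__(self) -> None:
        if self.r2 > 0:
            raise ValueError("respiration constant r2 must be <= 0")
        unknown = set(self.vm_profiles) - set(SUCROSE_ENZYMES)
        if unknown:
            raise ValueError(f"unknown enzymes in vm_profiles: {sorted(unknown)}")

    def gross_input(self, t) -> np.ndarray:
        """r1(t) + r2 in C1 units (the only terms changing total carbon)."""
        return np.asarray(self.r1(t)) + self.r2


def apply_rgt_doubling(obj, high_light: bool = True):
    """Double enzymatic capacities for the ~10 °C warmer high-light regime.

    Following the Q10 ≈ 2 reaction-rate/temperature rule, all maximal
    reaction rates (V_m values, bounds and time profiles) and all
    mass-action rate constants (values and bounds) are multiplied by two;
    Michaelis and inhibition constants are unchanged. A marker prevents the
    doubling from being applied twice; with ``high_light=False`` the object
    is returned unchanged.
    """
    if not high_light:
        return obj
    if getattr(obj, "rgt_doubled", False):
        raise ValueError("temperature doubling already applied; reset before re-applying")
    if isinstance(obj, ForcingSet):
        doubled = {name: _scaled(profile, 2.0) for name, profile in obj.vm_profiles.items()}
        return dataclasses.replace(obj, vm_profiles=doubled, rgt_doubled=True)
    if hasattr(obj, "with_rgt_doubling"):  # ParameterSet
        return obj.with_rgt_doubling()
    raise TypeError(f"cannot apply temperature doubling to {type(obj).__name__}")


def _scaled(profile: Callable, factor: float) -> Callable:
    def scaled(t):
        return factor * np.asarray(profile(t))

    return scaled
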