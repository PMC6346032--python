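"""Tabular I/O, run configuration and the end-to-end pipeline.

All on-disk formats are plain text: tab-separated tables with a header
line and '.' decimals for time series, YAML for parameter sets and
variants, JSON for fit results and run manifests. Every artifact embeds
the seed and a hash of the configuration that produced it, so equal
hashes imply equal numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcings import SampledSeries
from .model import ParameterSet, VariantConfig, VARIANTS, POOLS, MERGED_POOLS

logger = logging.getLogger("leafcarbon")

#: recognised series names and their units in time-series files
SERIES_REGISTRY = {
    "Starch": "umol_C6/gFW",
    "HP": "umol_C6/gFW",
    "Glc": "umol_C6/gFW",
    "Frc": "umol_C6/gFW",
    "Suc": "umol_C12/gFW",
    "Aa": "umol_C6/gFW",
    "Cit": "umol_C6/gFW",
    "Mal": "umol_C6/gFW",
    "Fum": "umol_C6/gFW",
    "MF": "umol_C6/gFW",
    "CaAa": "umol_C6/gFW",
    "SC": "umol_C6/gFW",
    "Export": "umol_C6/gFW",
    "SPS": "umol/gFW/h",
    "Inv": "umol/gFW/h",
    "GlcK": "umol/gFW/h",
    "FrcK": "umol/gFW/h",
}


# ---------------------------------------------------------------------------
# time-series tables
# ---------------------------------------------------------------------------

def write_timeseries(series: dict, path) -> Path:
    """Write replicated series as a tidy TSV (time_h, replicate, pool, value)."""
    rows = []
    for name in series:
        s = series[name]
        for rep in range(s.n_replicates):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": s.times,
                        "replicate": rep + 1,
                        "pool": name,
                        "value": s.values[rep],
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)[["time_h", "replicate", "pool", "value"]]
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_timeseries(path) -> dict:
    """Read a tidy TSV back into per-pool :class:`SampledSeries`.

    Rejects empty files, unknown series names and duplicated
    (time, replicate, pool) rows; replicate structure is preserved.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty time-series file") from None
    required = {"time_h", "replicate", "pool", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    unknown = set(frame["pool"]) - set(SERIES_REGISTRY)
    if unknown:
        raise ValueError(f"{path}: unknown series names {sorted(unknown)}")
    dup = frame.duplicated(subset=["time_h", "replicate", "pool"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicated row (time_h={row['time_h']}, "
            f"replicate={row['replicate']}, pool={row['pool']})"
        )
    out = {}
    for name, sub in frame.groupby("pool", sort=False):
        wide = sub.pivot(index="replicate", columns="time_h", values="value")
        if wide.isna().any().any():
            raise ValueError(f"{path}: series {name!r} has missing (time, replicate) cells")
        times = np.asarray(wide.columns, dtype=float)
        out[name] = SampledSeries(times, wide.to_numpy(dtype=float),
                                  units=SERIES_REGISTRY[name], name=str(name))
    return out


def write_gas_exchange(day1: SampledSeries, day2: SampledSeries, path) -> Path:
    frames = []
    for day, s in ((1, day1), (2, day2)):
        frames.append(pd.DataFrame({"time_h": s.times, "day": day, "value": s.mean}))
    pd.concat(frames, ignore_index=True).to_csv(
        Path(path), sep="\t", index=False, float_format="%.10g"
    )
    return Path(path)


def read_gas_exchange(path) -> tuple[SampledSeries, SampledSeries]:
    frame = pd.read_csv(Path(path), sep="\t")
    out = []
    for day in (1, 2):
        sub = frame[frame["day"] == day].sort_values("time_h")
        if sub.empty:
            raise ValueError(f"{path}: missing day-{day} trace")
        out.append(
            SampledSeries(sub["time_h"].to_numpy(float), sub["value"].to_numpy(float),
                          units="umol_CO2/gFW/h", name=f"net_co2_day{day}")
        )
    return out[0], out[1]


def write_trajectory(traj, path) -> Path:
    traj.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
    return Path(path)


# ---------------------------------------------------------------------------
# parameters / variants (lossless YAML round trip)
# ---------------------------------------------------------------------------

def write_params(params: ParameterSet, path) -> Path:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
    return Path(path)


def read_params(path) -> ParameterSet:
    return ParameterSet.from_dict(yaml.safe_load(Path(path).read_text()))


def write_variant(variant: VariantConfig, path) -> Path:
    Path(path).write_text(yaml.safe_dump(variant.to_dict(), sort_keys=True))
    return Path(path)


def read_variant(path) -> VariantConfig:
    return VariantConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """One reproducible pipeline run (generate → fit → report)."""

    preset: str = "Ler-control"
    variant: str = "08"
    seed: int = 0
    n_replicates: int = 6
    noise_cv: float = 0.05
    n_runs: int = 1
    swarm_size: int = 20
    iterations: int = 40
    pattern_max_evals: int = 800
    free_params: tuple | None = None
    out_dir: str = "leafcarbon_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["free_params"] = list(self.free_params) if self.free_params else None
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline for one scenario and write all artifacts.

    Stages: synthetic-data generation, forcing construction, truth
    simulation with the carbon-balance diagnostic, bound-constrained
    fitting, and the structural-carbon gain report. Artifacts land in
    ``config.out_dir`` together with a manifest recording the seed, the
    configuration hash and per-stage wall times.
    """
    from . import synthetic
    from .fitting import CostSpec, fit, report_cost_table
    from .growth import growth_input_from_traces, sc_gain_report
    from .model import carbon_balance_residual, simulate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.variant not in VARIANTS:
        raise ValueError(f"unknown variant {config.variant!r}")
    variant = VARIANTS[config.variant]
    stages = []
    artifacts: dict = {"out_dir": str(out)}

    def stage(name):
        stages.append({"stage": name, "t_start": time.time()})
        logger.info("pipeline stage: %s", name)

    def done(**scalars):
        stages[-1]["wall_s"] = round(time.time() - stages[-1].pop("t_start"), 3)
        stages[-1].update(scalars)

    try:
        stage("generate")
        ds = synthetic.generate(config.preset, n_replicates=config.n_replicates,
                                noise_cv=config.noise_cv, seed=config.seed)
        synthetic.export_dataset(ds, out)
        done(n_samples=sum(s.values.size for s in ds.samples.values()))

        stage("forcings")
        forcings = synthetic.fit_forcings(ds, variant)
        initial = synthetic.initial_state(ds, variant)
        done()

        stage("simulate")
        grid = np.arange(0.0, 24.001, 0.25)
        truth_traj = ds.trajectory
        write_trajectory(truth_traj, out / "trajectory_truth.tsv")
        resid = carbon_balance_residual(truth_traj)
        np.savetxt(out / "carbon_balance_residual.tsv",
                   np.column_stack([truth_traj.t, resid]), delimiter="\t",
                   header="time_h\tresidual_umolC6", comments="")
        done(max_abs_residual=float(np.max(np.abs(resid))))

        stage("fit")
        spec = CostSpec(observed=synthetic.observed_pools(ds), sc_target=ds.sc_target)
        result = fit(
            forcings, initial, spec, variant=variant,
            params_base=ds.preset.midpoint_params(), free=config.free_params,
            n_runs=config.n_runs, seed=config.seed,
            swarm_size=config.swarm_size, iterations=config.iterations,
            pattern_max_evals=config.pattern_max_evals,
        )
        (out / "fit_result.json").write_text(json.dumps(
            {
                "best_cost": result.cost,
                "per_run_costs": result.per_run_costs,
                "free": list(result.free_names),
                "seed": result.seed,
                "best_params": result.best_params.to_dict(),
            }, indent=2))
        table = report_cost_table({f"{config.preset}/{config.variant}": result})
        table.to_csv(out / "cost_table.tsv", sep="\t")
        fitted_traj = simulate(result.best_params, forcings, initial, grid,
                               variant=variant, scenario_id=config.preset)
        write_trajectory(fitted_traj, out / "trajectory_fitted.tsv")
        done(best_cost=result.cost)

        stage("sc-gain")
        ginp = growth_input_from_traces(ds.gas_day1.times, ds.gas_day1.mean,
                                        ds.gas_day2.times, ds.gas_day2.mean,
                                        gfw2=ds.preset.gfw2)
        report = sc_gain_report(ginp)
        (out / "sc_gain.json").write_text(json.dumps(report, indent=2))
        done(sc_gain=report["sc_gain_umol_c6_per_gfw"])
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stages[-1]['stage']!r}: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": _package_version(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    artifacts["fit_result"] = result
    artifacts["dataset"] = ds
    return artifacts


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("leafcarbon")
    except PackageNotFoundError:
        return "unknown"
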