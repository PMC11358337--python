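"""Scenario runners and output writers.

Three study designs are provided: a single forcing run to (approximate)
periodic state; a heterotroph-ablation contrast (identical configuration
with and without the heterotroph inoculum), which probes organic-acid
accumulation and pH regulation; and a four-season sweep over the built-in
presets, which probes the water-activity dependence of daily growth.
All outputs are deterministic: the model contains no randomness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import Config, RunConfig, write_resolved_config
from .environment import SEASON_PRESETS, EnvironmentalForcing, make_diel_forcing, read_forcing_table
from .model import Trajectory, detect_periodic_state, simulate


def build_forcing(cfg: Config) -> EnvironmentalForcing:
    env = cfg.environment
    if env.forcing_csv:
        return read_forcing_table(env.forcing_csv)
    return make_diel_forcing(env.season_preset(), env.resolution_h)


def run_single(cfg: Config, forcing: EnvironmentalForcing | None = None,
               initial=None) -> Trajectory:
    forcing = forcing if forcing is not None else build_forcing(cfg)
    return simulate(forcing, cfg.model_params(),
                    initial=initial or cfg.initial,
                    n_days=cfg.run.n_days, grid_h=cfg.run.grid_h,
                    rtol=cfg.run.rtol, method=cfg.run.method)


def trajectory_summary(traj: Trajectory, periodic_tol: float = 1e-3) -> dict:
    """Per-run summary: periodicity, growth, composition, pH and a_w stats."""
    df = traj.derived_frame()
    per_day = int(round(24.0 / (traj.times[1] - traj.times[0])))
    last = df.iloc[-per_day:] if len(df) > per_day else df
    summary = {
        "extinct": traj.extinct,
        "final_composition": traj.composition_fractions(),
        "daily_mean_pH": float(last["pH"].mean()),
        "daily_min_pH": float(last["pH"].min()),
        "daily_max_pH": float(last["pH"].max()),
        "daily_mean_aw": float(last["a_w"].mean()),
        "daily_min_aw": float(last["a_w"].min()),
        "daily_max_aw": float(last["a_w"].max()),
        "daily_mean_S_TOA": float(last["S_TOA"].mean()),
    }
    try:
        summary.update(detect_periodic_state(traj, periodic_tol))
    except ValueError:
        summary.update({"periodic": False, "day_reached": None,
                        "growth_rate_per_day": float("nan")})
    return summary


@dataclass
class ScenarioResult:
    """Named scenario with per-variant trajectories and summaries."""

    scenario: str
    trajectories: dict[str, Trajectory]
    summaries: dict[str, dict]
    metrics: dict = field(default_factory=dict)


def run_scenario(cfg: Config, scenario: str) -> ScenarioResult:
    """Run one of ``single_day``, ``ablation`` or ``seasons``."""
    tol = cfg.run.periodic_tol
    if scenario == "single_day":
        traj = run_single(cfg)
        return ScenarioResult(scenario, {"default": traj},
                              {"default": trajectory_summary(traj, tol)})

    if scenario == "ablation":
        forcing = build_forcing(cfg)
        with_h = run_single(cfg, forcing)
        initial_no_h = dataclasses.replace(cfg.initial, f_MH=0.0)
        without_h = run_single(cfg, forcing, initial=initial_no_h)
        trajs = {"with_heterotrophs": with_h, "without_heterotrophs": without_h}
        sums = {k: trajectory_summary(v, tol) for k, v in trajs.items()}
        metrics = {
            "delta_mean_S_TOA": (sums["without_heterotrophs"]["daily_mean_S_TOA"]
                                 - sums["with_heterotrophs"]["daily_mean_S_TOA"]),
            "delta_min_pH": (sums["without_heterotrophs"]["daily_min_pH"]
                             - sums["with_heterotrophs"]["daily_min_pH"]),
        }
        return ScenarioResult(scenario, trajs, sums, metrics)

    if scenario == "seasons":
        trajs, sums = {}, {}
        for name in SEASON_PRESETS:
            season_cfg = dataclasses.replace(
                cfg, environment=dataclasses.replace(
                    cfg.environment, preset=name, forcing_csv=None))
            trajs[name] = run_single(season_cfg)
            sums[name] = trajectory_summary(trajs[name], tol)
        growth = {k: v["growth_rate_per_day"] for k, v in sums.items()}
        metrics = {"growth_per_day": growth,
                   "mean_aw": {k: v["daily_mean_aw"] for k, v in sums.items()}}
        return ScenarioResult(scenario, trajs, sums, metrics)

    raise ValueError(f"unknown scenario {scenario!r}; "
                     "choose single_day, ablation or seasons")


def write_outputs(traj: Trajectory, outdir: str | Path,
                  cfg: Config | None = None,
                  periodic_tol: float = 1e-3) -> dict[str, Path]:
    """Write states.csv, rates.csv, summary.json and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    states = traj.derived_frame()
    paths["states"] = outdir / "states.csv"
    states.to_csv(paths["states"], index=False, float_format="%.10g")

    rates = traj.rates_frame()
    paths["rates"] = outdir / "rates.csv"
    rates.to_csv(paths["rates"], index=False, float_format="%.10g")

    summary = trajectory_summary(traj, periodic_tol)
    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)

    if cfg is not None:
        paths["config"] = outdir / "resolved_config.yaml"
        write_resolved_config(cfg, paths["config"])
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
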