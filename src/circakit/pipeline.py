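"""Declarative, reproducible analysis runs.

A run is described by a YAML document with a global seed and a list of steps;
each step either simulates a recording or analyses a previously produced CSV.
Everything a run writes (data products, a log, a machine-readable summary, a
copy of the effective config) is deterministic given the config and seed: the
summary JSON is byte-identical across repeated runs.

Per-step RNG streams are derived from the global seed and the step index, so
inserting a step does not silently reseed later ones within the same index.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import actogram, biolum, circular, periodogram, reentrainment, simulate, spectral
from .series import LightSchedule, read_series_csv, write_series_csv

__all__ = ["ConfigError", "run_pipeline", "derive_seed"]


class ConfigError(ValueError):
    """A configuration problem with an actionable message."""


def derive_seed(master_seed: int, stream: int) -> int:
    """Deterministic per-stream seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


_SIM_PARAMS = {
    "activity": simulate.ActivitySimParams,
    "biolum": simulate.BiolumSimParams,
    "temperature": simulate.TempSimParams,
}


def _build_schedule(spec: dict | str | None, duration_days: float) -> LightSchedule:
    n = int(np.ceil(duration_days))
    if spec is None or spec == "DD":
        return LightSchedule.dd(n)
    if spec == "LL":
        return LightSchedule.ll(n)
    if spec == "LD":
        return LightSchedule.ld(n)
    if isinstance(spec, dict):
        kind = spec.get("kind", "LD")
        if kind == "jet_lag":
            return LightSchedule.jet_lag(
                n_pre_days=int(spec.get("n_pre_days", 10)),
                advance_h=float(spec.get("advance_h", 8.0)),
                n_post_days=n - int(spec.get("n_pre_days", 10)),
            )
        if kind in ("LD", "DD", "LL"):
            return _build_schedule(kind, duration_days)
    raise ConfigError(f"unknown light schedule specification: {spec!r}")


def _simulate_step(step: dict, seed: int, out_dir: Path, log: list[str]) -> dict:
    kind = step.get("kind")
    params = dict(step.get("params", {}))
    save = step.get("save", f"{kind}.csv")
    if kind in _SIM_PARAMS:
        cls = _SIM_PARAMS[kind]
        sched_spec = params.pop("schedule", None)
        p = cls(seed=seed, **params)
        if kind == "activity":
            sched = _build_schedule(sched_spec, p.duration_days)
            series = simulate.generate_activity(p, sched)
        elif kind == "biolum":
            series = simulate.generate_bioluminescence(p)
        else:
            series = simulate.generate_temperature(p)
        write_series_csv(out_dir / save, series, header={**asdict(p), "seed": seed})
        log.append(f"simulate {kind} -> {save} ({series.n} samples)")
        return {"file": save, "n_samples": int(series.n)}
    if kind == "onsets":
        traj = simulate.generate_onset_shift(seed=seed, **params)
        path = out_dir / save
        with open(path, "w") as fh:
            fh.write("day,shift_h\n")
            for d, h in zip(traj.day, traj.hours):
                fh.write(f"{int(d)},{h:.6f}\n")
        log.append(f"simulate onsets -> {save} ({traj.day.size} days)")
        return {"file": save, "n_days": int(traj.day.size)}
    if kind == "phases":
        ph = simulate.sample_von_mises_by_r(seed=seed, **params)
        path = out_dir / save
        with open(path, "w") as fh:
            fh.write("phase_h\n")
            for h in ph.to_hours():
                fh.write(f"{h:.6f}\n")
        log.append(f"simulate phases -> {save} ({ph.n} angles)")
        return {"file": save, "n": int(ph.n)}
    raise ConfigError(f"unknown simulate kind: {kind!r}")


def _analyze_step(step: dict, out_dir: Path, log: list[str]) -> dict:
    op = step["step"]
    if op == "periodogram":
        s = read_series_csv(out_dir / step["input"])
        period = periodogram.estimate_period(
            s,
            analysis_start_day=float(step.get("start_day", 3)),
            analysis_span_days=float(step.get("span_days", 40)),
            p_min_h=float(step.get("pmin", 20)),
            p_max_h=float(step.get("pmax", 28)),
            resolution_min=float(step.get("resolution_min", 6)),
            alpha=float(step.get("alpha", 0.05)),
        )
        log.append(f"periodogram {step['input']}: {period:.2f} h")
        return {"estimated_period_h": period}
    if op == "fft_power":
        s = read_series_csv(out_dir / step["input"])
        cfg = spectral.SpectralConfig(
            tuple(step.get("range_h", (20, 36))), float(step.get("band", 0.006)))
        tc = spectral.fft_power_timecourse(
            s, cfg, float(step.get("window_days", 10)), float(step.get("step_days", 1)))
        save = step.get("save", "fft_power.csv")
        write_series_csv(out_dir / save, tc)
        log.append(f"fft_power {step['input']} -> {save}")
        return {"file": save, "mean_peak_power": float(np.nanmean(tc.values))}
    if op == "rayleigh":
        hours = np.loadtxt(out_dir / step["input"], skiprows=1)
        res = circular.rayleigh(circular.PhaseSet.from_hours(hours))
        log.append(f"rayleigh {step['input']}: r={res.r:.3f} p={res.p:.3g}")
        return {"r": res.r, "mean_hour": res.mean_hour(), "z": res.z, "p": res.p}
    if op == "ps50":
        import pandas as pd

        df = pd.read_csv(out_dir / step["input"], comment="#")
        onsets = reentrainment.OnsetSeries(
            df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
        fit = reentrainment.fit_ps50(onsets)
        log.append(f"ps50 {step['input']}: {fit.ps50_days:.2f} days")
        return {"ps50_days": fit.ps50_days, "top": fit.top, "bottom": fit.bottom,
                "hillslope": fit.hillslope, "rss": fit.rss}
    if op == "actogram":
        s = read_series_csv(out_dir / step["input"])
        grid = actogram.double_plot_matrix(s, float(step.get("bin_minutes", 6)))
        save = step.get("save", "actogram.csv")
        np.savetxt(out_dir / save, grid, fmt="%.6g", delimiter=",")
        log.append(f"actogram {step['input']} -> {save} {grid.shape}")
        return {"file": save, "shape": list(grid.shape)}
    raise ConfigError(f"unknown pipeline step: {op!r}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute a declarative run and write artifacts under ``out_dir``.

    Returns the summary dict; also writes ``summary.json``, ``run.log`` and
    ``config.yaml`` (the effective configuration including the seed).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "steps" not in config:
        raise ConfigError("config must be a mapping with a 'steps' list")
    master_seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {master_seed}"]
    summary: dict = {"seed": master_seed, "steps": []}
    for i, step in enumerate(config["steps"]):
        if not isinstance(step, dict) or "step" not in step:
            raise ConfigError(f"step {i} must be a mapping with a 'step' key")
        if step["step"] == "simulate":
            result = _simulate_step(step, derive_seed(master_seed, i), out, log)
        else:
            result = _analyze_step(step, out, log)
        summary["steps"].append({"step": step["step"], **result})
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**config, "seed": master_seed}, fh, sort_keys=True)
    return summary
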