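"""Orchestration: YAML-configured end-to-end runs with manifest logging.

A run config describes what to do (simulate / ramp / dwell / fit), where the
inputs live, and which condition is the control.  ``run_pipeline`` executes
the requested stages deterministically for a given seed and writes CSV/JSON
tables plus a manifest (package and library versions, seed, config hash) so
a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dose_response, dwell_analysis, ramp_analysis, synthetic_data
from .trace_model import Ligand, read_traces, write_traces

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration is invalid (detected before any computation)."""


@dataclass
class RunConfig:
    """Validated run configuration (see ``from_dict`` for the YAML schema)."""

    stages: list[str]
    seed: int = 0
    out_dir: Path = Path("riboforce_out")
    control_ligand: str = "control"
    simulate: dict = field(default_factory=dict)
    ramp: dict = field(default_factory=dict)
    dwell: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    KNOWN_STAGES = ("simulate", "ramp", "dwell", "fit")

    @classmethod
    def from_dict(cls, cfg: dict, out_dir: str | Path, seed: int | None = None) -> "RunConfig":
        stages = cfg.get("stages")
        if not stages:
            raise ConfigError("config must list at least one stage under 'stages'")
        unknown = [s for s in stages if s not in cls.KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        rc = cls(
            stages=list(stages),
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
            out_dir=Path(out_dir),
            control_ligand=cfg.get("control_ligand", "control"),
            simulate=cfg.get("simulate", {}),
            ramp=cfg.get("ramp", {}),
            dwell=cfg.get("dwell", {}),
            fit=cfg.get("fit", {}),
            raw=cfg,
        )
        for stage in ("ramp", "dwell"):
            if stage in rc.stages:
                sc = getattr(rc, stage)
                if "input" not in sc and "simulate" not in rc.stages:
                    raise ConfigError(f"stage '{stage}' needs an 'input' path or a simulate stage")
                path = sc.get("input")
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"stage '{stage}': input path {path} does not exist")
        if "fit" in rc.stages:
            for key in ("titration", "gel"):
                path = rc.fit.get(key)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"fit stage: {key} path {path} does not exist")
        return rc

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path, seed: int | None = None) -> "RunConfig":
        with open(path) as f:
            cfg = yaml.safe_load(f)
        if not isinstance(cfg, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(cfg, out_dir, seed)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _build_model(spec: dict) -> synthetic_data.KineticModel:
    return synthetic_data.KineticModel(**spec)


def _build_protocol(spec: dict) -> synthetic_data.ProtocolParams:
    return synthetic_data.ProtocolParams(**spec)


def _stage_simulate(rc: RunConfig, rng: np.random.Generator) -> Path:
    sc = rc.simulate
    model = _build_model(sc.get("model", {}))
    protocol = _build_protocol(sc.get("protocol", {}))
    concentrations = sc.get("concentrations", [0.0])
    n_beads = int(sc.get("n_beads", 5))
    if protocol.kind == "ramp":
        traces, truth = synthetic_data.simulate_ramp_cohort(
            model, protocol, concentrations, n_beads, rng
        )
        sidecar = {
            f"{bead}@{conc:g}": [
                {"direction": e.direction.value, "force": e.force, "size": e.size,
                 "time": e.time, "cycle": e.cycle_index}
                for e in evs
            ]
            for (bead, conc), evs in truth.items()
        }
    else:
        traces, truth = synthetic_data.simulate_constant_force_cohort(
            model, protocol, concentrations, n_beads, rng
        )
        sidecar = {
            f"{bead}@{conc:g}": [
                {"state": d.state.value, "start": d.start, "duration": d.duration,
                 "censored": d.censored}
                for d in dwells
            ]
            for (bead, conc), dwells in truth.items()
        }
    out = rc.out_dir / "traces.csv"
    write_traces(traces, out, format="csv")
    with open(rc.out_dir / "ground_truth.json", "w") as f:
        json.dump(sidecar, f)
    return out


def _stage_ramp(rc: RunConfig, traces_path: Path) -> dict:
    traces = read_traces(traces_path, format=rc.ramp.get("format", "csv"))
    criteria = ramp_analysis.SelectionCriteria(**rc.ramp.get("criteria", {}))
    result = ramp_analysis.analyze_ramp_cohort(
        traces,
        criteria=criteria,
        method=rc.ramp.get("method", "cluster"),
        control_ligand=rc.control_ligand,
        run_qc=bool(rc.ramp.get("qc", False)),
    )
    result["stats"].to_csv(rc.out_dir / "stats.csv", index=False)
    result["cycles"].to_csv(rc.out_dir / "events.csv", index=False)
    result["verdicts"].to_csv(rc.out_dir / "selection.csv", index=False)
    fits = {}
    if not result["normalized"].empty and rc.ramp.get("dose_response", True):
        for direction in ("unfold", "refold"):
            try:
                resp, fit = ramp_analysis.ramp_dose_response(result["normalized"], direction)
                fits[direction] = {
                    "params": fit.params,
                    "std_errors": fit.std_errors,
                    "flags": list(fit.flags),
                    "response": resp.to_dict(orient="list"),
                }
            except (ValueError, dose_response.FitConvergenceError) as e:
                fits[direction] = {"error": str(e)}
    with open(rc.out_dir / "ramp_fits.json", "w") as f:
        json.dump(fits, f, indent=1)
    return {"exclusions": result["exclusions"]}


def _stage_dwell(rc: RunConfig, traces_path: Path, rng: np.random.Generator) -> dict:
    traces = read_traces(traces_path, format=rc.dwell.get("format", "csv"))
    expected_len = float(rc.dwell.get("expected_structure_length", 15.0))
    dwells_by = {}
    exclusions = []
    for tr in traces:
        check_folding = tr.condition.ligand is Ligand.PREQ1
        verdict = dwell_analysis.exclude_noisy(tr, expected_len, check_folding=check_folding)
        if not verdict.passed:
            exclusions.append({"bead_id": tr.bead_id, "reason": ",".join(verdict.reasons)})
            continue
        try:
            path = dwell_analysis.assign_states(tr)
        except dwell_analysis.StateAssignmentError as e:
            exclusions.append({"bead_id": tr.bead_id, "reason": str(e)})
            continue
        key = (tr.bead_id, tr.condition.ligand.value, tr.condition.concentration)
        dwells_by[key] = dwell_analysis.extract_dwells(path)
    dwells_df = dwell_analysis.dwell_table(dwells_by)
    dwells_df.to_csv(rc.out_dir / "dwells.csv", index=False)
    if not dwells_df.empty:
        rates = dwell_analysis.aggregate_rates(dwells_df, control_ligand=rc.control_ligand, rng=rng)
        rates.to_csv(rc.out_dir / "rates.csv", index=False)
        dwell_analysis.summarize_rates(rates).to_csv(rc.out_dir / "rates_summary.csv", index=False)
    return {"exclusions": exclusions}


def _stage_fit(rc: RunConfig, rng: np.random.Generator) -> None:
    report = {}
    if "titration" in rc.fit:
        table = pd.read_csv(rc.fit["titration"])
        fit = dose_response.fit_one_site_total(
            table, fix_ns_slope=bool(rc.fit.get("fix_ns_slope", False))
        )
        report["one_site_total"] = {
            "params": fit.params, "std_errors": fit.std_errors, "flags": list(fit.flags)
        }
    if "gel" in rc.fit:
        gel = pd.read_csv(rc.fit["gel"])
        eff = gel["terminated"] / (gel["terminated"] + gel["readthrough"])
        fit = dose_response.fit_t50(gel["concentration_molar"], eff, rng=rng)
        report["termination"] = {
            "params": fit.params, "std_errors": fit.std_errors, "flags": list(fit.flags)
        }
    with open(rc.out_dir / "dose_fits.json", "w") as f:
        json.dump(report, f, indent=1)


def run_pipeline(rc: RunConfig) -> dict:
    """Execute the configured stages; returns a manifest dict (also written).

    Deterministic for a fixed config and seed: every random stage draws from
    a generator seeded from ``rc.seed``.
    """
    rc.out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rc.seed)
    exclusions: list[dict] = []
    traces_path = None
    if "simulate" in rc.stages:
        traces_path = _stage_simulate(rc, rng)
    if "ramp" in rc.stages:
        path = Path(rc.ramp.get("input", traces_path))
        exclusions += _stage_ramp(rc, path)["exclusions"]
    if "dwell" in rc.stages:
        path = Path(rc.dwell.get("input", traces_path))
        exclusions += _stage_dwell(rc, path, rng)["exclusions"]
    if "fit" in rc.stages:
        _stage_fit(rc, rng)
    manifest = {
        "riboforce_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": rc.seed,
        "stages": rc.stages,
        "config_hash": _config_hash(rc.raw),
        "exclusions": exclusions,
    }
    with open(rc.out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
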