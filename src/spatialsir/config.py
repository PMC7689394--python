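"""Run configuration: schema, validation, serialization and dispatch.

A :class:`RunConfig` names one experiment plus the parameter sections it
needs; it round-trips losslessly through YAML or JSON.  Every stochastic
operation derives its seed deterministically from the master seed, an
operation tag and a replicate counter (see :mod:`spatialsir._rng`), so
re-running the same config byte-reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from ._rng import child_seed
from .analysis import (
    beta_sweep,
    circle_timescales,
    fit_dmin_first_passage,
    intervention_outcome,
    log_derivative_thresholds,
    propagation_curve,
    run_intervention_experiment,
)
from .exceptions import ConfigError
from .network import ModelParams, build_network, degree_summary, write_network
from .percolation import estimate_pc_square
from .sir import EpidemicParams, InterventionSpec, run_sir, write_recovery_events
from .strategy import StrategyProblem, optimize_strategy
from .theory import threshold_summary

__all__ = ["RunConfig", "load_config", "save_config", "run_experiment"]

EXPERIMENTS = (
    "theory",
    "build",
    "simulate",
    "sweep",
    "propagate",
    "intervene",
    "percolation",
    "optimize",
)

_MODEL_KEYS = {"L", "zeta", "k_intra", "k_inter"}
_EPI_KEYS = {"beta", "origin", "max_steps"}
_IV_KEYS = {"strategy", "t_x", "new_value", "t_q"}
_SWEEP_KEYS = {"beta_min", "beta_max", "n_beta", "replicates"}
_PROP_KEYS = {"replicates", "max_steps"}
_PERC_KEYS = {"size", "replicates"}
_OPT_KEYS = {"K0", "Q0", "beta", "epsilon", "n_points"}
_TOP_KEYS = {
    "experiment",
    "seed",
    "output",
    "model",
    "epidemic",
    "interventions",
    "sweep",
    "propagate",
    "percolation",
    "optimize",
    "theory",
}
_THEORY_KEYS = {"K", "Q", "k_inter", "zeta"}


@dataclass
class RunConfig:
    experiment: str
    seed: int = 0
    output: str = "out"
    model: Optional[dict] = None
    epidemic: Optional[dict] = None
    interventions: list = field(default_factory=list)
    sweep: Optional[dict] = None
    propagate: Optional[dict] = None
    percolation: Optional[dict] = None
    optimize: Optional[dict] = None
    theory: Optional[dict] = None

    def __post_init__(self) -> None:
        errors = []
        if self.experiment not in EXPERIMENTS:
            errors.append(f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        for name, section, allowed in (
            ("model", self.model, _MODEL_KEYS),
            ("epidemic", self.epidemic, _EPI_KEYS),
            ("sweep", self.sweep, _SWEEP_KEYS),
            ("propagate", self.propagate, _PROP_KEYS),
            ("percolation", self.percolation, _PERC_KEYS),
            ("optimize", self.optimize, _OPT_KEYS),
            ("theory", self.theory, _THEORY_KEYS),
        ):
            if section is None:
                continue
            unknown = set(section) - allowed
            if unknown:
                errors.append(f"unknown keys in section '{name}': {sorted(unknown)}")
        for i, iv in enumerate(self.interventions):
            unknown = set(iv) - _IV_KEYS
            if unknown:
                errors.append(f"unknown keys in interventions[{i}]: {sorted(unknown)}")
        if errors:
            raise ConfigError("; ".join(errors))
        # construct domain objects eagerly so their validation fires here
        if self.model is not None:
            self.model_params()
        if self.epidemic is not None:
            self.epidemic_params()
        for iv in self.intervention_specs():
            _ = iv

    def model_params(self) -> ModelParams:
        if self.model is None:
            raise ConfigError("this experiment requires a 'model' section")
        return ModelParams(**self.model)

    def epidemic_params(self) -> EpidemicParams:
        if self.epidemic is None:
            raise ConfigError("this experiment requires an 'epidemic' section")
        return EpidemicParams(**self.epidemic)

    def intervention_specs(self) -> list[InterventionSpec]:
        return [InterventionSpec(**iv) for iv in self.interventions]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset, one parser covers both
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.as_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def _fmt(x: Any) -> Any:
    """17-significant-digit float serialization so equality checks on
    re-runs are meaningful."""
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.17g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_fmt(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _fmt(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_fmt(v) for v in x]
    return x


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_fmt(payload), indent=2) + "\n")


def _write_csv(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in zip(*columns):
            fh.write(",".join(f"{v:.17g}" if isinstance(v, float) else str(v) for v in row) + "\n")


def run_experiment(config: RunConfig, out_dir: Optional[str | Path] = None) -> dict[str, str]:
    """Dispatch a config to its experiment; write outputs + manifest.

    Returns a mapping of artifact names to file paths.  The manifest
    records the config, the package version and a SHA-256 per output so
    reproducibility is checkable byte-for-byte.
    """
    out = Path(out_dir if out_dir is not None else config.output)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    written: dict[str, str] = {}

    if config.experiment == "theory":
        sec = config.theory or {}
        if "Q" in sec:
            K, Q = sec["K"], sec["Q"]
        else:
            K = sec["K"]
            Q = sec["k_inter"] * sec["zeta"] ** 2
        res = threshold_summary(K, Q)
        p = out / "theory.json"
        _write_json(p, res.as_dict())
        written["theory"] = str(p)

    elif config.experiment == "build":
        net = build_network(config.model_params(), child_seed(seed, "build-net"))
        written.update(write_network(net, out / "network"))
        deg = degree_summary(net)
        p = out / "degrees.json"
        _write_json(
            p,
            {
                "mean_intra_degree": deg.mean_intra_degree,
                "mean_inter_degree": deg.mean_inter_degree,
                "community_inter_count_mean": float(deg.community_inter_counts.mean()),
            },
        )
        written["degrees"] = str(p)

    elif config.experiment == "simulate":
        net = build_network(config.model_params(), child_seed(seed, "sim-net"))
        run = run_sir(
            net,
            config.epidemic_params(),
            interventions=config.intervention_specs(),
            seed=child_seed(seed, "sim-sir"),
            record_events=True,
        )
        events_path = out / "recovery_events.tsv"
        write_recovery_events(run, events_path)
        written["recovery_events"] = str(events_path)
        p = out / "run.json"
        _write_json(
            p,
            {
                "origin": run.origin,
                "final_r": run.final_r,
                "final_extent": run.final_extent,
                "extent_at_intervention": run.extent_at_intervention,
                "duration": run.duration,
                "exhausted": run.exhausted,
                "s": run.s_counts,
                "i": run.i_counts,
                "r": run.r_counts,
                "rmax": run.rmax_series,
            },
        )
        written["run"] = str(p)

    elif config.experiment == "sweep":
        sec = config.sweep or {}
        betas = np.linspace(sec["beta_min"], sec["beta_max"], sec["n_beta"])
        sweep = beta_sweep(config.model_params(), betas, sec["replicates"], seed)
        det = log_derivative_thresholds(sweep)
        p_csv = out / "sweep.csv"
        _write_csv(
            p_csv,
            ["beta", "mean_R", "dlogR"],
            [sweep.betas, sweep.mean_r, det.derivative],
        )
        p = out / "thresholds.json"
        _write_json(
            p, {"beta_1": det.beta_1, "beta_2": det.beta_2, "collided": det.collided}
        )
        written["sweep"] = str(p_csv)
        written["thresholds"] = str(p)

    elif config.experiment == "propagate":
        sec = config.propagate or {}
        epi = config.epidemic_params()
        curve = propagation_curve(
            config.model_params(),
            epi.beta,
            sec["replicates"],
            seed,
            max_steps=sec.get("max_steps", epi.max_steps),
        )
        taus = circle_timescales(curve)
        try:
            dmin = fit_dmin_first_passage(curve)
        except Exception:
            dmin = None
        p_csv = out / "propagation.csv"
        _write_csv(
            p_csv,
            ["t", "rmax_mean", "rmax_mean_active", "n_active"],
            [curve.t, curve.rmax_mean, curve.rmax_mean_active, curve.n_active],
        )
        p = out / "propagation.json"
        _write_json(
            p,
            {
                "tau0": taus.tau0,
                "tau1": taus.tau1,
                "tau2": taus.tau2,
                "tau_x": taus.tau_x,
                "d_min": dmin,
                "degenerate": curve.degenerate,
            },
        )
        written["propagation"] = str(p_csv)
        written["timescales"] = str(p)

    elif config.experiment == "intervene":
        sec = config.propagate or {}
        epi = config.epidemic_params()
        params = config.model_params()
        runs = run_intervention_experiment(
            params,
            epi.beta,
            config.intervention_specs(),
            sec["replicates"],
            seed,
            max_steps=sec.get("max_steps", epi.max_steps),
        )
        outcome = intervention_outcome(runs, params.zeta)
        p = out / "intervention.json"
        _write_json(
            p,
            {
                "extent_at_intervention": outcome.extent_at_intervention,
                "final_extent": outcome.final_extent,
                "stopped": outcome.stopped,
                "band": outcome.band,
            },
        )
        written["intervention"] = str(p)

    elif config.experiment == "percolation":
        sec = config.percolation or {}
        est = estimate_pc_square(sec.get("size", 128), sec.get("replicates", 200), seed)
        p = out / "percolation.json"
        _write_json(
            p,
            {
                "p_c_estimate": est.p_c,
                "stderr": est.stderr,
                "replicates": est.replicates,
                "size": est.size,
            },
        )
        written["percolation"] = str(p)

    elif config.experiment == "optimize":
        sec = config.optimize or {}
        problem = StrategyProblem(
            K0=sec["K0"],
            Q0=sec["Q0"],
            beta=sec["beta"],
            epsilon=sec.get("epsilon", 1e-3),
        )
        res = optimize_strategy(problem, n_points=sec.get("n_points", 400))
        p = out / "optimize.json"
        _write_json(
            p,
            {
                "K_opt": res.K_opt,
                "Q_opt": res.Q_opt,
                "W_opt": res.W_opt,
                "strategy": res.strategy,
            },
        )
        written["optimize"] = str(p)

    manifest = {
        "config": config.as_dict(),
        "version": __version__,
        "outputs": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in written.items()
        },
    }
    mp = out / "manifest.json"
    _write_json(mp, manifest)
    written["manifest"] = str(mp)
    return written
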