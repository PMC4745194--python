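"""Configuration files, serialization, and deterministic fixtures.

Run configurations are JSON documents with a fixed schema; unknown keys
are rejected by name and missing entries fall back to the published
defaults, so a minimal config can be just ``{}`` or a handful of
parameter overrides.  Numeric fields round-trip bit-identically
(shortest-repr JSON floats).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .model import ModelParameters, SystemState, STATE_VARS
from .simulate import (DEFAULT_ATOL, DEFAULT_RTOL, Trajectory, scenario)
from .thresholds import ThresholdReport

__all__ = ["SolverOptions", "RunConfig", "load_config", "write_config",
           "write_trajectory_csv", "threshold_report_json",
           "generate_fixtures", "CSV_HEADER"]

CSV_HEADER = "t,T,S,C,F_beta,F_gamma,M_I,M_II"


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = DEFAULT_RTOL
    atol_cells: float = 1e-40     # T and S
    atol_other: float = 1e-12     # cytokines / receptors / CTLs
    method: str = "LSODA"
    n_samples: int = 1000

    def atol_vector(self) -> tuple:
        return (self.atol_cells, self.atol_cells) + (self.atol_other,) * 5


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: parameters (including the
    treatment rate ``N``), initial state, horizon, solver options,
    threshold mode, output path, and the seed used only for fixture
    generation."""

    parameters: ModelParameters = ModelParameters()
    initial_state: SystemState = SystemState(70.0, 30.0, 250.0, 50.0, 50.0,
                                             50.0, 50.0)
    t_end: float = 10_000.0
    mode: str = "paper"
    solver: SolverOptions = SolverOptions()
    out: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "initial_state": self.initial_state.to_dict(),
            "t_end": float(self.t_end),
            "mode": self.mode,
            "solver": dataclasses.asdict(self.solver),
            "out": self.out,
            "seed": int(self.seed),
        }


_TOP_KEYS = ("parameters", "initial_state", "t_end", "mode", "solver",
             "out", "seed")
_SOLVER_KEYS = tuple(f.name for f in dataclasses.fields(SolverOptions))


def _require_number(val, key):
    if isinstance(val, bool) or not isinstance(val, (int, float)) \
            or not math.isfinite(val):
        raise ConfigurationError(f"value for {key!r} must be a finite number,"
                                 f" got {val!r}")
    return float(val)


def config_from_dict(doc: dict) -> RunConfig:
    for key in doc:
        if key not in _TOP_KEYS:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    params = ModelParameters.from_dict(doc.get("parameters", {}))
    init_doc = doc.get("initial_state", {})
    for key in init_doc:
        if key not in STATE_VARS:
            raise ConfigurationError(f"unknown initial-state key {key!r}")
    base = RunConfig()
    init_vals = base.initial_state.to_dict()
    init_vals.update({k: _require_number(v, k) for k, v in init_doc.items()})
    solver_doc = doc.get("solver", {})
    for key in solver_doc:
        if key not in _SOLVER_KEYS:
            raise ConfigurationError(f"unknown solver key {key!r}")
    solver_vals = dataclasses.asdict(base.solver)
    solver_vals.update(solver_doc)
    mode = doc.get("mode", "paper")
    if mode not in ("paper", "consistent"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    return RunConfig(
        parameters=params,
        initial_state=SystemState(**init_vals),
        t_end=_require_number(doc.get("t_end", base.t_end), "t_end"),
        mode=mode,
        solver=SolverOptions(**solver_vals),
        out=doc.get("out"),
        seed=int(doc.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration root must be a JSON object")
    return config_from_dict(doc)


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Single header line then one row per sample, 17 significant
    digits (lossless for doubles)."""
    lines = [CSV_HEADER]
    for t, row in zip(traj.times, traj.states):
        lines.append(",".join(f"{v:.17g}" for v in (t, *row)))
    Path(path).write_text("\n".join(lines) + "\n")


def threshold_report_json(report: ThresholdReport, path=None) -> str:
    """Serialize a threshold report (all fields plus the mode flag);
    optionally write to ``path``.  JSON floats use the shortest
    round-tripping representation, so a re-read equals the report at
    bit level."""
    text = json.dumps(report.to_dict(), indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# Table-1 rows carrying a time unit get an independent perturbation
# factor; tied rows (aS = .1 aT, abetaS = abetaT, and the "Estimated"
# duplicates) follow their parent.
_RATE_FIELDS = ("r1", "aT", "r2", "ralpha", "muC", "gbeta", "abetaT",
                "mubeta", "gMI", "aMIgamma", "muMI", "aMIIgamma", "muMII",
                "agammaC", "mugamma")


def generate_fixtures(seed: int) -> dict[str, RunConfig]:
    """Deterministic fixture set: the three scenario configs plus 20
    parameter sets with every independent rate multiplied by a
    log-uniform factor in [0.5, 2]."""
    out: dict[str, RunConfig] = {}
    for name in ("fig1", "fig2", "fig3"):
        sc = scenario(name)
        out[name] = RunConfig(parameters=sc.params, initial_state=sc.init,
                              t_end=sc.t_end, seed=int(seed))
    rng = np.random.default_rng(int(seed))
    base = ModelParameters().to_dict()
    for k in range(20):
        d = dict(base)
        for name in _RATE_FIELDS:
            d[name] = base[name] * float(np.exp(
                rng.uniform(np.log(0.5), np.log(2.0))))
        d["aS"] = 0.1 * d["aT"]
        d["abetaS"] = d["abetaT"]
        out[f"perturbed{k:02d}"] = RunConfig(
            parameters=ModelParameters.from_dict(d),
            initial_state=RunConfig().initial_state,
            t_end=200.0, seed=int(seed))
    return out
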