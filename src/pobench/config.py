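"""Run configuration, results serialization and reproducibility metadata.

A run is fully described by a :class:`RunConfig`; the summary written next
to the results embeds the resolved config (plus seed, package version and a
config hash) so any result can be re-run from its own output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import (
    BenchmarkResult,
    MTDDistanceCriterion,
    Phase12Criterion,
    run_original_benchmark,
    run_po_benchmark_binary,
    run_po_benchmark_multi,
)
from .scenario import Scenario, load_scenario

__all__ = ["RunConfig", "load_config", "run_from_config", "write_results", "read_proportions"]

_MODES = ("po", "original", "multi")


@dataclass
class RunConfig:
    """Serializable description of one benchmark run."""

    scenario: str
    mode: str = "po"
    n: int | None = None
    Z: int = 10_000
    seed: int = 0
    gamma: float | None = None
    rho: float = 0.0
    shared_ordering: bool = False
    prior_mode: str = "distinct_values"
    tie_policy: str = "split"
    eta1: float = 0.8
    eta2: float = 0.8
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.prior_mode not in ("distinct_values", "per_ordering"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.tie_policy not in ("split", "first"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")
        if self.Z < 1:
            raise ValueError("Z must be >= 1")
        if abs(self.rho) > 1:
            raise ValueError("rho must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file and/or keyword overrides.

    Flags override file values; unknown keys are rejected with the
    offending field names.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "scenario" not in data:
        raise ValueError("config must name a scenario (packaged id or file path)")
    return RunConfig(**data)


def run_from_config(config: RunConfig) -> BenchmarkResult:
    """Execute the run a config describes."""
    scenario: Scenario = load_scenario(config.scenario)
    if config.mode == "original":
        return run_original_benchmark(
            scenario, n=config.n, Z=config.Z, seed=config.seed, gamma=config.gamma,
            tie_policy=config.tie_policy,
        )
    if config.mode == "po":
        return run_po_benchmark_binary(
            scenario, n=config.n, Z=config.Z, seed=config.seed,
            gamma=config.gamma, prior_mode=config.prior_mode,
            tie_policy=config.tie_policy,
        )
    criterion = None
    if scenario.phi is not None and scenario.psi is not None:
        criterion = Phase12Criterion(
            phi=scenario.phi, psi=scenario.psi, eta1=config.eta1, eta2=config.eta2
        )
    elif config.gamma is not None or scenario.gamma is not None:
        criterion = MTDDistanceCriterion(gamma=config.gamma or scenario.gamma)
    return run_po_benchmark_multi(
        scenario, n=config.n, Z=config.Z, seed=config.seed, criterion=criterion,
        shared=config.shared_ordering, rho=config.rho, prior_mode=config.prior_mode,
    )


def write_results(
    result: BenchmarkResult, prefix: str | Path, config: RunConfig | None = None
) -> dict[str, Path]:
    """Write ``PREFIX_proportions.csv`` and ``PREFIX_summary.json``.

    The CSV holds the selection percentages on the dose grid (full
    precision; header = agent-B dose labels, rows = agent-A doses) plus a
    no-selection row.  The JSON summary reports the PCS both to one
    decimal, matching how such operating characteristics are tabulated,
    and at full precision, together with everything needed to re-run.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.parent / f"{prefix.name}_proportions.csv"
    json_path = prefix.parent / f"{prefix.name}_summary.json"

    pct = 100.0 * result.proportions_matrix
    header = "," + ",".join(f"b{l}" for l in range(1, result.L + 1))
    lines = [header]
    for k in range(result.K):
        lines.append(f"a{k + 1}," + ",".join(repr(float(v)) for v in pct[k]))
    lines.append(f"no_selection,{float(100.0 * result.no_selection)!r}")
    csv_path.write_text("\n".join(lines) + "\n")

    summary = {
        "package": "pobench",
        "version": __version__,
        "scenario": result.scenario_name,
        "mode": result.mode,
        "K": result.K,
        "L": result.L,
        "n": result.n,
        "Z": result.Z,
        "seed": result.seed,
        "settings": _jsonify(result.settings),
        "targets": [list(t) for t in result.targets],
        "pcs_percent": result.pcs if result.targets else None,
        "pcs_percent_1dp": round(result.pcs, 1) if result.targets else None,
        "proportions": result.proportions.tolist(),
        "no_selection": result.no_selection,
        "config": config.to_dict() if config else None,
        "config_hash": config.hash() if config else None,
    }
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    if result.replicates is not None:
        rep_path = prefix.parent / f"{prefix.name}_replicates.csv"
        np.savetxt(rep_path, result.replicates, delimiter=",")
        return {"proportions": csv_path, "summary": json_path, "replicates": rep_path}
    return {"proportions": csv_path, "summary": json_path}


def read_proportions(csv_path: str | Path) -> tuple[np.ndarray, float]:
    """Read back a proportions CSV: (K x L matrix, no-selection), as fractions."""
    rows = [ln.split(",") for ln in Path(csv_path).read_text().strip().splitlines()]
    body = [[float(v) for v in r[1:]] for r in rows[1:-1]]
    no_sel = float(rows[-1][1])
    return np.asarray(body) / 100.0, no_sel / 100.0


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj
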