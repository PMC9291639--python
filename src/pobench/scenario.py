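"""True simulation scenarios and per-ordering parameter assignments.

A *scenario* fixes the true combination-level parameters of a simulated
trial: the toxicity probability ``p_kl`` at each combination, optionally a
per-combination efficacy parameter (a normal mean in the Phase I/II
setting), the selection target (``gamma`` for MTC search, or the
``(phi, psi)`` admissibility bounds), and the set of combinations counted
as correct selections.

Given a scenario and the set of feasible complete orderings, the benchmark
treats the *values* of the parameters as known but their *placement* as
unknown: under ordering ``s`` the r-th smallest value is assigned to the
position holding rank r.  This module builds those permuted assignments
``q_kl^(s)``, the per-position candidate-value counts ``t_kl`` and the
prior mass ``h_kl^(s)`` that the value at (k, l) is the one ordering ``s``
assigns there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .grid import DoseGrid, OrderingSet

__all__ = [
    "Scenario",
    "ScenarioError",
    "OrderingAssignment",
    "validate_monotone",
    "build_assignments",
    "candidate_value_counts",
    "derive_targets",
    "load_scenario",
    "list_scenarios",
]


class ScenarioError(ValueError):
    """Invalid scenario specification."""


def validate_monotone(values: np.ndarray, direction: str = "increasing") -> None:
    """Check within-agent monotonicity of a parameter matrix.

    ``increasing`` requires values nondecreasing in both indices (toxicity);
    ``decreasing`` requires nonincreasing values (e.g. a change-from-baseline
    efficacy marker where lower is better).
    """
    v = np.asarray(values, dtype=float)
    if direction == "decreasing":
        v = -v
    elif direction != "increasing":
        raise ValueError(f"unknown direction {direction!r}")
    if np.any(np.diff(v, axis=0) < 0) or np.any(np.diff(v, axis=1) < 0):
        raise ScenarioError(
            f"parameter matrix is not {direction} within each agent"
        )


@dataclass
class Scenario:
    """True combination-level parameters of a simulated dual-agent trial."""

    name: str
    tox_probs: np.ndarray
    targets: list[tuple[int, int]] = field(default_factory=list)
    gamma: float | None = None
    eff_means: np.ndarray | None = None
    eff_sd: float = 1.0
    phi: float | None = None
    psi: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.tox_probs = np.asarray(self.tox_probs, dtype=float)
        if self.tox_probs.ndim != 2:
            raise ScenarioError("tox_probs must be a K x L matrix")
        if np.any(self.tox_probs <= 0) or np.any(self.tox_probs >= 1):
            raise ScenarioError("toxicity probabilities must lie strictly in (0, 1)")
        validate_monotone(self.tox_probs, "increasing")
        if self.eff_means is not None:
            self.eff_means = np.asarray(self.eff_means, dtype=float)
            if self.eff_means.shape != self.tox_probs.shape:
                raise ScenarioError("eff_means shape must match tox_probs")
            validate_monotone(self.eff_means, "decreasing")
        self.targets = [tuple(int(v) for v in t) for t in self.targets]
        K, L = self.tox_probs.shape
        for k, l in self.targets:
            if not (1 <= k <= K and 1 <= l <= L):
                raise ScenarioError(f"target ({k}, {l}) outside the {K}x{L} grid")

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(*self.tox_probs.shape)

    def target_flat_indices(self) -> np.ndarray:
        """Row-major flat indices of the target combinations."""
        L = self.tox_probs.shape[1]
        return np.array([(k - 1) * L + (l - 1) for k, l in self.targets], dtype=int)


def derive_targets(
    prob_matrix: np.ndarray, gamma: float, tol: float = 1e-9
) -> list[tuple[int, int]]:
    """Positions whose toxicity probability is closest to ``gamma``.

    Convenience helper; scenario files normally carry the target set
    explicitly so that 'correct' stays under the analyst's control.
    """
    p = np.asarray(prob_matrix, dtype=float)
    dist = np.abs(p - gamma)
    best = dist.min()
    ks, ls = np.nonzero(dist <= best + tol)
    return [(int(k) + 1, int(l) + 1) for k, l in zip(ks, ls)]


@dataclass
class OrderingAssignment:
    """Permuted parameter assignments ``q_kl^(s)`` over all feasible orderings.

    Attributes
    ----------
    values : (S, K*L) array
        ``values[s, j]`` is the parameter value at position j (row-major)
        under ordering s; equals ``sorted_values[rank - 1]``.
    sorted_values : (K*L,) array
        True values sorted by rank (ascending for an increasing endpoint,
        descending for a decreasing one).
    distinct_values : (D,) array of the distinct true values, rank-sorted.
    value_idx : (S, K*L) int array indexing ``distinct_values``.
    t : (K*L,) int array — number of distinct candidate values per position.
    log_prior : (S, K*L) array of ``log h_kl^(s)``.
    """

    orderings: OrderingSet
    direction: str
    values: np.ndarray
    sorted_values: np.ndarray
    distinct_values: np.ndarray
    value_idx: np.ndarray
    t: np.ndarray
    log_prior: np.ndarray
    prior_mode: str

    @property
    def S(self) -> int:
        return self.orderings.S

    def true_ordering_indices(self, true_matrix: np.ndarray) -> np.ndarray:
        """Indices of orderings whose assignment equals the true matrix.

        Several orderings can coincide with the truth when true values tie;
        they remain distinct orderings but identical assignments.
        """
        truth = np.asarray(true_matrix, dtype=float).ravel()
        return np.nonzero(np.all(self.values == truth[None, :], axis=1))[0]

    def assignment_class_labels(self) -> np.ndarray:
        """Label orderings by identical value matrices (ties collapse).

        Returns an (S,) int array; orderings with the same label assign the
        same value to every position and are indistinguishable from data.
        """
        _, labels = np.unique(self.value_idx, axis=0, return_inverse=True)
        return labels


def build_assignments(
    true_values: np.ndarray,
    orderings: OrderingSet,
    direction: str = "increasing",
    prior_mode: str = "distinct_values",
) -> OrderingAssignment:
    """Assign the true parameter values to positions under every ordering.

    Under ordering ``s`` the position holding rank r receives the r-th
    smallest true value (r-th largest for ``direction='decreasing'``), so
    the assignments are exactly the permutations of the true values
    compatible with the feasible complete orderings.

    ``prior_mode`` sets the prior mass ``h_kl^(s)`` that the value at a
    position is the one ordering ``s`` puts there:

    - ``distinct_values`` — uniform over the distinct candidate values at
      the position: ``h = 1/t_kl`` (the default, matching ``h = 1/2`` at
      the incomparable corner of a 2x2 grid with distinct values);
    - ``per_ordering`` — induced by a uniform prior over orderings:
      ``h`` is the fraction of orderings assigning that value there.
    """
    vals = np.asarray(true_values, dtype=float).ravel()
    grid = orderings.grid
    if vals.size != grid.n_combos:
        raise ScenarioError("number of parameter values must equal K*L")
    validate_monotone(vals.reshape(grid.K, grid.L), direction)

    order = np.argsort(vals, kind="stable")
    if direction == "decreasing":
        order = order[::-1]
    sorted_values = vals[order]
    values = sorted_values[orderings.ranks - 1]

    distinct_values, rank_to_idx = np.unique(sorted_values, return_inverse=True)
    if direction == "decreasing":  # keep rank order: largest first
        distinct_values = distinct_values[::-1]
        rank_to_idx = len(distinct_values) - 1 - rank_to_idx
    value_idx = rank_to_idx[orderings.ranks - 1]

    t = np.array(
        [len(np.unique(value_idx[:, j])) for j in range(grid.n_combos)], dtype=int
    )

    S = orderings.S
    if prior_mode == "distinct_values":
        log_prior = np.broadcast_to(-np.log(t)[None, :], (S, grid.n_combos)).copy()
    elif prior_mode == "per_ordering":
        log_prior = np.empty((S, grid.n_combos))
        for j in range(grid.n_combos):
            _, inv, counts = np.unique(
                value_idx[:, j], return_inverse=True, return_counts=True
            )
            log_prior[:, j] = np.log(counts[inv] / S)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")

    return OrderingAssignment(
        orderings=orderings,
        direction=direction,
        values=values,
        sorted_values=sorted_values,
        distinct_values=distinct_values,
        value_idx=value_idx,
        t=t,
        log_prior=log_prior,
        prior_mode=prior_mode,
    )


def candidate_value_counts(assignment: OrderingAssignment) -> np.ndarray:
    """The ``t_kl`` matrix: distinct candidate values per position, K x L."""
    grid = assignment.orderings.grid
    return assignment.t.reshape(grid.K, grid.L)


# ---------------------------------------------------------------------------
# packaged scenario library


def _scenario_from_dict(data: dict, name: str) -> Scenario:
    known = {
        "name", "rows", "cols", "tox_probs", "eff_means", "eff_sd",
        "gamma", "phi", "psi", "targets", "n",
    }
    unknown = set(data) - known
    if unknown:
        raise ScenarioError(f"unknown scenario fields: {sorted(unknown)}")
    tox = np.asarray(data["tox_probs"], dtype=float)
    if "rows" in data and tox.shape != (data["rows"], data["cols"]):
        raise ScenarioError("tox_probs shape disagrees with rows/cols")
    return Scenario(
        name=data.get("name", name),
        tox_probs=tox,
        targets=[tuple(t) for t in data.get("targets", [])],
        gamma=data.get("gamma"),
        eff_means=data.get("eff_means"),
        eff_sd=float(data.get("eff_sd", 1.0)),
        phi=data.get("phi"),
        psi=data.get("psi"),
        n=data.get("n"),
    )


def load_scenario(name_or_path: str | Path) -> Scenario:
    """Load a scenario by packaged id (e.g. ``table2_scenario1``) or file path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml", ".json"} or path.exists():
        text = path.read_text()
        stem = path.stem
    else:
        ref = resources.files("pobench") / "scenarios" / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(
                f"no packaged scenario {name_or_path!r}; "
                f"available: {', '.join(list_scenarios())}"
            )
        text = ref.read_text()
        stem = str(name_or_path)
    data = yaml.safe_load(text)
    return _scenario_from_dict(data, stem)


def list_scenarios() -> list[str]:
    """Names of the scenario fixtures shipped with the package."""
    root = resources.files("pobench") / "scenarios"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))
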