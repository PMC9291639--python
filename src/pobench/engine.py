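"""Monte-Carlo benchmark engine.

Runs the complete-information benchmark over Z simulated trials in two
modes:

- *original* — the classical nonparametric optimal benchmark, which treats
  the ordering of the combinations as known: per replicate, estimate
  ``p_hat = x/n`` at every combination and select by the decision
  criterion;
- *partial ordering* (PO) — the generalization for unknown ordering: per
  replicate, compute the power-likelihood posterior over all feasible
  complete orderings, apply the criterion under each ordering, and
  accumulate selection mass weighted by the ordering probabilities.

Both modes draw each replicate's latent profiles from an independent,
counter-based substream of one root seed, so replicate z is reproducible in
isolation and the two modes see identical data under a shared seed.

The PO fast path exploits the fact that, under complete information, the
estimate at a position depends only on the *value* assigned there: per
replicate it computes one estimate per distinct candidate value, finds the
minimizing ranks once, and scatters ordering-probability mass to positions
through a precomputed rank-to-position table.  This keeps Z = 10^4
replicates over S = 6006 orderings desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .grid import OrderingSet, compute_weights, enumerate_linear_extensions
from .posterior import (
    binary_log_likelihood_table,
    gather_log_terms,
    normal_log_likelihood_table,
    normalize_log_terms,
)
from .profiles import generate_profiles, replicate_rng
from .scenario import Scenario, build_assignments

__all__ = [
    "MTDDistanceCriterion",
    "Phase12Criterion",
    "BenchmarkResult",
    "select_mtd",
    "phase12_criterion",
    "run_original_benchmark",
    "run_po_benchmark_binary",
    "run_po_benchmark_multi",
    "po_replicate_binary",
    "compute_pcs",
    "pcs_ratio",
]

_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class MTDDistanceCriterion:
    """Select the combination whose estimated toxicity is closest to gamma."""

    gamma: float

    kind = "mtd_distance"


@dataclass(frozen=True)
class Phase12Criterion:
    """Safe-and-efficacious trade-off for binary toxicity + normal efficacy.

    A combination is admissible when the posterior probability of excess
    toxicity ``P(p > phi | x)`` stays below ``eta1`` (conjugate
    beta(a, b) prior) and the posterior probability that the efficacy mean
    exceeds ``psi`` stays below ``eta2`` (normal prior on the mean, known
    unit-scale sampling model; lower efficacy responses are better).  Among
    admissible combinations the one with the lowest mean response wins; if
    none is admissible the trial selects nothing.

    The default eta/prior values are this package's choices, not published
    calibrations.
    """

    phi: float
    psi: float
    eta1: float = 0.8
    eta2: float = 0.8
    tox_prior: tuple[float, float] = (1.0, 1.0)
    eff_prior_mean: float = 0.0
    eff_prior_sd: float = 10.0

    kind = "phase12_tradeoff"


@dataclass
class BenchmarkResult:
    """Aggregated selection proportions of one benchmark run.

    ``proportions`` has K*L + 1 entries in row-major position order, the
    last being the no-admissible-selection mass; entries sum to one.
    """

    scenario_name: str
    mode: str
    K: int
    L: int
    n: int
    Z: int
    seed: int
    proportions: np.ndarray
    targets: list[tuple[int, int]]
    settings: dict = field(default_factory=dict)
    mean_entropy: float | None = None
    mean_class_entropy: float | None = None
    replicates: np.ndarray | None = None

    @property
    def proportions_matrix(self) -> np.ndarray:
        return self.proportions[:-1].reshape(self.K, self.L)

    @property
    def no_selection(self) -> float:
        return float(self.proportions[-1])

    @property
    def pcs(self) -> float:
        return compute_pcs(self)


def compute_pcs(
    result: BenchmarkResult, target_set: Sequence[tuple[int, int]] | None = None
) -> float:
    """Proportion of correct selections, in percent.

    Sums the selection proportions over the target combinations.
    """
    targets = list(target_set) if target_set is not None else result.targets
    if not targets:
        raise ValueError("target set is empty")
    flat = [(k - 1) * result.L + (l - 1) for k, l in targets]
    return float(100.0 * result.proportions[flat].sum())


def pcs_ratio(design_pcs: float, benchmark_pcs: float) -> float:
    """Design-to-benchmark PCS ratio in percent (benchmark = 100)."""
    return 100.0 * design_pcs / benchmark_pcs


# ---------------------------------------------------------------------------
# selection criteria


def select_mtd(estimates: np.ndarray, gamma: float) -> np.ndarray:
    """Selection mass over positions: argmin of |estimate - gamma|.

    Exact ties split mass equally among the tied minimizers, which keeps
    the selection deterministic given the data.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    dist = np.abs(est - gamma)
    mask = np.isclose(dist, dist.min(), rtol=0.0, atol=_TIE_ATOL)
    return mask / mask.sum()


def _tie_split_mask(dist: np.ndarray, tie_policy: str = "split") -> np.ndarray:
    """Row-wise selection masses from a (Z, R) distance matrix.

    ``split`` shares each replicate's mass equally among exact-tie
    minimizers; ``first`` puts it all on the first minimizer (the behaviour
    of a plain argmin, kept as an option because published operating
    characteristics are sensitive to it when several combinations share a
    true parameter value).
    """
    if tie_policy == "first":
        mass = np.zeros_like(dist)
        mass[np.arange(dist.shape[0]), np.argmin(dist, axis=1)] = 1.0
        return mass
    if tie_policy != "split":
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    dmin = dist.min(axis=1, keepdims=True)
    mask = np.isclose(dist, dmin, rtol=0.0, atol=_TIE_ATOL)
    return mask / mask.sum(axis=1, keepdims=True)


def phase12_criterion(
    tox_counts: np.ndarray,
    n: int,
    eff_responses: np.ndarray,
    criterion: Phase12Criterion,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and admissibility for the Phase I/II trade-off.

    Parameters
    ----------
    tox_counts : (K*L,) DLT counts.
    eff_responses : (n, K*L) continuous efficacy responses.

    Returns
    -------
    scores : (K*L,) mean efficacy response per combination.
    admissible : (K*L,) bool, both posterior safety conditions met.
    """
    x = np.asarray(tox_counts, dtype=float).ravel()
    ybar = np.asarray(eff_responses, dtype=float).mean(axis=0)
    a, b = criterion.tox_prior
    tox_tail = stats.beta.sf(criterion.phi, a + x, b + n - x)
    post_prec = n + 1.0 / criterion.eff_prior_sd**2
    post_mean = (n * ybar + criterion.eff_prior_mean / criterion.eff_prior_sd**2) / post_prec
    eff_tail = stats.norm.sf(criterion.psi, loc=post_mean, scale=np.sqrt(1.0 / post_prec))
    admissible = (tox_tail < criterion.eta1) & (eff_tail < criterion.eta2)
    return ybar, admissible


def _phase12_tables(
    cd_t: np.ndarray,
    n: int,
    eff_values: np.ndarray,
    mean_z: float,
    criterion: Phase12Criterion,
    eff_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Admissibility and score per distinct candidate value (one replicate).

    Complete information makes both statistics depend only on the assigned
    value: a candidate toxicity v yields count ``#{u_t < v}`` and a
    candidate efficacy mean m yields sample mean ``m + eff_sd * mean_z``.
    """
    a, b = criterion.tox_prior
    tox_tail = stats.beta.sf(criterion.phi, a + cd_t, b + n - cd_t)
    adm_t = tox_tail < criterion.eta1
    ybar = eff_values + eff_sd * mean_z
    post_prec = n + 1.0 / criterion.eff_prior_sd**2
    post_mean = (n * ybar + criterion.eff_prior_mean / criterion.eff_prior_sd**2) / post_prec
    eff_tail = stats.norm.sf(criterion.psi, loc=post_mean, scale=np.sqrt(1.0 / post_prec))
    adm_e = eff_tail < criterion.eta2
    return adm_t, adm_e, ybar


# ---------------------------------------------------------------------------
# single-endpoint benchmark runs


def _resolve(scenario: Scenario, n: int | None, gamma: float | None) -> tuple[int, float]:
    n = n if n is not None else scenario.n
    gamma = gamma if gamma is not None else scenario.gamma
    if n is None or gamma is None:
        raise ValueError("n and gamma must be given by the scenario or the call")
    return int(n), float(gamma)


def run_original_benchmark(
    scenario: Scenario,
    n: int | None = None,
    Z: int = 10_000,
    seed: int = 0,
    gamma: float | None = None,
    tie_policy: str = "split",
    keep_replicates: bool = False,
    chunk: int = 1000,
) -> BenchmarkResult:
    """Known-ordering benchmark: select on ``x/n`` at the true assignment.

    With ``tie_policy='first'`` ties go to the first combination in
    row-major (k, l) order instead of being split.
    """
    n, gamma = _resolve(scenario, n, gamma)
    p = scenario.tox_probs.ravel()
    P = p.size
    Q = np.zeros(P)
    reps = np.empty((Z, P + 1)) if keep_replicates else None
    for start in range(0, Z, chunk):
        zs = range(start, min(start + chunk, Z))
        U = np.stack([replicate_rng(seed, z).random(n) for z in zs])
        x = (U[:, :, None] < p[None, None, :]).sum(axis=1)
        mass = _tie_split_mask(np.abs(x / n - gamma), tie_policy)
        Q += mass.sum(axis=0)
        if reps is not None:
            reps[start : start + len(mass), :P] = mass
            reps[start : start + len(mass), P] = 0.0
    proportions = np.append(Q / Z, 0.0)
    return BenchmarkResult(
        scenario_name=scenario.name, mode="original_benchmark",
        K=scenario.grid.K, L=scenario.grid.L, n=n, Z=Z, seed=seed,
        proportions=proportions, targets=list(scenario.targets),
        settings={"gamma": gamma, "tie_policy": tie_policy}, replicates=reps,
    )


def run_po_benchmark_binary(
    scenario: Scenario,
    orderings: OrderingSet | None = None,
    n: int | None = None,
    Z: int = 10_000,
    seed: int = 0,
    gamma: float | None = None,
    prior_mode: str = "distinct_values",
    weights: np.ndarray | None = None,
    tie_policy: str = "split",
    keep_replicates: bool = False,
    collect_entropy: bool = False,
    chunk: int = 1000,
) -> BenchmarkResult:
    """Partial-ordering benchmark for a single binary toxicity endpoint.

    Per replicate: generate profiles, form complete-information DLT counts,
    compute the power-likelihood posterior over all feasible orderings,
    select under every ordering by distance to gamma, and accumulate
    ordering-probability-weighted selection mass.
    """
    n, gamma = _resolve(scenario, n, gamma)
    grid = scenario.grid
    if orderings is None:
        orderings = enumerate_linear_extensions(grid)
    assignment = build_assignments(
        scenario.tox_probs, orderings, "increasing", prior_mode
    )
    if weights is None:
        weights = compute_weights(grid)
    P = grid.n_combos
    D = assignment.distinct_values
    # distinct index of the true value at each position, and at each rank
    idx_true = np.searchsorted(D, scenario.tox_probs.ravel())
    idx_rank = np.searchsorted(D, assignment.sorted_values)
    pos_of_rank = orderings.pos_of_rank  # (S, P)
    labels = assignment.assignment_class_labels() if collect_entropy else None
    if labels is not None:
        class_order = np.argsort(labels, kind="stable")
        class_bounds = np.flatnonzero(
            np.diff(labels[class_order], prepend=labels[class_order[0]] - 1)
        )

    rank_mass = np.zeros((P, orderings.S))  # accumulated over replicates
    rank_sums = np.zeros(P)  # S == 1 path: plain column sums, as the original mode
    reps = np.empty((Z, P + 1)) if keep_replicates else None
    ent_sum = 0.0
    cent_sum = 0.0
    for start in range(0, Z, chunk):
        zs = range(start, min(start + chunk, Z))
        B = len(zs)
        U = np.stack([replicate_rng(seed, z).random(n) for z in zs])
        cd = (U[:, :, None] < D[None, None, :]).sum(axis=1)  # (B, D)
        x = cd[:, idx_true]
        table = binary_log_likelihood_table(x, n, assignment)
        log_terms = gather_log_terms(table, assignment, weights, drop_constant=True)
        Ppost = normalize_log_terms(log_terms)  # (B, S)
        # fancy indexing may return an F-ordered view copy; force C order so
        # reductions round exactly as in the original-benchmark path
        est_by_rank = np.ascontiguousarray(cd[:, idx_rank])
        mass = _tie_split_mask(np.abs(est_by_rank / n - gamma), tie_policy)
        if orderings.S == 1:
            # accumulate exactly as the original benchmark does, so the two
            # modes are bit-identical under a shared seed
            rank_sums += mass.sum(axis=0)
        else:
            rank_mass += mass.T @ Ppost
        if collect_entropy:
            with np.errstate(divide="ignore", invalid="ignore"):
                lg = np.where(Ppost > 0, np.log(Ppost), 0.0)
            ent_sum += float(-(Ppost * lg).sum())
            pooled = np.add.reduceat(Ppost[:, class_order], class_bounds, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                lg = np.where(pooled > 0, np.log(pooled), 0.0)
            cent_sum += float(-(pooled * lg).sum())
        if reps is not None:
            for b in range(B):
                q = np.zeros(P)
                for r in np.flatnonzero(mass[b] > 0):
                    q += mass[b, r] * np.bincount(
                        pos_of_rank[:, r], weights=Ppost[b], minlength=P
                    )
                reps[start + b, :P] = q
                reps[start + b, P] = 0.0

    Q = np.zeros(P)
    if orderings.S == 1:
        Q[pos_of_rank[0]] = rank_sums
    else:
        for r in range(P):
            Q += np.bincount(pos_of_rank[:, r], weights=rank_mass[r], minlength=P)
    proportions = np.append(Q / Z, 0.0)
    return BenchmarkResult(
        scenario_name=scenario.name, mode="po_benchmark",
        K=grid.K, L=grid.L, n=n, Z=Z, seed=seed,
        proportions=proportions, targets=list(scenario.targets),
        settings={"gamma": gamma, "prior_mode": prior_mode, "S": orderings.S,
                  "tie_policy": tie_policy},
        mean_entropy=ent_sum / Z if collect_entropy else None,
        mean_class_entropy=cent_sum / Z if collect_entropy else None,
        replicates=reps,
    )


def po_replicate_binary(
    scenario: Scenario,
    u: np.ndarray,
    orderings: OrderingSet | None = None,
    gamma: float | None = None,
    prior_mode: str = "distinct_values",
    weights: np.ndarray | None = None,
):
    """One fully-detailed PO-benchmark replicate from explicit profiles.

    Returns a dict with the DLT counts, the ordering posterior, the
    per-ordering estimates and selection masses, and the accumulated
    per-combination selection mass ``Q_kl`` — the audit trail of a single
    simulated trial.
    """
    from .posterior import ordering_posterior_binary
    from .profiles import ProfileSet, binary_counts, estimate_under_ordering

    _, gamma = _resolve(scenario, n=len(np.ravel(u)), gamma=gamma)
    u = np.asarray(u, dtype=float).ravel()
    n = u.size
    grid = scenario.grid
    if orderings is None:
        orderings = enumerate_linear_extensions(grid)
    assignment = build_assignments(
        scenario.tox_probs, orderings, "increasing", prior_mode
    )
    x = binary_counts(u, scenario.tox_probs)
    post = ordering_posterior_binary(x, n, assignment, weights)
    profiles = ProfileSet(u=u[:, None])
    P = grid.n_combos
    Q = np.zeros(P)
    estimates = np.empty((orderings.S, P))
    selections = np.empty((orderings.S, P))
    for s in range(orderings.S):
        estimates[s] = estimate_under_ordering(profiles, assignment.values[s])
        selections[s] = select_mtd(estimates[s], gamma)
        Q += post.probs[s] * selections[s]
    return {
        "counts": x,
        "posterior": post,
        "estimates": estimates,
        "selections": selections,
        "Q": Q,
    }


# ---------------------------------------------------------------------------
# multi-endpoint benchmark


def run_po_benchmark_multi(
    scenario: Scenario,
    n: int | None = None,
    Z: int = 10_000,
    seed: int = 0,
    criterion: Phase12Criterion | MTDDistanceCriterion | None = None,
    shared: bool = False,
    rho: float = 0.0,
    prior_mode: str = "distinct_values",
    orderings: OrderingSet | None = None,
    keep_replicates: bool = False,
) -> BenchmarkResult:
    """Partial-ordering benchmark with binary toxicity + normal efficacy.

    Per replicate: draw one toxicity and one efficacy profile per patient
    (Gaussian copula correlation ``rho``), quantile-transform into
    complete-information responses, compute per-endpoint ordering
    posteriors (joint product, or one shared-ordering posterior when
    ``shared=True``), apply the selection criterion under every ordering
    pair, and accumulate probability-weighted selections.  Replicates where
    no combination is admissible contribute to the no-selection cell.
    """
    if scenario.eff_means is None:
        raise ValueError("scenario has no efficacy parameters")
    n = int(n if n is not None else scenario.n)
    if criterion is None:
        if scenario.phi is None or scenario.psi is None:
            raise ValueError("scenario lacks (phi, psi) and no criterion was given")
        criterion = Phase12Criterion(phi=scenario.phi, psi=scenario.psi)
    grid = scenario.grid
    if orderings is None:
        orderings = enumerate_linear_extensions(grid)
    assign_t = build_assignments(scenario.tox_probs, orderings, "increasing", prior_mode)
    assign_e = build_assignments(scenario.eff_means, orderings, "decreasing", prior_mode)
    w = compute_weights(grid)
    P = grid.n_combos
    S = orderings.S
    Dt = assign_t.distinct_values
    idx_true_t = np.searchsorted(Dt, scenario.tox_probs.ravel())
    eff_sd = scenario.eff_sd

    Q = np.zeros(P + 1)
    reps = np.empty((Z, P + 1)) if keep_replicates else None
    mtd = isinstance(criterion, MTDDistanceCriterion)
    for z in range(Z):
        prof = generate_profiles(n, Q=2, rho=rho, seed=seed, replicate=z)
        u_t, u_e = prof.u[:, 0], prof.u[:, 1]
        cd_t = (u_t[:, None] < Dt[None, :]).sum(axis=0)  # (Dt,)
        x = cd_t[idx_true_t]
        z_e = stats.norm.ppf(u_e)
        mean_z = float(z_e.mean())
        table_t = binary_log_likelihood_table(x, n, assign_t)
        y = scenario.eff_means.ravel()[None, :] + eff_sd * z_e[:, None]
        table_e = normal_log_likelihood_table(y, assign_e, scale=eff_sd)
        lt_t = gather_log_terms(table_t, assign_t, w, drop_constant=not shared)
        # with one shared ordering the prior enters the bracket once only
        lt_e = gather_log_terms(
            table_e, assign_e, w, drop_constant=not shared, include_prior=not shared
        )

        if mtd:
            p_t = normalize_log_terms(lt_t)
            est = cd_t[assign_t.value_idx] / n  # (S, P)
            mass = _tie_split_mask(np.abs(est - criterion.gamma))
            qz = np.append(p_t @ mass, 0.0)
        else:
            adm_t, adm_e, ybar = _phase12_tables(
                cd_t, n, assign_e.distinct_values, mean_z, criterion, eff_sd
            )
            A1 = adm_t[assign_t.value_idx]  # (S, P)
            A2 = adm_e[assign_e.value_idx]
            E = ybar[assign_e.value_idx]
            if shared:
                p_s = normalize_log_terms(lt_t + lt_e)  # one prior set below
                score = np.where(A1 & A2, E, np.inf)  # (S, P)
                qz = _selection_mass(score, p_s[:, None].T)  # treat as (1, S) pairs
            else:
                p_t = normalize_log_terms(lt_t)
                p_e = normalize_log_terms(lt_e)
                score = np.where(A1[:, None, :] & A2[None, :, :], E[None, :, :], np.inf)
                pjoint = np.outer(p_t, p_e)
                qz = _selection_mass(score.reshape(S * S, P), pjoint.reshape(1, S * S))
        Q += qz
        if reps is not None:
            reps[z] = qz

    proportions = Q / Z
    return BenchmarkResult(
        scenario_name=scenario.name, mode="po_benchmark_multi",
        K=grid.K, L=grid.L, n=n, Z=Z, seed=seed,
        proportions=proportions, targets=list(scenario.targets),
        settings={
            "criterion": criterion.kind, "shared": shared, "rho": rho,
            "prior_mode": prior_mode, "S": S,
            **{k: v for k, v in vars(criterion).items()},
        },
        replicates=reps,
    )


def _selection_mass(score: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Probability-weighted selection mass over positions + no-selection.

    ``score`` is (G, P) with +inf marking inadmissible cells for each of G
    ordering configurations; ``probs`` is (1, G) configuration weights.
    Minimum-score cells split each configuration's weight; configurations
    with no admissible cell send their weight to the trailing cell.
    """
    G, P = score.shape
    w = probs.ravel()
    out = np.zeros(P + 1)
    finite = np.isfinite(score)
    any_adm = finite.any(axis=1)
    if np.any(~any_adm):
        out[P] += w[~any_adm].sum()
    if np.any(any_adm):
        sc = score[any_adm]
        smin = sc.min(axis=1, keepdims=True)
        mask = np.isclose(sc, smin, rtol=0.0, atol=_TIE_ATOL) & np.isfinite(sc)
        mass = mask / mask.sum(axis=1, keepdims=True)
        out[:P] = w[any_adm] @ mass
    return out
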