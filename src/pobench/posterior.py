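"""Posterior probability of each feasible complete ordering.

Given complete-information responses, the benchmark asks how likely it is
that they were generated under each feasible ordering ``s`` of the known
parameter values.  The probability is a *power likelihood* (tempered
Bayesian) posterior: every combination contributes its likelihood times its
prior mass, raised to a weight ``w_kl`` in (0, 1],

    P(s = s' | data)  ∝  prod_kl [ L(data_kl, q_kl^(s')) * h_kl^(s') ]^{w_kl},

so combinations with many incomparable peers — which carry less information
about the complete ordering — are down-weighted.  All arithmetic is in log
space with max-subtraction: with thousands of orderings and a dozen
combinations the direct-space product underflows.

For several endpoints, independent per-endpoint posteriors combine by an
outer product; when toxicity and efficacy are assumed to share one ordering
the two likelihoods multiply inside the same power bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import compute_weights
from .scenario import OrderingAssignment

__all__ = [
    "OrderingPosterior",
    "DegenerateLikelihoodError",
    "ordering_posterior_binary",
    "ordering_posterior_continuous",
    "joint_ordering_posterior",
    "shared_ordering_posterior",
    "binary_log_likelihood_table",
    "normal_log_likelihood_table",
    "gather_log_terms",
    "normalize_log_terms",
    "entropy",
    "class_entropy",
]


class DegenerateLikelihoodError(ValueError):
    """A candidate parameter makes the likelihood identically zero."""


@dataclass
class OrderingPosterior:
    """Probability vector over orderings (or a matrix over ordering pairs)."""

    probs: np.ndarray
    log_terms: np.ndarray  # unnormalized log posterior mass, same shape
    endpoint: str = ""

    @property
    def S(self) -> int:
        return self.probs.size

    def entropy(self) -> float:
        return entropy(self.probs)


def normalize_log_terms(log_terms: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction; rows sum to one exactly as floats allow."""
    shifted = log_terms - np.max(log_terms, axis=axis, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=axis, keepdims=True)


def entropy(probs: np.ndarray) -> float:
    """Shannon entropy in nats; zero entries contribute nothing."""
    p = np.asarray(probs, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def class_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Entropy after pooling orderings with identical assignments.

    Orderings whose value matrices coincide (true-value ties) are
    indistinguishable from data; pooling them measures how concentrated
    the posterior is on *distinguishable* hypotheses.
    """
    pooled = np.bincount(np.asarray(labels), weights=np.asarray(probs, float).ravel())
    return entropy(pooled)


# ---------------------------------------------------------------------------
# log-likelihood tables over distinct candidate values


def binary_log_likelihood_table(
    x: np.ndarray, n: int, assignment: OrderingAssignment
) -> np.ndarray:
    """log Bin(x_kl; n, v_d) for every position and distinct candidate value.

    Parameters
    ----------
    x : (..., K*L) array of DLT counts (a batch of replicates is allowed).

    Returns
    -------
    (..., K*L, D) array.  The binomial coefficient is kept as printed in
    the model even where it cancels in normalization.
    """
    v = assignment.distinct_values
    if np.any(v <= 0) or np.any(v >= 1):
        bad = v[(v <= 0) | (v >= 1)]
        raise DegenerateLikelihoodError(
            f"candidate toxicity probabilities {bad} lie outside (0, 1)"
        )
    x = np.asarray(x)
    return stats.binom.logpmf(x[..., None], n, v[(None,) * x.ndim])


def normal_log_likelihood_table(
    y: np.ndarray, assignment: OrderingAssignment, scale: float = 1.0
) -> np.ndarray:
    """Sum of normal log densities of responses at each candidate location.

    Parameters
    ----------
    y : (n, K*L) responses at each position (one replicate), or a batch
        (Z, n, K*L).

    Returns
    -------
    (..., K*L, D) array with entries ``sum_i log N(y_i; v_d, scale)`` via
    the sufficient statistics (sum, sum of squares).
    """
    if not np.isfinite(scale) or scale <= 0:
        raise DegenerateLikelihoodError(f"non-positive scale {scale}")
    y = np.asarray(y, dtype=float)
    n = y.shape[-2]
    s1 = y.sum(axis=-2)  # (..., KL)
    s2 = (y**2).sum(axis=-2)
    v = assignment.distinct_values
    ss = s2[..., None] - 2.0 * v * s1[..., None] + n * v**2
    out = -0.5 * ss / scale**2 - n * np.log(scale * np.sqrt(2.0 * np.pi))
    if not np.all(np.isfinite(out)):
        raise DegenerateLikelihoodError("non-finite density in likelihood table")
    return out


def gather_log_terms(
    loglik_table: np.ndarray,
    assignment: OrderingAssignment,
    weights: np.ndarray | None = None,
    drop_constant: bool = False,
    include_prior: bool = True,
) -> np.ndarray:
    """Weighted log posterior mass of every ordering from a likelihood table.

    ``log_terms[..., s] = sum_j w_j * (loglik[..., j, idx(s, j)] + log h_j^(s))``
    computed by indexed gather-and-sum over positions, which keeps a
    Z x S batch tractable even for thousands of orderings.

    ``drop_constant`` skips positions with a single candidate value, whose
    contribution is the same for every ordering and cancels in
    normalization (the absolute log level then changes, the posterior
    does not).
    """
    grid = assignment.orderings.grid
    if weights is None:
        weights = compute_weights(grid)
    w = np.asarray(weights, dtype=float).ravel()
    idx = assignment.value_idx  # (S, KL)
    S = assignment.S
    lead = loglik_table.shape[:-2]
    out = np.zeros(lead + (S,))
    for j in range(grid.n_combos):
        if w[j] == 0.0 or (drop_constant and assignment.t[j] == 1):
            continue
        out += w[j] * loglik_table[..., j, :][..., idx[:, j]]
    if include_prior:
        out += (assignment.log_prior * w[None, :]).sum(axis=1)  # (S,)
    return out


# ---------------------------------------------------------------------------
# public posterior operations


def ordering_posterior_binary(
    x: np.ndarray,
    n: int,
    assignment: OrderingAssignment,
    weights: np.ndarray | None = None,
) -> OrderingPosterior:
    """Posterior over orderings for one binary endpoint.

    ``x`` is the K x L matrix of complete-information DLT counts out of n.
    """
    x = np.asarray(x).ravel()
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("counts must lie in 0..n")
    table = binary_log_likelihood_table(x, n, assignment)
    log_terms = gather_log_terms(table, assignment, weights)
    return OrderingPosterior(
        probs=normalize_log_terms(log_terms), log_terms=log_terms, endpoint="binary"
    )


def ordering_posterior_continuous(
    y: np.ndarray,
    assignment: OrderingAssignment,
    weights: np.ndarray | None = None,
    scale: float = 1.0,
) -> OrderingPosterior:
    """Posterior over orderings for one continuous endpoint.

    ``y`` is an (n, K*L) matrix of complete-information responses; the
    endpoint family is normal with known scale and candidate locations
    given by the assignment.
    """
    table = normal_log_likelihood_table(y, assignment, scale=scale)
    log_terms = gather_log_terms(table, assignment, weights)
    return OrderingPosterior(
        probs=normalize_log_terms(log_terms), log_terms=log_terms, endpoint="normal"
    )


def joint_ordering_posterior(
    post_t: OrderingPosterior, post_e: OrderingPosterior
) -> OrderingPosterior:
    """Joint probability of an (s_t, s_e) ordering pair.

    Marginal posteriors multiply and renormalize over all pairs; with
    already-normalized marginals this is simply the outer product.
    """
    joint = np.outer(post_t.probs, post_e.probs)
    joint /= joint.sum()
    log_terms = post_t.log_terms[:, None] + post_e.log_terms[None, :]
    return OrderingPosterior(
        probs=joint, log_terms=log_terms,
        endpoint=f"{post_t.endpoint}*{post_e.endpoint}",
    )


def shared_ordering_posterior(
    x_tox: np.ndarray,
    n: int,
    assignment_t: OrderingAssignment,
    y_eff: np.ndarray,
    assignment_e: OrderingAssignment,
    weights: np.ndarray | None = None,
    scale: float = 1.0,
) -> OrderingPosterior:
    """Posterior over a single ordering shared by toxicity and efficacy.

    Both endpoint likelihoods multiply inside the same power bracket with
    one prior ``h_kl^(s)`` (taken from the toxicity assignment):

        P(s|.) ∝ prod_kl [ L_t * L_e * h_kl^(s) ]^{w_kl}.
    """
    if assignment_t.S != assignment_e.S or assignment_t.orderings.grid != assignment_e.orderings.grid:
        raise ValueError("toxicity and efficacy must share one ordering set")
    grid = assignment_t.orderings.grid
    if weights is None:
        weights = compute_weights(grid)
    w = np.asarray(weights, dtype=float).ravel()
    table_t = binary_log_likelihood_table(np.asarray(x_tox).ravel(), n, assignment_t)
    table_e = normal_log_likelihood_table(y_eff, assignment_e, scale=scale)
    ll = np.zeros(assignment_t.S)
    for j in range(grid.n_combos):
        ll += w[j] * (
            table_t[j, assignment_t.value_idx[:, j]]
            + table_e[j, assignment_e.value_idx[:, j]]
        )
    log_terms = ll + (assignment_t.log_prior * w[None, :]).sum(axis=1)
    return OrderingPosterior(
        probs=normalize_log_terms(log_terms), log_terms=log_terms, endpoint="shared"
    )
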