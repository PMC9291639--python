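"""Latent patient profiles and complete-information responses.

The benchmark's device is *complete information*: each simulated patient i
carries one latent profile ``u^(i) ~ U(0,1)`` per endpoint that determines
their outcome at every combination simultaneously.  A binary toxicity
outcome at combination ``d_kl`` is a DLT iff ``u^(i) < p_kl``; a continuous
outcome is the quantile transform ``F_kl^{-1}(u^(i))`` of the same profile.
Because one profile drives all combinations, responses are perfectly
coherent with the scenario's ordering — the information a real trial could
never collect.

Multiple endpoints share a Gaussian copula: profiles are generated as
correlated standard normals (correlation ``rho``) mapped through the normal
CDF, so each column stays marginally uniform while endpoints co-vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ProfileSet",
    "replicate_rng",
    "generate_profiles",
    "binary_counts",
    "binary_responses",
    "continuous_responses",
    "estimate_under_ordering",
]


@dataclass
class ProfileSet:
    """Latent profiles for one simulated trial: u is (n, Q), columns U(0,1)."""

    u: np.ndarray
    rho: float = 0.0
    seed: object = None

    @property
    def n(self) -> int:
        return self.u.shape[0]

    @property
    def Q(self) -> int:
        return self.u.shape[1]


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible substream for one replicate.

    Built from ``SeedSequence(seed, spawn_key=(replicate,))`` over the
    counter-based Philox generator, so replicate z can be regenerated in
    isolation and any execution order of replicates yields the same data.
    """
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(seed, spawn_key=(replicate,)))
    )


def generate_profiles(
    n: int,
    Q: int = 1,
    rho: float = 0.0,
    seed: int | np.random.Generator = 0,
    replicate: int = 0,
) -> ProfileSet:
    """Draw n patients' latent profiles for Q endpoints.

    ``rho`` is the pairwise correlation of the underlying Gaussian copula
    (applied between every pair of endpoint columns); ``rho = 0`` gives
    independent endpoints, ``rho = 1`` comonotone ones.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    if Q > 2 and rho < 0:
        raise ValueError("negative rho requires Q <= 2 for a valid copula")
    rng = seed if isinstance(seed, np.random.Generator) else replicate_rng(seed, replicate)
    if Q == 1 or rho == 0.0:
        u = rng.random((n, Q))
    elif rho == 1.0:  # comonotone: one profile drives every endpoint
        u = np.tile(rng.random((n, 1)), (1, Q))
    elif rho == -1.0:
        u0 = rng.random((n, 1))
        u = np.hstack([u0, 1.0 - u0])
    else:
        cov = np.full((Q, Q), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(Q), cov, size=n, method="cholesky")
        u = stats.norm.cdf(z)
    return ProfileSet(u=u, rho=rho, seed=seed)


def binary_counts(u: np.ndarray, prob_matrix: np.ndarray) -> np.ndarray:
    """DLT counts ``x_kl = #{i : u^(i) < p_kl}`` for one endpoint column.

    A patient tolerates every combination whose toxicity probability lies
    below their profile; the DLT indicator uses the strict inequality
    ``u < p`` (ties have probability zero).
    """
    u = np.asarray(u, dtype=float).ravel()
    p = np.asarray(prob_matrix, dtype=float)
    return (u[:, None] < p.ravel()[None, :]).sum(axis=0).reshape(p.shape)


def binary_responses(profiles: ProfileSet, prob_matrix: np.ndarray, endpoint: int = 0):
    """Per-patient binary outcome matrix (n, K*L) and per-combination counts."""
    p = np.asarray(prob_matrix, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    y = profiles.u[:, endpoint][:, None] < p.ravel()[None, :]
    return y.astype(np.int8), y.sum(axis=0).reshape(p.shape)


_CONTINUOUS_FAMILIES = {
    "normal": lambda u, loc, scale: stats.norm.ppf(u, loc=loc, scale=scale),
}


def continuous_responses(
    profiles: ProfileSet,
    loc_matrix: np.ndarray,
    scale: float = 1.0,
    family: str = "normal",
    endpoint: int = 0,
) -> np.ndarray:
    """Quantile-transform profiles into continuous responses, (n, K*L).

    Response of patient i at combination (k, l) is ``F_kl^{-1}(u^(i))``
    where ``F_kl`` is the endpoint's CDF with location ``loc_matrix[k, l]``
    and common scale (Phase I/II efficacy uses normal(mu_kl, 1)).
    """
    try:
        ppf = _CONTINUOUS_FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unsupported family {family!r}; known: {sorted(_CONTINUOUS_FAMILIES)}"
        ) from None
    loc = np.asarray(loc_matrix, dtype=float).ravel()
    return ppf(profiles.u[:, endpoint][:, None], loc[None, :], scale)


def estimate_under_ordering(
    profiles: ProfileSet,
    assigned_values: np.ndarray,
    endpoint: int = 0,
    kind: str = "binary",
    scale: float = 1.0,
) -> np.ndarray:
    """Parameter estimates at every position under one ordering's assignment.

    Reuses the trial's own profiles (never regenerating them): for a binary
    endpoint the estimate at a position carrying assigned value q is the
    fraction of profiles strictly below q; for a normal endpoint it is the
    sample mean of the quantile-transformed responses at the assigned mean.
    """
    q = np.asarray(assigned_values, dtype=float).ravel()
    u = profiles.u[:, endpoint]
    if kind == "binary":
        return (u[:, None] < q[None, :]).mean(axis=0)
    if kind == "normal":
        return stats.norm.ppf(u, loc=0.0, scale=scale).mean() + q
    raise ValueError(f"unknown endpoint kind {kind!r}")
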