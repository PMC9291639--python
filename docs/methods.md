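# Methods

## Model and procedure

A dual-agent scenario fixes the true toxicity probability `p_kl` at every
combination `d_kl` of dose `a_k` of drug A and `b_l` of drug B, with
`p_kl` nondecreasing in both indices (and optionally a per-combination
efficacy parameter, nonincreasing in both indices when lower responses are
better).  The benchmark is a Monte-Carlo evaluation tool, not a design: it
answers how often *any* procedure could select a target combination if it
saw each patient's complete information.

Per replicate the engine:

1. draws one latent profile per patient and endpoint, `u ~ U(0,1)`
   (endpoints coupled by a Gaussian copula with correlation `rho`);
2. forms complete-information responses — binary: a DLT at `d_kl` iff
   `u < p_kl`, counts `x_kl`; continuous: the quantile transform
   `F_kl^{-1}(u)`;
3. computes the posterior probability of every feasible complete ordering
   of the combinations (the linear extensions of the grid partial order)
   via the power likelihood
   `P(s|x) ∝ ∏_kl [L(x_kl, q_kl^(s)) · h_kl^(s)]^{w_kl}`, where `q^(s)`
   places the r-th smallest true value at the position with rank r under
   ordering `s`;
4. applies the selection criterion under each ordering, re-using the same
   profiles, and accumulates each ordering's selection weighted by its
   posterior probability;
5. averages the per-replicate selection masses over `Z` replicates.

The known-ordering ("original") mode skips steps 3–4 and selects directly
on `x_kl/n`.  Summing the proportions over the scenario's target set gives
the PCS bound, reported in percent.

Selection criteria:

- **MTC distance** — minimize `|estimate − γ|`; `γ` is the target toxicity
  probability (unitless, typically 0.20–0.35).
- **Phase I/II trade-off** — among combinations whose posterior
  probability of excess toxicity `P(p > φ | x)` (conjugate beta(1,1)
  prior) stays below `η₁` and whose posterior probability that the
  efficacy mean exceeds `ψ` (normal prior on the mean, known unit sampling
  variance) stays below `η₂`, select the best (lowest) mean response;
  replicates with no admissible combination are tallied in a separate
  no-selection cell.  The defaults `η₁ = η₂ = 0.8`, beta(1,1) and
  normal(0, 10²) priors are this package's choices — published
  evaluations of this setting do not disclose their values — and are
  exposed in the configuration.

## Orderings, weights, priors

Feasible complete orderings are enumerated by recursively assigning the
next rank to a currently minimal unfilled grid cell; for a rectangular
grid these are the standard Young tableaux of shape K×L, so the
hook-length formula provides an exact, independent count used both as a
test oracle and as a capacity guard (enumeration refuses above 10⁶
extensions).  Orderings are canonically sorted lexicographically by rank
vector so indices are stable across runs.

The weight `w_kl = 1/(1 + #incomparable(k,l))` down-weights positions
incomparable to many others; incomparability is structural (product
order), giving `w = 1` at the corners and, e.g., `1/5` across the middle
row of a 3×5 grid.

The prior `h_kl^(s)` that the value at a position is the one ordering `s`
assigns there has two modes: `distinct_values` (default) sets
`h = 1/t_kl` with `t_kl` the number of distinct candidate values at the
position; `per_ordering` sets `h` to the fraction of orderings assigning
that value there (the mass induced by a uniform prior over orderings).
Both reduce to `h = 1/2` at the off-diagonal corners of a 2×2 grid with
distinct values.  Under either uniform reading the prior is constant
within a position and cancels in the normalization; it matters only for
informative priors.

## Numerical choices

- All posterior arithmetic is in log space with max-subtraction
  normalization; 6006 orderings × 15 combinations underflow directly.
- Per replicate, the log-pmf is evaluated once per distinct candidate
  value per position and orderings are scored by indexed gather-and-sum;
  positions with a single candidate value contribute a constant and are
  skipped.  Selection likewise depends only on the value at a position,
  so distances are computed per rank and ordering-probability mass is
  scattered to positions through a precomputed rank→position table.  This
  keeps `Z = 10⁴` over `S = 6006` orderings at roughly 15 s on one CPU.
- Ties in the selection criterion split mass equally among exact
  minimizers (`tie_policy="split"`, deterministic given the data); a
  `"first"` policy (plain argmin) is provided because published operating
  characteristics are sensitive to tie handling when several combinations
  share a true value.  Tie detection uses an absolute tolerance of 1e-12
  on distances that are exact multiples of 1/n minus γ.
- RNG: replicate `z` draws from
  `Philox(SeedSequence(seed, spawn_key=(z,)))`, a counter-based substream,
  so any single replicate is reproducible in isolation and any execution
  order yields identical aggregates.
- With `S = 1` (a single-agent chain) the partial-ordering runner
  accumulates exactly as the known-ordering runner, making the two modes
  bit-identical under a shared seed (fancy-indexed arrays are forced to
  C order so reductions round identically).
- Scenario validation requires strict `0 < p < 1` and within-agent
  monotonicity; candidate probabilities at 0 or 1 raise a
  degenerate-likelihood error naming the offending values.

## What the generator emulates — and what it does not

Profiles are exchangeable across patients and constant over time: no
accrual drift, no patient covariates, no missing or delayed outcomes.
The copula couples endpoints within a patient but the marginal laws are
exactly the scenario's; model misspecification is therefore out of frame.
Passing tests show the machinery reproduces the benchmark's operating
characteristics under its own assumptions; they say nothing about how a
real trial deviates from complete information, which no design can attain.

## Sensitivity to unpublished implementation details

The worked 2×2 example, the ordering counts and the per-replicate
brute-force oracles are reproduced exactly.  On tie-heavy 3×5 scenarios
the PCS of the partial-ordering mode is sensitive, at the 1–3 point
level, to choices no published description pins down: the tie policy and
the prior mode interact with duplicated true probabilities (several
orderings then share one assignment).  The defaults (equal split,
`distinct_values`) are kept throughout; the alternatives are exposed as
configuration, not silently blended.  Monte-Carlo standard error of a PCS
near 70% at `Z = 10⁴` is about 0.3–0.5 points.

## Problem sizes used in tests and scripts

Unit and property tests run on 2×2…2×4 grids with `n ≤ 30` and a few
hundred replicates; the full-scale checks use the packaged 3×5 scenarios
at `n = 60`, `Z = 10⁴` (the standard replication count for such tables)
and the consistency check uses `n = 5000`, `Z = 200`, where the pooled
posterior entropy over distinguishable assignments falls below 0.1 nats.
Phase I/II runs in tests use `Z = 300–500`, which is enough for the
qualitative concentration checks; the 2×4 fixtures carry `n = 60` as the
package's choice since the published study does not state its sample
size.
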