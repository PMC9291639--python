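"""Benchmark engine: selection criteria, replicate mechanics, aggregation."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import pobench as pb


# ---------------------------------------------------------------------------
# selection criterion


def test_select_mtd_worked_example():
    """Under the true ordering's estimates, d21 is the unique selection."""
    mass = pb.select_mtd([0.10, 0.50, 0.20, 0.60], gamma=0.20)
    assert np.allclose(mass, [0, 0, 1, 0])


def test_select_mtd_ties():
    assert np.allclose(pb.select_mtd([0.2, 0.2, 0.2], 0.3), 1 / 3)
    assert np.allclose(pb.select_mtd([0.1, 0.3, 0.3], 0.3), [0, 0.5, 0.5])


# ---------------------------------------------------------------------------
# single-replicate audit path


def test_po_replicate_worked_example(worked_scenario, worked_profiles, paper_ordering_index):
    """The printed single-trial selection vector (0.00, 0.31, 0.69, 0.00)."""
    rep = pb.po_replicate_binary(worked_scenario, worked_profiles)
    assert np.array_equal(rep["counts"], [[1, 5], [2, 6]])
    q = np.round(rep["Q"], 2)
    assert np.allclose(q, [0.00, 0.31, 0.69, 0.00])
    # ordering s=1 selects d21, ordering s=2 selects d12
    sel_true = rep["selections"][paper_ordering_index]
    assert np.allclose(sel_true, [0, 0, 1, 0])
    assert np.allclose(rep["selections"][1 - paper_ordering_index], [0, 1, 0, 0])
    assert rep["Q"].sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# benchmark runs, binary endpoint


def test_single_ordering_modes_identical():
    """With S = 1 (a chain) the PO and original benchmarks coincide bit-for-bit."""
    sc = pb.Scenario(
        "chain", [[0.05, 0.15, 0.30, 0.50]], targets=[(1, 3)], gamma=0.30, n=20
    )
    po = pb.run_po_benchmark_binary(sc, Z=200, seed=9)
    orig = pb.run_original_benchmark(sc, Z=200, seed=9)
    assert po.settings["S"] == 1
    assert np.array_equal(po.proportions, orig.proportions)


def test_replicate_mass_conservation(worked_scenario):
    """Every replicate's selection mass sums to one before averaging."""
    res = pb.run_po_benchmark_binary(worked_scenario, Z=50, seed=4, keep_replicates=True)
    assert np.allclose(res.replicates.sum(axis=1), 1.0, atol=1e-9)
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(res.replicates.mean(axis=0), res.proportions, atol=1e-9)


def test_chunking_does_not_change_aggregates(worked_scenario):
    a = pb.run_po_benchmark_binary(worked_scenario, Z=37, seed=5, chunk=8)
    b = pb.run_po_benchmark_binary(worked_scenario, Z=37, seed=5, chunk=1000)
    assert np.allclose(a.proportions, b.proportions, atol=1e-12)


def test_po_never_beats_original_beyond_mc_error():
    """Ordering uncertainty can only blunt the upper bound."""
    for name in ["table2_scenario1", "table2_scenario6"]:
        sc = pb.load_scenario(name)
        po = pb.run_po_benchmark_binary(sc, Z=500, seed=3, keep_replicates=True)
        orig = pb.run_original_benchmark(sc, Z=500, seed=3)
        flat = sc.target_flat_indices()
        se = 100 * po.replicates[:, flat].sum(axis=1).std() / np.sqrt(po.Z)
        assert po.pcs <= orig.pcs + 3 * se


def test_original_benchmark_consistency_limit():
    """A scenario containing gamma exactly is found almost surely as n grows."""
    sc = pb.Scenario(
        "easy", [[0.05, 0.30, 0.60]], targets=[(1, 2)], gamma=0.30, n=5000
    )
    res = pb.run_original_benchmark(sc, Z=500, seed=1)
    assert res.pcs > 99.0


def test_doubling_reps_halves_mc_standard_error(worked_scenario):
    """se(PCS) scales as 1/sqrt(Z): the per-replicate spread is Z-free."""
    r1 = pb.run_po_benchmark_binary(worked_scenario, Z=1000, seed=8, keep_replicates=True)
    r4 = pb.run_po_benchmark_binary(worked_scenario, Z=4000, seed=8, keep_replicates=True)
    flat = worked_scenario.target_flat_indices()
    s1 = r1.replicates[:, flat].sum(axis=1).std()
    s4 = r4.replicates[:, flat].sum(axis=1).std()
    assert s4 == pytest.approx(s1, rel=0.15)
    se_ratio = (s1 / np.sqrt(1000)) / (s4 / np.sqrt(4000))
    assert se_ratio == pytest.approx(2.0, rel=0.2)


def test_table1_scenario1_concentrates_on_diagonal_targets():
    """3x3 illustration: selections concentrate on d12 and d21."""
    sc = pb.load_scenario("table1_scenario1")
    res = pb.run_original_benchmark(sc, Z=2000, seed=2)
    m = res.proportions_matrix
    assert m[0, 1] + m[1, 0] > 0.60
    assert abs(m[0, 1] - m[1, 0]) < 0.10  # symmetric targets, similar mass
    assert res.pcs == pytest.approx(72.8, abs=6.0)  # printed 36.5 + 36.3


def test_tie_policy_first_is_deterministic_and_valid(worked_scenario):
    res = pb.run_po_benchmark_binary(worked_scenario, Z=100, seed=1, tie_policy="first")
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        pb.run_po_benchmark_binary(worked_scenario, Z=10, seed=1, tie_policy="random")


def test_pcs_helpers():
    res = pb.run_original_benchmark(
        pb.Scenario("c", [[0.1, 0.3]], targets=[(1, 2)], gamma=0.3, n=10), Z=20, seed=0
    )
    assert pb.compute_pcs(res, [(1, 1), (1, 2)]) == pytest.approx(100.0, abs=1e-9)
    assert pb.pcs_ratio(72.8, 73.8) == pytest.approx(98.6, abs=0.05)
    with pytest.raises(ValueError):
        pb.compute_pcs(res, [])


# ---------------------------------------------------------------------------
# Phase I/II criterion


def test_phase12_tox_tail_closed_form():
    """x = 0 of 10 with beta(1,1): P(p > 0.3) = 0.7^11 — admissible at eta1 = 0.2."""
    crit = pb.Phase12Criterion(phi=0.3, psi=0.0, eta1=0.2, eta2=1.0)
    scores, adm = pb.phase12_criterion(
        np.array([0]), 10, np.full((10, 1), -1.0), crit
    )
    assert stats.beta.sf(0.3, 1, 11) == pytest.approx(0.7**11, rel=1e-12)
    assert adm[0]
    crit_hot = pb.Phase12Criterion(phi=0.3, psi=0.0, eta1=0.2, eta2=1.0)
    _, adm_hot = pb.phase12_criterion(np.array([8]), 10, np.full((10, 1), -1.0), crit_hot)
    assert not adm_hot[0]


def test_phase12_efficacy_symmetry_at_zero():
    """All-zero responses with psi = 0 give tail 1/2: inadmissible below 0.5."""
    crit = pb.Phase12Criterion(phi=0.3, psi=0.0, eta1=1.0, eta2=0.4)
    _, adm = pb.phase12_criterion(np.array([0]), 10, np.zeros((10, 1)), crit)
    assert not adm[0]
    crit2 = pb.Phase12Criterion(phi=0.3, psi=0.0, eta1=1.0, eta2=0.6)
    _, adm2 = pb.phase12_criterion(np.array([0]), 10, np.zeros((10, 1)), crit2)
    assert adm2[0]


def test_phase12_tails_match_quadrature_oracle():
    """Both posterior tail probabilities agree with numeric integration."""
    rng = np.random.default_rng(21)
    n = 14
    x = 4
    crit = pb.Phase12Criterion(phi=0.3, psi=-0.5)
    a, b = crit.tox_prior
    tail_beta = stats.beta.sf(crit.phi, a + x, b + n - x)
    num, _ = quad(lambda v: stats.beta.pdf(v, a + x, b + n - x), crit.phi, 1.0)
    assert tail_beta == pytest.approx(num, abs=1e-9)

    y = rng.normal(-0.8, 1.0, n)
    post_prec = n + 1.0 / crit.eff_prior_sd**2
    post_mean = (n * y.mean() + crit.eff_prior_mean / crit.eff_prior_sd**2) / post_prec
    tail_norm = stats.norm.sf(crit.psi, post_mean, np.sqrt(1.0 / post_prec))
    num2, _ = quad(
        lambda v: stats.norm.pdf(v, post_mean, np.sqrt(1.0 / post_prec)),
        crit.psi, np.inf,
    )
    assert tail_norm == pytest.approx(num2, abs=1e-9)


# ---------------------------------------------------------------------------
# multi-endpoint engine


def brute_force_multi(scenario, n, Z, seed, criterion, rho=0.0):
    """Straight-line reimplementation of the multi-endpoint benchmark loop."""
    oset = pb.enumerate_linear_extensions(scenario.grid)
    a_t = pb.build_assignments(scenario.tox_probs, oset)
    a_e = pb.build_assignments(scenario.eff_means, oset, direction="decreasing")
    w = pb.compute_weights(scenario.grid)
    P = scenario.grid.n_combos
    Q = np.zeros(P + 1)
    for z in range(Z):
        prof = pb.generate_profiles(n, Q=2, rho=rho, seed=seed, replicate=z)
        u_t, u_e = prof.u[:, 0], prof.u[:, 1]
        x = pb.binary_counts(u_t, scenario.tox_probs).ravel()
        y = scenario.eff_means.ravel()[None, :] + stats.norm.ppf(u_e)[:, None]
        post_t = pb.ordering_posterior_binary(x, n, a_t, w)
        post_e = pb.ordering_posterior_continuous(y, a_e, w)
        joint = pb.joint_ordering_posterior(post_t, post_e)
        for st in range(oset.S):
            x_s = np.array([(u_t < a_t.values[st, j]).sum() for j in range(P)])
            for se in range(oset.S):
                y_s = a_e.values[se][None, :] + stats.norm.ppf(u_e)[:, None]
                scores, adm = pb.phase12_criterion(x_s, n, y_s, criterion)
                pr = joint.probs[st, se]
                if not adm.any():
                    Q[P] += pr
                    continue
                sc = np.where(adm, scores, np.inf)
                mask = np.isclose(sc, sc.min(), rtol=0, atol=1e-12)
                Q[:P] += pr * mask / mask.sum()
    return Q / Z


def test_multi_endpoint_matches_brute_force():
    """Vectorized engine vs independent straight-line loop, 2x2 toy."""
    sc = pb.Scenario(
        "toy12",
        [[0.10, 0.30], [0.25, 0.50]],
        eff_means=[[0.0, -2.0], [-1.0, -3.5]],
        targets=[(1, 2)],
        phi=0.35, psi=-0.5, n=16,
    )
    crit = pb.Phase12Criterion(phi=sc.phi, psi=sc.psi)
    res = pb.run_po_benchmark_multi(sc, Z=60, seed=13, criterion=crit)
    brute = brute_force_multi(sc, 16, 60, 13, crit)
    assert np.allclose(res.proportions, brute, atol=1e-9)
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)


def test_multi_all_admissible_flat_efficacy_selects_uniformly():
    """Flat efficacy + permissive bounds: full ties spread mass evenly."""
    sc = pb.Scenario(
        "flat",
        [[0.05, 0.10], [0.08, 0.15]],
        eff_means=[[-1.0, -1.0], [-1.0, -1.0]],
        targets=[(1, 1)],
        phi=0.9, psi=5.0, n=10,
    )
    crit = pb.Phase12Criterion(phi=0.9, psi=5.0, eta1=1.0, eta2=1.0)
    res = pb.run_po_benchmark_multi(sc, Z=30, seed=2, criterion=crit)
    assert np.allclose(res.proportions[:4], 0.25, atol=1e-9)
    assert res.no_selection == 0.0


def test_multi_nothing_admissible_goes_to_no_selection():
    sc = pb.Scenario(
        "toxic",
        [[0.60, 0.70], [0.65, 0.80]],
        eff_means=[[0.5, 0.0], [0.2, -0.5]],
        targets=[(1, 1)],
        phi=0.05, psi=-10.0, n=20,
    )
    crit = pb.Phase12Criterion(phi=0.05, psi=-10.0, eta1=0.1, eta2=0.1)
    res = pb.run_po_benchmark_multi(sc, Z=20, seed=1, criterion=crit)
    assert res.no_selection == pytest.approx(1.0, abs=1e-12)


def test_multi_mtd_criterion_uses_toxicity_only():
    """With a distance criterion the efficacy endpoint cannot move selections."""
    base = dict(tox_probs=[[0.10, 0.30], [0.20, 0.45]], targets=[(1, 2)], n=24)
    sc_a = pb.Scenario("a", eff_means=[[0.0, -2.0], [-1.0, -3.0]], phi=0.3, psi=0.0, **base)
    sc_b = pb.Scenario("b", eff_means=[[0.0, -0.5], [-0.2, -0.7]], phi=0.3, psi=0.0, **base)
    crit = pb.MTDDistanceCriterion(gamma=0.30)
    ra = pb.run_po_benchmark_multi(sc_a, Z=50, seed=7, criterion=crit)
    rb = pb.run_po_benchmark_multi(sc_b, Z=50, seed=7, criterion=crit)
    assert np.allclose(ra.proportions, rb.proportions, atol=1e-12)


def test_multi_shared_ordering_mode_runs_and_conserves_mass():
    sc = pb.load_scenario("table4_scenario1")
    res = pb.run_po_benchmark_multi(sc, Z=40, seed=3, shared=True)
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.settings["shared"] is True


def test_multi_copula_correlation_accepted():
    sc = pb.load_scenario("table4_scenario1")
    res = pb.run_po_benchmark_multi(sc, Z=20, seed=5, rho=0.5)
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
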