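"""Likelihood correctness against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import binom, multinomial, nbinom, poisson

import countmix as cm
from countmix.likelihoods import (
    binmix_marginal_loglik_arrays,
    multimix_loglik_arrays,
    nb_glmm_loglik_arrays,
)
from oracles import binmix_unit_loglik, cell_probs_enumerated, multimix_unit_loglik


# -- cell probabilities -----------------------------------------------------


def test_cell_probs_symmetric_at_half():
    cp = cm.history_cell_probs(0.5, 3)
    assert np.allclose(cp.pi_obs, 0.125)
    assert cp.pi0 == pytest.approx(0.125)
    assert np.allclose(cp.conditional(), 1 / 7)


def test_cell_probs_zero_detection():
    cp = cm.history_cell_probs(0.0, 3)
    assert cp.pi0 == 1.0
    assert np.allclose(cp.pi_obs, 0.0)


def test_cell_probs_direct_products():
    cp = cm.history_cell_probs(0.2, 3)
    assert cp.histories[1] == "110"
    assert cp.pi_obs[1] == pytest.approx(0.2 * 0.2 * 0.8)
    assert cp.pi0 == pytest.approx(0.8**3)
    with pytest.raises(ValueError):
        cm.history_cell_probs(1.2, 3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(0.0, 1.0), J=st.integers(1, 5))
def test_cell_probs_sum_to_one_and_match_enumeration(p, J):
    cp = cm.history_cell_probs(p, J)
    assert cp.pi_obs.sum() + cp.pi0 == pytest.approx(1.0, abs=1e-12)
    ref = cell_probs_enumerated(p, J)
    assert np.allclose(cp.pi_obs, ref[:-1], atol=1e-12)
    assert cp.pi0 == pytest.approx(ref[-1], abs=1e-12)


# -- latent bound -----------------------------------------------------------


def test_latent_bound_rules():
    assert cm.compute_latent_bound(0) == 60
    assert cm.compute_latent_bound(10) == 180
    assert cm.compute_latent_bound(10, cm.KRule.unmarked()) == 110
    with pytest.raises(ValueError):
        cm.compute_latent_bound(-1)


# -- GLMM -------------------------------------------------------------------


def test_nb_glmm_matches_scipy_and_poisson_limit():
    y = np.arange(6)
    lam = np.full(6, 2.0)
    ll = nb_glmm_loglik_arrays(y, np.log(lam), 1.0)
    ref = nbinom.logpmf(y, 1.0, 1.0 / (1.0 + 2.0)).sum()
    assert ll == pytest.approx(ref, abs=1e-10)
    # phi -> inf limit: Poisson; y=0, lambda=1 has log density -1
    ll0 = nb_glmm_loglik_arrays([0], [0.0], None)
    assert ll0 == pytest.approx(-1.0, abs=1e-12)
    big = nb_glmm_loglik_arrays([0], [0.0], 1e9)
    assert big == pytest.approx(-1.0, abs=1e-6)


def test_nb_glmm_additivity_and_domain_errors():
    one = nb_glmm_loglik_arrays([3], [0.5], 2.0)
    two = nb_glmm_loglik_arrays([3, 3], [0.5, 0.5], 2.0)
    assert two == pytest.approx(2 * one, abs=1e-12)
    with pytest.raises(ValueError):
        nb_glmm_loglik_arrays([1], [0.0], -1.0)


def test_nb_glmm_table_wrapper(small_dataset):
    ap = cm.AbundanceParams(mu_alpha1=1.5, phi=2.0)
    ll = cm.nb_glmm_loglik(small_dataset.counts, ap, small_dataset.effects)
    units = small_dataset.counts
    log_lam, _ = cm.linear_predictors(units, ap, None, small_dataset.effects)
    lam = np.exp(log_lam)
    ref = nbinom.logpmf(units["count"], 2.0, 2.0 / (2.0 + lam)).sum()
    assert ll == pytest.approx(ref, abs=1e-8)


# -- binmix -----------------------------------------------------------------


def test_binmix_matches_bruteforce_oracle(small_dataset, unit_predictors):
    lam, p = unit_predictors
    ap = cm.AbundanceParams(mu_alpha1=1.5, phi=2.0)
    dp = small_dataset.detection
    mine = cm.binmix_marginal_loglik(small_dataset.counts, ap, dp,
                                     small_dataset.effects)
    Y = small_dataset.counts.pivot_table(
        index=["site", "species", "year", "restored"], columns="survey",
        values="count").to_numpy().astype(int)
    lower = Y.max(axis=1)
    K = cm.compute_latent_bound(lower)
    ref = sum(
        binmix_unit_loglik(Y[u], lam[u], p[u], 2.0, lower[u], K[u])
        for u in range(len(Y))
    )
    assert mine == pytest.approx(ref, abs=1e-8)


def test_binmix_poisson_thinning_closed_form():
    """With J = 1 and Poisson abundance, the marginal of a single count is
    Poisson(y; lambda p)."""
    lam, p = 4.0, 0.3
    lp = float(np.log(p / (1 - p)))
    for y in range(11):
        ll = binmix_marginal_loglik_arrays(
            np.array([[y]]), np.log([lam]), [lp], None, np.array([y]),
            np.array([600]))
        assert ll == pytest.approx(poisson.logpmf(y, lam * p), abs=1e-8)


def test_binmix_perfect_detection_forces_latent_zero():
    # y = (0,0,0), p ~ 1, Poisson lambda: marginal = exp(-lambda)
    lam = 2.5
    ll = binmix_marginal_loglik_arrays(
        np.zeros((1, 3), dtype=int), np.log([lam]), [30.0], None,
        np.array([0]), np.array([60]))
    assert ll == pytest.approx(-lam, abs=1e-8)


def test_binmix_random_instance_extreme_k():
    ll = binmix_marginal_loglik_arrays(
        np.array([[2, 1, 3]]), np.log([3.0]), [float(np.log(0.4 / 0.6))], 2.0,
        np.array([3]), np.array([500]))
    ref = binmix_unit_loglik([2, 1, 3], 3.0, 0.4, 2.0, 3, 500)
    assert ll == pytest.approx(ref, abs=1e-8)


def test_binmix_bound_violation_raises():
    with pytest.raises(ValueError, match="bound"):
        binmix_marginal_loglik_arrays(
            np.array([[70, 1, 1]]), np.log([2.0]), [0.0], 2.0,
            np.array([70]), np.array([60]))


# -- multimix ---------------------------------------------------------------


def test_multimix_matches_bruteforce_oracle(small_dataset, unit_predictors):
    lam, p = unit_predictors
    ap = cm.AbundanceParams(mu_alpha1=1.5, phi=2.0)
    dp = small_dataset.detection
    mine = cm.multimix_loglik(small_dataset.histories, ap, dp,
                              small_dataset.effects)
    hcols = [c for c in small_dataset.histories.columns if c.startswith("h")]
    T = small_dataset.histories[hcols].to_numpy()
    n = small_dataset.histories["n"].to_numpy()
    K = cm.compute_latent_bound(n)
    ref = sum(
        multimix_unit_loglik(T[u], n[u], lam[u], float(p[u]), 2.0, K[u])
        for u in range(len(T))
    )
    assert mine == pytest.approx(ref, abs=1e-8)


def test_multimix_empty_unit_reduces_to_pi0_mixture():
    """n = 0: the multinomial term vanishes and the marginal is the NB
    average of pi0^N."""
    lam, phi, p = 3.0, 2.0, 0.4
    ll = multimix_loglik_arrays(
        np.zeros((1, 7), dtype=int), np.array([0]), np.log([lam]),
        [float(np.log(p / (1 - p)))], phi, np.array([60]), 3)
    pi0 = (1 - p) ** 3
    ref = np.log(sum(
        nbinom.pmf(N, phi, phi / (phi + lam)) * pi0**N for N in range(0, 61)
    ))
    assert ll == pytest.approx(ref, abs=1e-8)


def test_multimix_factorization_identity():
    """For known N, the full 8-cell multinomial equals Binomial(n; N, 1-pi0)
    times the conditional multinomial over observable cells."""
    rng = np.random.default_rng(0)
    N, p = 10, 0.3
    cp = cm.history_cell_probs(p, 3)
    probs = np.append(cp.pi_obs, cp.pi0)
    tallies = rng.multinomial(N, probs)
    y, n0 = tallies[:-1], tallies[-1]
    n = int(y.sum())
    full = multinomial.logpmf(tallies, N, probs)
    split = (
        binom.logpmf(n, N, 1 - cp.pi0)
        + multinomial.logpmf(y, n, cp.pi_obs / (1 - cp.pi0))
    )
    assert full == pytest.approx(split, abs=1e-10)


def test_multimix_tally_mismatch_raises():
    with pytest.raises(ValueError, match="sum to n"):
        multimix_loglik_arrays(
            np.ones((1, 7), dtype=int), np.array([3]), np.log([2.0]), [0.0],
            2.0, np.array([96]), 3)


# -- K insensitivity (likelihood level) -------------------------------------


@pytest.mark.parametrize("fn", ["binmix", "multimix"])
def test_k_insensitivity_of_loglik(fn, small_dataset, unit_predictors):
    ap = cm.AbundanceParams(mu_alpha1=1.5, phi=2.0)
    dp = small_dataset.detection
    eff = small_dataset.effects
    if fn == "binmix":
        base = cm.binmix_marginal_loglik(small_dataset.counts, ap, dp, eff)
        double = cm.binmix_marginal_loglik(small_dataset.counts, ap, dp, eff,
                                           rule=cm.KRule(addend=5, multiplier=24))
    else:
        base = cm.multimix_loglik(small_dataset.histories, ap, dp, eff)
        double = cm.multimix_loglik(small_dataset.histories, ap, dp, eff,
                                    rule=cm.KRule(addend=5, multiplier=24))
    assert double == pytest.approx(base, abs=1e-8)


# -- gradients --------------------------------------------------------------


@pytest.mark.parametrize("kind", ["glmm", "binmix", "multimix"])
def test_objective_gradients_match_finite_differences(kind, small_dataset):
    from countmix.inference import _Core

    data = small_dataset.histories if kind == "multimix" else small_dataset.counts
    core = _Core(kind, data)
    rng = np.random.default_rng(5)
    x = core.init() + 0.05 * rng.standard_normal(core.layout.n)
    _, g = core.neg_log_post(x)
    for k in rng.choice(core.layout.n, size=12, replace=False):
        h = 1e-6 * (1 + abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        num = (core.neg_log_post(xp)[0] - core.neg_log_post(xm)[0]) / (2 * h)
        assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-5)
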