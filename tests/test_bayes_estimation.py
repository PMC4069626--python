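"""Posterior kernel, transform selection and quadrature summaries."""

import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from pairomega.alignment_io import PairAlignment
from pairomega.bayes_estimation import (
    GammaPrior,
    bayes_estimate,
    choose_transform,
    log_posterior_kernel,
    posterior_summaries,
)
from pairomega.codon_model import build_rate_matrix
from pairomega.counting_ng import ng_estimate
from pairomega.ml_estimation import log_likelihood, maximize_likelihood
from pairomega.simulator import SimConfig, simulate_pair


def test_prior_defaults_and_validation():
    prior = GammaPrior()
    assert prior.mean_t == pytest.approx(1.0)
    assert prior.mean_omega == pytest.approx(0.5)
    with pytest.raises(ValueError):
        GammaPrior(alpha_t=0.0)


def test_kernel_reduces_to_prior_without_data(fequal, prior):
    val = log_posterior_kernel(None, fequal, 2.0, prior, 0.5, 0.5)
    expected = gamma_dist.logpdf(0.5, 1.1, scale=1 / 1.1) + gamma_dist.logpdf(
        0.5, 1.1, scale=1 / 2.2
    )
    assert val == pytest.approx(expected, abs=1e-10)
    with pytest.raises(ValueError):
        log_posterior_kernel(None, fequal, 2.0, prior, -0.1, 0.5)


def test_kernel_equals_loglik_plus_gamma_densities(fequal, prior):
    aln = simulate_pair(SimConfig(L_c=50, t=0.5, omega=0.5, kappa=2, seed=3))
    model = build_rate_matrix(fequal, kappa=2.0, omega=0.5)
    expected = (
        log_likelihood(aln, model, 0.5)
        + gamma_dist.logpdf(0.5, 1.1, scale=1 / 1.1)
        + gamma_dist.logpdf(0.5, 1.1, scale=1 / 2.2)
    )
    assert log_posterior_kernel(aln, fequal, 2.0, prior, 0.5, 0.5) == pytest.approx(
        expected, abs=1e-8
    )


def test_kernel_decays_for_extreme_omega(fequal, prior):
    aln = simulate_pair(SimConfig(L_c=50, t=0.5, omega=0.5, kappa=2, seed=3))
    vals = [
        log_posterior_kernel(aln, fequal, 2.0, prior, 0.5, w)
        for w in (0.5, 5.0, 50.0, 500.0)
    ]
    assert vals[0] > vals[1] > vals[2] > vals[3]


def test_transform_branch_selection(fequal, prior, case_fixtures):
    expected_branch = {
        "caseI": "ng_branch",
        "caseII": "hessian_branch",
        "caseIII": "hessian_branch",
        "caseIV": "hessian_branch",
        "caseV": "hessian_branch",
    }
    for name, aln in case_fixtures.items():
        ng = ng_estimate(aln)
        ml = maximize_likelihood(aln, fequal, ng=ng)
        tr = choose_transform(ml, ng, aln, fequal, prior, kappa=ml.kappa_hat)
        assert tr.source == expected_branch[name], name
        assert tr.sigma1 > 0 and tr.sigma2 > 0


def test_ng_branch_centers_at_log_mles(fequal, prior, case_fixtures):
    aln = case_fixtures["caseI"]
    ng = ng_estimate(aln)
    ml = maximize_likelihood(aln, fequal, ng=ng)
    tr = choose_transform(ml, ng, aln, fequal, prior, kappa=ml.kappa_hat)
    assert tr.mu1 == pytest.approx(math.log(ml.t_hat))
    assert tr.mu2 == pytest.approx(math.log(ml.omega_hat))


def test_no_data_posterior_equals_prior(fequal):
    prior = GammaPrior()
    res = bayes_estimate(None, fequal, prior=prior)
    assert res.mean_t == pytest.approx(prior.mean_t, abs=1e-3)
    assert res.mean_omega == pytest.approx(prior.mean_omega, abs=1e-3)
    # gamma survival-function oracle for the positive-selection probability
    tail = float(gamma_dist.sf(1.0, 1.1, scale=1 / 2.2))
    assert res.prob_omega_gt1 == pytest.approx(tail, abs=1e-3)
    # prior variances: alpha/beta^2
    assert res.var_t == pytest.approx(1.1 / 1.1**2, rel=1e-3)
    assert res.var_omega == pytest.approx(1.1 / 2.2**2, rel=1e-3)


def test_summaries_finite_on_all_case_fixtures(fequal, prior, case_fixtures):
    for name, aln in case_fixtures.items():
        res = bayes_estimate(aln, fequal, prior=prior)
        for v in (res.mean_t, res.mean_omega, res.var_t, res.var_omega,
                  res.cov_t_omega, res.prob_omega_gt1):
            assert math.isfinite(v), f"{name}: non-finite summary"
        assert res.var_t >= 0 and res.var_omega >= 0
        assert abs(res.cov_t_omega) <= math.sqrt(res.var_t * res.var_omega) + 1e-12
        assert 0.0 <= res.prob_omega_gt1 <= 1.0


def test_tail_probability_complement(fequal, prior, case_fixtures):
    """P(omega > 1 | x) + P(omega <= 1 | x) = 1 computed as two restrictions."""
    from pairomega.bayes_estimation import _PosteriorKernel, _map_nodes
    from scipy.special import roots_legendre

    aln = case_fixtures["caseIV"]
    ng = ng_estimate(aln)
    ml = maximize_likelihood(aln, fequal, ng=ng)
    tr = choose_transform(ml, ng, aln, fequal, prior, kappa=ml.kappa_hat)
    res = posterior_summaries(aln, fequal, ml.kappa_hat, prior, tr, n=32)
    # complementary restriction: z2 in (-1, z*)
    kern = _PosteriorKernel(aln, fequal, ml.kappa_hat, prior)
    z_star = math.tanh(-tr.mu2 / (2 * tr.sigma2))
    z, w = roots_legendre(32)
    ts, jac1 = _map_nodes(z, tr.mu1, tr.sigma1)
    half = (z_star + 1.0) / 2.0
    z2 = -1.0 + half * (z + 1.0)
    np.clip(z2, -1 + 1e-15, 1 - 1e-15, out=z2)
    oms, jac2 = _map_nodes(z2, tr.mu2, tr.sigma2)
    r = np.exp(kern.log_g_grid(ts, oms) - res.l_max) * np.outer(ts * jac1, oms * jac2)
    p_le1 = float(w @ r @ w) * half / res.norm_const_scaled
    assert res.prob_omega_gt1 + p_le1 == pytest.approx(1.0, abs=1e-6)


def test_quadrature_convergence_32_vs_64(fequal, prior, case_fixtures):
    """Summaries are already converged at the default 32 points."""
    for name, aln in case_fixtures.items():
        ng = ng_estimate(aln)
        ml = maximize_likelihood(aln, fequal, ng=ng)
        tr = choose_transform(ml, ng, aln, fequal, prior, kappa=ml.kappa_hat)
        s32 = posterior_summaries(aln, fequal, ml.kappa_hat, prior, tr, n=32)
        s64 = posterior_summaries(aln, fequal, ml.kappa_hat, prior, tr, n=64)
        assert s32.mean_t == pytest.approx(s64.mean_t, rel=1e-4), name
        assert s32.mean_omega == pytest.approx(s64.mean_omega, rel=1e-4), name
        assert s32.prob_omega_gt1 == pytest.approx(
            s64.prob_omega_gt1, rel=1e-4, abs=1e-9
        ), name
        # second moments converge slightly slower for the skewed,
        # prior-dominated identical-sequence posterior
        vtol = 1e-3 if name == "caseII" else 1e-4
        assert s32.var_t == pytest.approx(s64.var_t, rel=vtol), name
        assert s32.var_omega == pytest.approx(s64.var_omega, rel=vtol), name


def test_posterior_tracks_mle_when_data_dominate(fequal, prior):
    aln = simulate_pair(SimConfig(L_c=5000, t=1.0, omega=0.5, kappa=2, seed=77))
    ng = ng_estimate(aln)
    ml = maximize_likelihood(aln, fequal, ng=ng)
    res = bayes_estimate(aln, fequal, prior=prior, ml=ml, ng=ng)
    assert abs(res.mean_t - ml.t_hat) < 0.02
    assert abs(res.mean_omega - ml.omega_hat) < 0.02


def test_more_informative_prior_shrinks_toward_its_mean(fequal):
    """Under AP1 (omega ~ G(2,4)) posteriors move toward 0.5."""
    default = GammaPrior()
    ap1 = GammaPrior(alpha_t=2.0, beta_t=2.0, alpha_omega=2.0, beta_omega=4.0)
    # a pair with a low MLE of omega
    aln = simulate_pair(SimConfig(L_c=150, t=0.3, omega=0.05, kappa=2, seed=55))
    r_def = bayes_estimate(aln, fequal, prior=default)
    r_ap1 = bayes_estimate(aln, fequal, prior=ap1)
    assert r_ap1.mean_omega > r_def.mean_omega  # pulled up toward 0.5
    # and a pair with a high MLE of omega
    aln2 = simulate_pair(SimConfig(L_c=150, t=0.3, omega=4.0, kappa=2, seed=56))
    r_def2 = bayes_estimate(aln2, fequal, prior=default)
    r_ap12 = bayes_estimate(aln2, fequal, prior=ap1)
    assert r_ap12.mean_omega < r_def2.mean_omega  # pulled down toward 0.5


def test_identical_sequences_posterior_means(fequal, prior, case_fixtures):
    res = bayes_estimate(case_fixtures["caseII"], fequal, prior=prior)
    assert res.mean_t == pytest.approx(0.011, abs=0.005)
    assert res.mean_omega == pytest.approx(0.496, abs=0.02)
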