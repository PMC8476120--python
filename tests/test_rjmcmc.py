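"""Reversible-jump mixture sampler: Gibbs validity, recovery, thresholds."""

from __future__ import annotations

import numpy as np
import pytest

from collapse_kinetics.rjmcmc import (
    NINE_COMPONENT_REFERENCE,
    MixtureHyperParams,
    assign_counts_by_cutoff,
    cutoffs_from_means,
    linearity_check,
    modal_k,
    run_chain,
    run_chains,
    summarize,
)


def test_same_seed_gives_identical_chain():
    rng = np.random.default_rng(0)
    data = rng.normal(100, 5, 200)
    a = run_chain(data, n_sweeps=200, seed=3)
    b = run_chain(data, n_sweeps=200, seed=3)
    assert [s.k for s in a] == [s.k for s in b]
    assert all(np.array_equal(x.means, y.means) for x, y in zip(a, b))


def test_zero_range_data_rejected():
    with pytest.raises(ValueError):
        run_chain(np.full(100, 7.0), n_sweeps=10, seed=0)


def test_mean_ordering_invariant_holds_at_every_sweep():
    rng = np.random.default_rng(1)
    data = np.concatenate([rng.normal(100, 5, 300), rng.normal(200, 5, 300)])
    chain = run_chain(data, MixtureHyperParams(k_max=5), n_sweeps=800, seed=5)
    for s in chain:
        assert np.all(np.diff(s.means) > 0)
        assert s.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s.weights > 0)


def test_fixed_k_gibbs_matches_quadrature_posterior():
    """With dimension moves disabled the sampler is a plain Gibbs sampler.

    Independent oracle: for one component the posterior of (mu, tau) given
    the hierarchical prior (beta integrated out analytically against its
    Gamma(g, h) hyperprior) is evaluated on a 2-D quadrature grid; the Gibbs
    posterior means must agree within Monte Carlo error (< 2%).
    """
    rng = np.random.default_rng(2)
    data = rng.normal(120.0, 10.0, 150)
    hp = MixtureHyperParams(k_max=1).resolve(data)
    chain = run_chain(data, hp, n_sweeps=6000, seed=9, fix_k=True)
    kept = chain[1000:]
    mu_hat = np.mean([s.means[0] for s in kept])
    tau_hat = np.mean([1.0 / s.variances[0] for s in kept])

    # quadrature oracle -----------------------------------------------------
    # p(tau) = integral Gamma(tau; a, b) Gamma(b; g, h) db  (compound gamma)
    #        = h^g/B(a,g) * tau^(a-1) / (tau + h)^(a+g)  up to normalisation
    from scipy.special import gammaln

    y = data
    n = y.size
    a, g, h, kappa, xi = hp.alpha, hp.g, hp.h, hp.kappa, hp.xi
    mu_grid = np.linspace(y.mean() - 6 * y.std() / np.sqrt(n),
                          y.mean() + 6 * y.std() / np.sqrt(n), 401)
    tau_grid = np.linspace(1e-5, 5.0 / y.var(), 801)
    M, T = np.meshgrid(mu_grid, tau_grid, indexing="ij")
    ss = n * (M - y.mean()) ** 2 + ((y - y.mean()) ** 2).sum()
    log_post = (
        (a - 1 + n / 2) * np.log(T)
        - (a + g) * np.log(T + h)   # compound-gamma prior with beta integrated
        - 0.5 * T * ss
        - 0.5 * kappa * (M - xi) ** 2
    )
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    mu_oracle = float((post * M).sum())
    tau_oracle = float((post * T).sum())

    assert abs(mu_hat - mu_oracle) <= 0.02 * abs(mu_oracle)
    assert abs(tau_hat - tau_oracle) <= 0.05 * abs(tau_oracle)


def test_single_component_data_yields_modal_k_one():
    rng = np.random.default_rng(3)
    data = rng.normal(100, 5, 500)
    chains = run_chains(data, MixtureHyperParams(k_max=5), n_sweeps=1500,
                        n_chains=2, seed=4)
    assert modal_k(chains) == 1


def test_two_component_recovery_and_weights():
    rng = np.random.default_rng(4)
    data = np.concatenate([rng.normal(100, 5, 500), rng.normal(200, 5, 500)])
    chains = run_chains(data, MixtureHyperParams(k_max=6), n_sweeps=2500,
                        n_chains=2, seed=6)
    assert modal_k(chains) == 2
    summary = summarize(chains, 2)
    assert abs(summary.means[0] - 100) <= 3.0
    assert abs(summary.means[1] - 200) <= 3.0
    assert abs(summary.weights[0] - 0.5) <= 0.05
    assert abs(summary.weights[1] - 0.5) <= 0.05


def test_summarize_trivial_cases():
    from collapse_kinetics.rjmcmc import MixtureState

    st = MixtureState(k=2, means=np.array([10.0, 20.0]),
                      variances=np.array([4.0, 9.0]),
                      weights=np.array([0.4, 0.6]), beta=1.0)
    chain = [st] * 10
    s1 = summarize([chain], 2, burn_in_frac=0.0)
    assert np.allclose(s1.means, [10, 20])
    assert np.allclose(s1.weights, [0.4, 0.6])
    assert s1.occupancy_fraction == 1.0
    s2 = summarize([chain, list(chain)], 2, burn_in_frac=0.0)
    assert np.allclose(s2.means, s1.means)
    with pytest.raises(ValueError):
        summarize([chain], 3)


def test_linearity_check_exact_line():
    slope, r2 = linearity_check(np.array([0.0, 100.0, 200.0, 300.0]))
    assert slope == pytest.approx(100.0)
    assert r2 == pytest.approx(1.0)


def test_linearity_check_on_published_nine_component_means():
    means = np.array(NINE_COMPONENT_REFERENCE["means"])
    slope, r2 = linearity_check(means)
    oracle = np.polyfit(np.arange(1, 9), means[1:], 1)
    assert slope == pytest.approx(oracle[0])
    assert r2 > 0.9  # the published class means are close to a straight line


def test_linearity_check_needs_three_components():
    with pytest.raises(ValueError):
        linearity_check(np.array([1.0, 2.0]))


def test_cutoffs_midpoints():
    assert cutoffs_from_means(np.array([0.0, 10.0])).tolist() == [5.0]
    cuts = cutoffs_from_means(np.array([1.0, 3.0, 7.0]))
    assert cuts.tolist() == [2.0, 5.0]


def test_cutoffs_published_nine_component_boundaries():
    cuts = cutoffs_from_means(np.array(NINE_COMPONENT_REFERENCE["means"]))
    # (24.52 + 138.57)/2 = 81.545, printed as 81.55 (half-up)
    assert cuts[0] == pytest.approx(81.545, abs=1e-9)
    # (138.57 + 173.87)/2 = 156.22 exactly at two decimals
    assert cuts[1] == pytest.approx(156.22, abs=1e-9)


def test_cutoffs_reject_unordered_means():
    with pytest.raises(ValueError):
        cutoffs_from_means(np.array([5.0, 3.0]))


def test_assign_counts_by_cutoff():
    cuts = cutoffs_from_means(np.array(NINE_COMPONENT_REFERENCE["means"]))
    assert assign_counts_by_cutoff(100.0, cuts) == 1
    assert assign_counts_by_cutoff(10.0, cuts) == 0
    assert assign_counts_by_cutoff(1e4, cuts) == 8
    out = assign_counts_by_cutoff(np.array([10.0, 100.0, 400.0]), cuts)
    assert out.tolist() == [0, 1, 6]
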