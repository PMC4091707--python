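"""Steady state, likelihood, model selection, inversion — with 4^L oracles."""

import numpy as np
import pytest

from bindscape.background import (
    enumerate_sequence_space,
    neutral_energy_spectrum,
    neutral_log_probs_encoded,
    quantized_matrix,
)
from bindscape.fitness import ExponentialParams, FermiDiracParams, log_fd_fitness
from bindscape.inference import (
    GridSpec,
    aicc,
    akaike_weights,
    exp_factorized_steady_state,
    fit_gridsearch,
    invert_landscape,
    log_likelihood,
    log_odds_matrix,
    profile_likelihood,
    steady_state_density,
)
from bindscape.energy import random_energy_matrix
from bindscape.synthetic import sample_steady_state_sites


def _quantized_energies(matrix, spectrum, idx):
    k = quantized_matrix(matrix, spectrum.bin_width)
    L = matrix.length
    return k[np.arange(L), idx].sum(axis=1) * spectrum.bin_width


def _fd_fn(params):
    return lambda E: log_fd_fitness(E, params.f0, params.beta, params.mu)


class TestSteadyStateDensity:
    def test_nu_zero_returns_q0(self, small_spectrum):
        params = FermiDiracParams(f0=0.5, beta=1.0, mu=3.0)
        dens = steady_state_density(small_spectrum, _fd_fn(params), 0.0)
        assert np.allclose(dens, small_spectrum.probs)

    def test_matches_sequence_enumeration(self, yeast_bg, small_matrix, small_spectrum):
        """Brute-force sum of pi0 F^nu over all 4^L sequences, binned."""
        params = FermiDiracParams(f0=0.1, beta=1.686, mu=4.0)
        nu = 5.0
        dens = steady_state_density(small_spectrum, _fd_fn(params), nu)
        idx = enumerate_sequence_space(4)
        pi0 = np.exp(neutral_log_probs_encoded(yeast_bg, idx))
        qe = _quantized_energies(small_matrix, small_spectrum, idx)
        w = pi0 * np.exp(nu * _fd_fn(params)(qe))
        expected = np.zeros(small_spectrum.probs.size)
        np.add.at(expected, small_spectrum.bin_index(qe), w)
        expected /= expected.sum()
        assert np.abs(dens - expected).max() < 1e-8

    def test_invariant_under_fitness_rescaling(self, small_spectrum):
        params = FermiDiracParams(f0=0.2, beta=1.0, mu=4.0)
        nu = 3.0
        a = steady_state_density(small_spectrum, _fd_fn(params), nu)
        shifted = lambda E: _fd_fn(params)(E) + 1.7  # F -> cF
        b = steady_state_density(small_spectrum, shifted, nu)
        assert np.allclose(a, b, atol=1e-12)


class TestLogLikelihood:
    def test_deterministic(self, small_spectrum):
        params = FermiDiracParams(f0=0.3, beta=1.2, mu=3.5)
        E = np.array([3.0, 3.5, 4.0])
        a = log_likelihood(E, small_spectrum, _fd_fn(params), 4.0)
        b = log_likelihood(E, small_spectrum, _fd_fn(params), 4.0)
        assert a == b

    def test_matches_sequence_space_likelihood(self, yeast_bg, small_matrix, small_spectrum):
        """Full sequence-space likelihood (pi0 terms dropped from both)."""
        rng = np.random.default_rng(0)
        params = FermiDiracParams(f0=0.05, beta=1.686, mu=4.0)
        nu = 3.0
        idx = enumerate_sequence_space(4)
        pi0 = np.exp(neutral_log_probs_encoded(yeast_bg, idx))
        qe = _quantized_energies(small_matrix, small_spectrum, idx)
        sites = idx[rng.choice(idx.shape[0], size=40)]
        site_E = _quantized_energies(small_matrix, small_spectrum, sites)
        got = log_likelihood(site_E, small_spectrum, _fd_fn(params), nu)
        lw = nu * _fd_fn(params)(qe)
        Z = (pi0 * np.exp(lw)).sum()
        expected = (nu * _fd_fn(params)(site_E)).sum() - site_E.size * np.log(Z)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_gamma_degeneracy_on_tail_data(self, medium_matrix, medium_spectrum):
        """Constant gamma = nu (1 - f0): tail-only data give equal lnL."""
        support = medium_spectrum.centers[medium_spectrum.probs > 0]
        mu = support.min() - 6.0
        E = support[(support > mu + 7.0) & (support < mu + 10.0)][:50]
        gamma = 5.0
        lnls = []
        for f0 in (0.99, 0.999, 0.9999):
            nu = gamma / (1 - f0)
            p = FermiDiracParams(f0=f0, beta=1.0, mu=mu, nu=nu)
            lnls.append(log_likelihood(E, medium_spectrum, _fd_fn(p), nu))
        assert max(lnls) - min(lnls) < 0.01

    def test_gamma_degeneracy_steady_state_tvd(self, medium_spectrum):
        support = medium_spectrum.centers[medium_spectrum.probs > 0]
        mu = support.min() - 2.0
        gamma = 20.0
        dens = []
        for f0 in (0.99, 0.999, 0.9999):
            nu = gamma / (1 - f0)
            p = FermiDiracParams(f0=f0, beta=1.0, mu=mu, nu=nu)
            dens.append(steady_state_density(medium_spectrum, _fd_fn(p), nu))
        for i in range(len(dens)):
            for j in range(i + 1, len(dens)):
                assert 0.5 * np.abs(dens[i] - dens[j]).sum() < 0.01

    def test_mu_shift_degeneracy_on_tail(self, medium_spectrum):
        """On the exponential tail, mu -> mu + d with gamma e^{beta d} held
        fixed leaves the steady state unchanged."""
        support = medium_spectrum.centers[medium_spectrum.probs > 0]
        beta = 1.0
        mu = support.min() - 3.0
        d = 2.0 / beta
        f0 = 0.99
        gamma = 10.0
        a = steady_state_density(
            medium_spectrum,
            _fd_fn(FermiDiracParams(f0=f0, beta=beta, mu=mu)),
            gamma / (1 - f0),
        )
        # shifting mu down by d scales the tail weight by e^{-beta d}
        b = steady_state_density(
            medium_spectrum,
            _fd_fn(FermiDiracParams(f0=f0, beta=beta, mu=mu - d)),
            gamma * np.exp(beta * d) / (1 - f0),
        )
        assert 0.5 * np.abs(a - b).sum() < 0.01

    def test_energy_outside_support_rejected(self, small_spectrum):
        params = FermiDiracParams(f0=0.5, beta=1.0, mu=0.0)
        with pytest.raises(ValueError):
            log_likelihood([1e3], small_spectrum, _fd_fn(params), 1.0)


class TestAicc:
    def test_worked_example(self):
        assert aicc(-100.0, 4, 50) == pytest.approx(208.8889, abs=1e-4)

    def test_large_n_limit(self):
        assert aicc(-10.0, 3, 10**7) == pytest.approx(2 * 3 + 20, abs=1e-4)

    def test_penalty_difference_limit(self):
        # equal lnL, k=3 vs k=4: AICc difference -> -2 as n -> infinity
        d = aicc(-50.0, 3, 10**7) - aicc(-50.0, 4, 10**7)
        assert d == pytest.approx(-2.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 4, 5)


class TestAkaikeWeights:
    def test_equal_aicc_uniform(self):
        assert np.allclose(akaike_weights([10.0, 10.0, 10.0]), 1 / 3)

    @pytest.mark.parametrize(
        "deltas, expected, tol",
        [
            # printed AIC differences (CFD-UFD, EXP-UFD) and weights
            ((0.0, 3.054, 35.734), (0.822, 0.178, 1.43e-8), 1e-3),
            ((0.0, -1.469, -3.869), (0.100, 0.208, 0.692), 1e-3),
        ],
    )
    def test_published_weight_rows(self, deltas, expected, tol):
        w = akaike_weights(np.array(deltas))
        for got, want in zip(w, expected):
            if want < 1e-6:
                assert got == pytest.approx(want, rel=0.05)
            else:
                assert got == pytest.approx(want, abs=tol)


class TestGridSearch:
    def test_exp_rate_recovery(self, yeast_bg, medium_matrix, medium_spectrum):
        """Sites generated under exponential fitness recover the rate."""
        rate = 2.0
        p = FermiDiracParams(f0=0.0, beta=1.0, mu=0.0)  # placeholder
        idx = enumerate_sequence_space(8)
        pi0 = np.exp(neutral_log_probs_encoded(yeast_bg, idx))
        E = medium_matrix.energies_encoded(idx)
        w = pi0 * np.exp(-rate * E)
        w /= w.sum()
        rng = np.random.default_rng(1)
        sites_E = E[rng.choice(idx.shape[0], size=1000, p=w)]
        fit = fit_gridsearch(sites_E, medium_spectrum, "EXP")
        assert fit.params.rate == pytest.approx(rate, rel=0.10)
        assert fit.k == 1

    def test_cfd_matches_ufd_on_tail_data(self, yeast_bg, medium_matrix, medium_spectrum):
        """Tail-regime data: constrained f0=0.99 fit is as likely as the
        unconstrained one (raw likelihoods essentially equivalent)."""
        truth = FermiDiracParams(
            f0=0.99, beta=1.0, mu=medium_matrix.min_energy - 3.0, nu=20000.0
        )
        from bindscape.background import quantized_site_energies

        sites = sample_steady_state_sites(
            medium_matrix, yeast_bg, truth, truth.nu, 500, seed=3
        )
        E = quantized_site_energies(medium_matrix, medium_spectrum, sites)
        # full default mesh: on a coarsened mesh the constrained fit pays a
        # larger quantization penalty and the comparison is not meaningful
        ufd = fit_gridsearch(E, medium_spectrum, "UFD")
        cfd = fit_gridsearch(E, medium_spectrum, "CFD")
        assert abs(ufd.log_likelihood - cfd.log_likelihood) < 0.5
        # the data sit on the exponential tail of the generating landscape
        from bindscape.fitness import classify_regime

        assert classify_regime(truth, E) == "exponential_tail"
        assert cfd.flags["gamma_degenerate"]  # f0 pinned at its cap
        assert cfd.k == 3 and ufd.k == 4

    def test_empty_mesh_rejected(self, small_spectrum):
        grid = GridSpec(beta=np.array([]))
        with pytest.raises(ValueError):
            fit_gridsearch(np.array([3.0] * 40), small_spectrum, "UFD", grid=grid)

    def test_few_sites_warns(self, small_spectrum):
        support = small_spectrum.centers[small_spectrum.probs > 0]
        grid = GridSpec().coarsen(4)
        with pytest.warns(UserWarning, match="sites"):
            fit_gridsearch(support[:5], small_spectrum, "EXP", grid=grid)


class TestInvertLandscape:
    def test_round_trip_recovery(self, yeast_bg, medium_matrix, medium_spectrum):
        """Sites from a known FD steady state reproduce ln F up to an
        affine transform with R^2 > 0.95 over populated bins."""
        truth = FermiDiracParams(f0=np.exp(-10), beta=1.686, mu=4.0, nu=6.0)
        sites = sample_steady_state_sites(
            medium_matrix, yeast_bg, truth, truth.nu, 10_000, seed=5
        )
        E = medium_matrix.energies(sites)
        land = invert_landscape(E, medium_spectrum, truth.nu, n_bins=15)
        centers = land.bin_centers[land.defined]
        est = land.log_fitness[land.defined]
        true_lnF = log_fd_fitness(centers, truth.f0, truth.beta, truth.mu)
        A = np.vstack([true_lnF, np.ones_like(true_lnF)]).T
        coef, res, *_ = np.linalg.lstsq(A, est, rcond=None)
        pred = A @ coef
        ss_res = ((est - pred) ** 2).sum()
        ss_tot = ((est - est.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.95

    def test_neutral_sites_give_flat_landscape(self, yeast_bg, medium_matrix, medium_spectrum):
        idx = enumerate_sequence_space(8)
        pi0 = np.exp(neutral_log_probs_encoded(yeast_bg, idx))
        rng = np.random.default_rng(6)
        E = medium_matrix.energies_encoded(
            idx[rng.choice(idx.shape[0], size=5000, p=pi0 / pi0.sum())]
        )
        land = invert_landscape(E, medium_spectrum, nu=5.0, n_bins=15)
        d = land.defined & (land.counts > 10)
        resid = land.log_fitness[d] - np.nanmean(land.log_fitness[d])
        assert np.all(np.abs(resid) < 3 * land.se[d] + 0.05)

    def test_empty_bins_flagged(self, medium_spectrum):
        support = medium_spectrum.centers[medium_spectrum.probs > 0]
        E = np.full(100, support[support.size // 2])
        land = invert_landscape(E, medium_spectrum, nu=2.0, n_bins=15)
        assert not land.defined.all()
        assert np.isnan(land.log_fitness[~land.defined]).all()


class TestProfileLikelihood:
    def test_profile_max_consistent_with_fit(self, yeast_bg, medium_matrix, medium_spectrum):
        from bindscape.background import quantized_site_energies

        truth = FermiDiracParams(f0=np.exp(-10), beta=1.686, mu=4.0, nu=6.0)
        sites = sample_steady_state_sites(
            medium_matrix, yeast_bg, truth, truth.nu, 300, seed=7
        )
        E = quantized_site_energies(medium_matrix, medium_spectrum, sites)
        grid = GridSpec().coarsen(4)
        fit = fit_gridsearch(E, medium_spectrum, "UFD", grid=grid)
        vals = [truth.mu - 1.0, fit.params.mu, truth.mu + 1.0]
        prof = profile_likelihood(E, medium_spectrum, "UFD", "mu", vals, grid=grid)
        assert prof[1] == pytest.approx(fit.log_likelihood, abs=1e-9)
        assert prof[1] >= max(prof) - 1e-9


def test_likelihood_heatmap_has_constant_gamma_ridge(yeast_bg, medium_matrix,
                                                     medium_spectrum):
    """On tail data the (nu, f0) heatmap is flat along constant gamma:
    cells with matched gamma have nearly equal re-optimized lnL."""
    from bindscape.background import quantized_site_energies
    from bindscape.inference import likelihood_heatmap

    truth = FermiDiracParams(
        f0=0.99, beta=1.0, mu=medium_matrix.min_energy - 3.0, nu=20000.0
    )
    sites = sample_steady_state_sites(
        medium_matrix, yeast_bg, truth, truth.nu, 300, seed=9
    )
    E = quantized_site_energies(medium_matrix, medium_spectrum, sites)
    base = GridSpec().coarsen(2)
    # cells (nu=1e3, f0=0.99) and (nu=1e4, f0=0.999) share gamma = 10
    grid = GridSpec(beta=base.beta, nu=np.array([1e3, 1e4]),
                    f0=np.array([0.99, 0.999]), mu_step=base.mu_step)
    nus, f0s, heat = likelihood_heatmap(E, medium_spectrum, grid=grid)
    assert heat.shape == (2, 2)
    # matched-gamma cells are near-degenerate (residual ~ n gamma p (1-f0));
    # the mismatched-gamma cells in the same rows are far worse
    assert abs(heat[0, 0] - heat[1, 1]) < 2.0
    assert heat[0, 1] < heat[0, 0] - 10.0
    assert heat[1, 0] > heat[1, 1] - 50.0  # gamma=100 still on the ridge side


class TestFactorizedExponential:
    def test_rate_zero_returns_background(self, yeast_bg, small_matrix):
        p = exp_factorized_steady_state(yeast_bg.mono, small_matrix, 0.0)
        assert np.allclose(p, yeast_bg.mono[None, :])

    def test_matches_enumeration(self, small_matrix):
        """Factorized per-position marginals equal the marginals of the
        full sequence distribution pi0 e^{-rate E} (mono background)."""
        mono = np.array([0.31, 0.19, 0.19, 0.31])
        rate = 1.3
        p = exp_factorized_steady_state(mono, small_matrix, rate)
        idx = enumerate_sequence_space(4)
        pi0 = mono[idx].prod(axis=1)
        w = pi0 * np.exp(-rate * small_matrix.energies_encoded(idx))
        w /= w.sum()
        for i in range(4):
            marg = np.bincount(idx[:, i], weights=w, minlength=4)
            assert np.abs(marg - p[i]).max() < 1e-12

    def test_log_odds_round_trip(self, small_matrix):
        """log_odds(factorized steady state) recovers rate * eps up to a
        per-position additive shift."""
        mono = np.array([0.31, 0.19, 0.19, 0.31])
        rate = 0.8
        p = exp_factorized_steady_state(mono, small_matrix, rate)
        eps_hat = log_odds_matrix(p, mono, beta_lo=1.0)
        resid = eps_hat - rate * small_matrix.epsilon
        resid -= resid.mean(axis=1, keepdims=True)
        # exact up to the per-position partition-function shift
        centered = rate * small_matrix.epsilon
        centered = centered - centered.mean(axis=1, keepdims=True)
        got = eps_hat - eps_hat.mean(axis=1, keepdims=True)
        assert np.abs(got - centered).max() < 1e-9

    def test_zero_frequency_needs_pseudocount(self):
        mono = np.full(4, 0.25)
        obs = np.array([[0.5, 0.5, 0.0, 0.0]])
        with pytest.raises(ValueError):
            log_odds_matrix(obs, mono, beta_lo=1.0)
        out = log_odds_matrix(obs, mono, beta_lo=1.0, pseudocount=1e-6)
        assert np.isfinite(out).all()
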