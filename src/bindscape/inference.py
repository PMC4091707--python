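"""Fitness-landscape inference from observed binding-site energies.

Under mutation-selection-drift balance in the monomorphic limit, the
steady-state distribution of site sequences is P(sigma) ~ pi0(sigma)
F(sigma)^nu; projected into energy space, P(E) ~ Q0(E) F(E)^nu.  Given a
neutral spectrum Q0 and a collection of observed site energies this module
computes the likelihood of parametric landscapes, maximizes it over an
explicit parameter mesh (the likelihood surface has extended degenerate
ridges, so gradient methods are avoided), selects among models with the
finite-sample Akaike criterion, and nonparametrically inverts the landscape
as ln F = (1/nu) [ln P_obs - ln Q0] up to an affine transform.

Three models are fitted:

UFD   unconstrained Fermi-Dirac, parameters (f0, beta, mu, nu), k = 4
CFD   "non-lethal" Fermi-Dirac with f0 fixed at 0.99, k = 3
EXP   exponential, F^nu = exp(-rate * E), single parameter, k = 1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .background import EnergySpectrum
from .fitness import ExponentialParams, FermiDiracParams, classify_regime, log_fd_fitness

F0_CAP = 0.99

#: Tolerance (kcal/mol) for site energies just beyond the quantized
#: spectrum support; covers per-position rounding drift for L up to ~25.
SUPPORT_SLACK = 0.25


def _log_grid(lo_exp: float, hi_exp: float, step: float) -> np.ndarray:
    n = int(round((hi_exp - lo_exp) / step)) + 1
    return 10.0 ** (lo_exp + step * np.arange(n))


@dataclass
class GridSpec:
    """Parameter mesh for the grid-search MLE.

    Defaults: beta on a 0.1-dex log grid over [0.1, 10]; nu on a 0.1-dex
    grid over [1, 1e6]; f0 = exp(-x) for x = 0.01 .. 10 in steps of 0.2,
    capped at 0.99 (so boundary values of f0 signal degeneracy rather than
    a genuine estimate); mu from (support min - 5) to (support max + 5)
    kcal/mol in steps of 0.1; the exponential rate on a 0.05-dex grid over
    [1e-2, 1e3].
    """

    beta: np.ndarray = field(default_factory=lambda: _log_grid(-1.0, 1.0, 0.1))
    nu: np.ndarray = field(default_factory=lambda: _log_grid(0.0, 6.0, 0.1))
    f0: np.ndarray = field(
        default_factory=lambda: np.minimum(
            np.exp(-np.arange(0.01, 10.0 + 1e-9, 0.2)), F0_CAP
        )
    )
    mu: np.ndarray | None = None
    rate: np.ndarray = field(default_factory=lambda: _log_grid(-2.0, 3.0, 0.05))
    mu_step: float = 0.1
    mu_pad: float = 5.0

    def mu_grid(self, spectrum: EnergySpectrum) -> np.ndarray:
        if self.mu is not None:
            return np.asarray(self.mu, dtype=float)
        centers = spectrum.centers[spectrum.probs > 0]
        lo, hi = centers.min() - self.mu_pad, centers.max() + self.mu_pad
        return np.arange(lo, hi + self.mu_step / 2, self.mu_step)

    def coarsen(self, factor: int = 2) -> "GridSpec":
        """Every ``factor``-th point on each axis (used for subsample refits)."""
        return GridSpec(
            beta=self.beta[::factor],
            nu=self.nu[::factor],
            f0=self.f0[::factor],
            mu=None if self.mu is None else self.mu[::factor],
            rate=self.rate[::factor],
            mu_step=self.mu_step * factor,
            mu_pad=self.mu_pad,
        )


@dataclass
class FitResult:
    """Maximum-likelihood fit of one landscape model."""

    model: str
    params: FermiDiracParams | ExponentialParams
    log_likelihood: float
    k: int
    n: int
    regime: str | None = None
    flags: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)


def steady_state_density(
    spectrum: EnergySpectrum, log_fitness_fn, nu: float
) -> np.ndarray:
    """P(E) ~ Q0(E) F(E)^nu on the spectrum's bins, normalized.

    ``log_fitness_fn`` maps energies to ln F.  nu = 0 returns Q0.  The
    density is invariant under F -> c F.  All arithmetic is in log space.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    with np.errstate(divide="ignore"):
        lw = np.where(
            spectrum.probs > 0, np.log(np.maximum(spectrum.probs, 1e-300)), -np.inf
        )
    if nu > 0:
        lw = lw + nu * np.asarray(log_fitness_fn(spectrum.centers), dtype=float)
    norm = logsumexp(lw)
    if not np.isfinite(norm):
        raise ValueError("steady-state density has zero total mass")
    return np.exp(lw - norm)


def log_likelihood(
    site_energies, spectrum: EnergySpectrum, log_fitness_fn, nu: float
) -> float:
    """ln L = nu * Sum_i ln F(E_i) - n ln Z with Z from the binned spectrum.

    The per-site neutral terms ln pi0(sigma_i) are constant across
    landscape models and are dropped; they cancel in any model comparison.
    Raises if a site energy falls outside the spectrum support.
    """
    E = np.asarray(site_energies, dtype=float)
    if E.size == 0:
        raise ValueError("need at least one site")
    support = spectrum.centers[spectrum.probs > 0]
    if E.min() < support.min() - SUPPORT_SLACK or E.max() > support.max() + SUPPORT_SLACK:
        raise ValueError("site energy outside the neutral spectrum support")
    with np.errstate(divide="ignore"):
        lq = np.where(
            spectrum.probs > 0, np.log(np.maximum(spectrum.probs, 1e-300)), -np.inf
        )
    lnF_bins = np.asarray(log_fitness_fn(spectrum.centers), dtype=float)
    lnZ = logsumexp(lq + nu * lnF_bins)
    return float(nu * np.sum(log_fitness_fn(E)) - E.size * lnZ)


def fd_log_likelihood(
    site_energies, spectrum: EnergySpectrum, params: FermiDiracParams
) -> float:
    """Continuous-parameter Fermi-Dirac log-likelihood (used off-mesh)."""
    fn = lambda E: log_fd_fitness(E, params.f0, params.beta, params.mu)
    return log_likelihood(site_energies, spectrum, fn, params.nu)


def aicc(lnL: float, k: int, n: int) -> float:
    """AICc = 2k - 2 lnL + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """w_i = exp(-Delta_i / 2) / Sum_j exp(-Delta_j / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two models to weight")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _fd_scan(uniq_E, counts, lq, centers, grid, spectrum, consume):
    """Evaluate the FD log-likelihood over the mesh.

    For each (f0, beta) pair, builds the (n_nu, n_mu) log-likelihood block
    and hands it to ``consume(f0_idx, beta_idx, block, mus)``.  Vectorized
    over mu, bins and nu; chunked over mu to bound memory; the inner
    logsumexp is hand-rolled (single max-shift pass) because it dominates
    the runtime.
    """
    mus = grid.mu_grid(spectrum)
    nus = np.asarray(grid.nu, dtype=float)
    n = counts.sum()
    max_cells = 4_000_000
    chunk = max(1, int(max_cells / (nus.size * centers.size)))
    buf = np.empty((nus.size, chunk, centers.size))
    for fi, f0 in enumerate(grid.f0):
        lf0 = np.log(f0) if f0 > 0 else -np.inf
        l1mf0 = np.log1p(-f0) if f0 < 1 else -np.inf
        for bi, beta in enumerate(grid.beta):
            lnF_sites = _lnF_block(uniq_E, mus, beta, lf0, l1mf0)
            S = lnF_sites @ counts  # (n_mu,)
            lnF_bins = _lnF_block(centers, mus, beta, lf0, l1mf0)
            block = np.empty((nus.size, mus.size))
            for s in range(0, mus.size, chunk):
                sl = slice(s, min(s + chunk, mus.size))
                w = sl.stop - sl.start
                A = buf[:, :w, :]
                np.multiply(nus[:, None, None], lnF_bins[None, sl, :], out=A)
                A += lq[None, None, :]
                M = A.max(axis=2)
                A -= M[:, :, None]
                np.exp(A, out=A)
                block[:, sl] = np.log(A.sum(axis=2)) + M
            block = nus[:, None] * S[None, :] - n * block
            consume(fi, bi, block, mus, nus)
    return mus, nus


def _lnF_block(E, mus, beta, lf0, l1mf0):
    x = beta * (E[None, :] - mus[:, None])
    lnp = -np.logaddexp(0.0, x)
    if lf0 == -np.inf:
        return lnp
    return np.logaddexp(lf0, l1mf0 + lnp)


# Effective spectrum resolution used in fits (kcal/mol).  Kept well below
# the occupancy-step width so the within-bin variation of the selection
# weight F^nu stays small where the data constrain the fit.
FIT_TARGET_BIN_WIDTH = 0.04


def _prepare(site_energies, spectrum, coarsen: int | str = "auto"):
    """Site-energy counts and (optionally coarsened) spectrum support.

    Fitting does not need the spectrum's full resolution: adjacent bins are
    merged (log-mass summed, centers mass-averaged) until the effective
    width is ~0.1 kcal/mol, matching the mu mesh step.  Pass ``coarsen=1``
    to disable.

    Site energies are snapped to the same bin centers used for the
    partition function, so the scanned objective is the exact multinomial
    log-likelihood of the binned model P(bin) = Q0 F^nu / Z.  Evaluating
    sites off-grid while normalizing on the grid would let very steep
    landscapes (large nu * beta) exploit the discretization error and run
    away along the degenerate ridge.
    """
    E = np.asarray(site_energies, dtype=float)
    mask = spectrum.probs > 0
    centers = spectrum.centers[mask]
    probs = spectrum.probs[mask]
    # energies of real sequences can exceed the quantized support by up to
    # L * bin_width / 2 (per-position rounding); allow that much slack and
    # snap such sites to the boundary bin
    slack = SUPPORT_SLACK
    if E.min() < centers.min() - slack or E.max() > centers.max() + slack:
        raise ValueError("site energy outside the neutral spectrum support")
    if coarsen == "auto":
        coarsen = max(1, int(round(FIT_TARGET_BIN_WIDTH / spectrum.bin_width)))
    if coarsen > 1:
        group = np.floor(spectrum.centers[mask] / (spectrum.bin_width * coarsen))
        group -= group.min()
        group = group.astype(int)
        mass = np.bincount(group, weights=probs)
        cw = np.bincount(group, weights=probs * centers)
        keep = mass > 0
        probs = mass[keep]
        centers = cw[keep] / probs
    # snap each site to the nearest center with neutral mass
    mids = 0.5 * (centers[1:] + centers[:-1])
    site_bin = np.searchsorted(mids, E)
    counts = np.bincount(site_bin, minlength=centers.size).astype(float)
    lq = np.log(probs)
    return centers, counts, lq, centers


def fit_gridsearch(
    site_energies,
    spectrum: EnergySpectrum,
    model: str = "UFD",
    grid: GridSpec | None = None,
) -> FitResult:
    """Exhaustive maximum-likelihood search over the parameter mesh.

    For best results score the sites on the spectrum's quantized grid
    (:func:`bindscape.background.quantized_site_energies`); binning exact
    energies leaves a ~1-bin mis-registration that biases the fit.

    Ties are broken deterministically toward smaller nu, then smaller beta,
    then larger mu, then smaller f0.  Degeneracy flags record whether the
    optimum sits in a known flat direction: f0 at its cap (only
    gamma = nu (1 - f0) is identifiable), or mu outside the span of the
    data (tail / plateau mu-degeneracies).
    """
    grid = grid or GridSpec()
    E = np.asarray(site_energies, dtype=float)
    n = E.size
    if n < 30:
        warnings.warn(f"only {n} sites; fits may be poorly constrained", stacklevel=2)
    uniq_E, counts, lq, centers = _prepare(E, spectrum)

    if model == "EXP":
        rates = np.asarray(grid.rate, dtype=float)
        sumE = E.sum()
        lnZ = logsumexp(lq[None, :] - rates[:, None] * centers[None, :], axis=1)
        lnL = -rates * sumE - n * lnZ
        i = int(np.argmax(lnL))
        params = ExponentialParams(rate=float(rates[i]))
        return FitResult("EXP", params, float(lnL[i]), 1, n)

    if model == "CFD":
        work = GridSpec(
            beta=grid.beta, nu=grid.nu, f0=np.array([F0_CAP]), mu=grid.mu,
            rate=grid.rate, mu_step=grid.mu_step, mu_pad=grid.mu_pad,
        )
        k = 3
    elif model == "UFD":
        work = grid
        k = 4
    else:
        raise ValueError(f"unknown model {model!r}")
    if work.f0.size == 0 or work.beta.size == 0 or work.nu.size == 0:
        raise ValueError("empty parameter mesh")

    best = {"lnL": -np.inf, "key": None, "params": None}

    def consume(fi, bi, block, mus, nus):
        m = block.max()
        if m < best["lnL"]:
            return
        cand_idx = np.argwhere(block == m)
        # prefer smallest nu, then largest mu
        order = np.lexsort((-cand_idx[:, 1], cand_idx[:, 0]))
        ni, mi = cand_idx[order[0]]
        key = (float(nus[ni]), float(work.beta[bi]), -float(mus[mi]), float(work.f0[fi]))
        if m > best["lnL"] or (m == best["lnL"] and key < best["key"]):
            best["lnL"] = float(m)
            best["key"] = key
            best["params"] = FermiDiracParams(
                f0=float(work.f0[fi]), beta=float(work.beta[bi]),
                mu=float(mus[mi]), nu=float(nus[ni]),
            )

    _fd_scan(uniq_E, counts, lq, centers, work, spectrum, consume)
    params = best["params"]
    x = params.beta * (E - params.mu)
    flags = {
        "gamma_degenerate": params.f0 >= F0_CAP - 1e-12,
        "mu_below_data": bool(x.min() > 2.0),
        "mu_above_data": bool(x.max() < -2.0),
    }
    regime = classify_regime(params, E)
    return FitResult(model, params, best["lnL"], k, n, regime=regime, flags=flags)


def fit_all_models(site_energies, spectrum, grid: GridSpec | None = None):
    """Fit UFD, CFD and EXP; returns (dict of FitResult, Akaike weights)."""
    fits = {
        m: fit_gridsearch(site_energies, spectrum, model=m, grid=grid)
        for m in ("UFD", "CFD", "EXP")
    }
    weights = akaike_weights([fits[m].aicc for m in ("UFD", "CFD", "EXP")])
    return fits, dict(zip(("UFD", "CFD", "EXP"), weights))


@dataclass
class BinnedLandscape:
    """Nonparametric ln-fitness estimate on equal-width energy bins."""

    bin_edges: np.ndarray
    log_fitness: np.ndarray  # up to an additive constant; NaN where undefined
    se: np.ndarray
    counts: np.ndarray
    neutral_mass: np.ndarray
    defined: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def invert_landscape(
    site_energies,
    spectrum: EnergySpectrum,
    nu: float,
    n_bins: int = 15,
    e_range: tuple | None = None,
) -> BinnedLandscape:
    """ln F(E) = (1/nu) [ln P_obs(E) - ln Q0(E)] on equal-width bins.

    ``e_range`` defaults to the spectrum support (for a quantized spectrum,
    the matrix's allowed energy range).  Bins with zero observed or zero
    neutral mass are flagged undefined, not interpolated.  The standard
    error on ln f_obs is the binomial delta-method value
    sqrt((1 - f) / (f N)), scaled by 1/nu.
    """
    if nu <= 0:
        raise ValueError("nu must be > 0")
    E = np.asarray(site_energies, dtype=float)
    if e_range is None:
        support = spectrum.centers[spectrum.probs > 0]
        e_range = (support.min(), support.max())
    edges = np.linspace(e_range[0], e_range[1], n_bins + 1)
    counts, _ = np.histogram(E, bins=edges)
    # neutral mass per bin from the fine spectrum
    which = np.clip(np.digitize(spectrum.centers, edges) - 1, 0, n_bins - 1)
    inside = (spectrum.centers >= edges[0]) & (spectrum.centers <= edges[-1])
    q = np.bincount(which[inside], weights=spectrum.probs[inside], minlength=n_bins)
    f_obs = counts / max(E.size, 1)
    defined = (counts > 0) & (q > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnF = np.where(defined, (np.log(f_obs) - np.log(q)) / nu, np.nan)
        se = np.where(defined, np.sqrt((1 - f_obs) / (f_obs * E.size)) / nu, np.nan)
    return BinnedLandscape(edges, lnF, se, counts, q, defined)


def profile_likelihood(
    site_energies,
    spectrum: EnergySpectrum,
    model: str,
    param_name: str,
    values,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Log-likelihood profile: re-optimize all other parameters per value."""
    grid = grid or GridSpec()
    out = np.empty(len(values))
    for i, v in enumerate(values):
        axes = {
            "beta": grid.beta, "nu": grid.nu, "f0": grid.f0,
            "mu": grid.mu if grid.mu is not None else grid.mu_grid(spectrum),
            "rate": grid.rate,
        }
        if param_name not in axes:
            raise ValueError(f"unknown parameter {param_name!r}")
        axes[param_name] = np.array([float(v)])
        sub = GridSpec(
            beta=axes["beta"], nu=axes["nu"], f0=axes["f0"], mu=axes["mu"],
            rate=axes["rate"], mu_step=grid.mu_step, mu_pad=grid.mu_pad,
        )
        out[i] = fit_gridsearch(site_energies, spectrum, model=model, grid=sub).log_likelihood
    return out


def likelihood_heatmap(
    site_energies,
    spectrum: EnergySpectrum,
    grid: GridSpec | None = None,
):
    """ln L over (nu, f0) with (beta, mu) re-optimized at each cell.

    Returned as (nu_grid, f0_grid, lnL matrix); on log-log axes of nu and
    1 - f0, lines of constant gamma = nu (1 - f0) are straight with slope 1,
    which makes the gamma degeneracy visible as a flat ridge.
    """
    grid = grid or GridSpec()
    uniq_E, counts, lq, centers = _prepare(site_energies, spectrum)
    heat = np.full((grid.nu.size, grid.f0.size), -np.inf)

    def consume(fi, bi, block, mus, nus):
        np.maximum(heat[:, fi], block.max(axis=1), out=heat[:, fi])

    _fd_scan(uniq_E, counts, lq, centers, grid, spectrum, consume)
    return grid.nu, grid.f0, heat


@dataclass
class FitDiagnostics:
    hessian: np.ndarray | None
    eigenvalues: np.ndarray | None
    eigenvectors: np.ndarray | None
    coord_names: tuple
    subsample_fits: list
    warning: str | None = None


def fit_diagnostics(
    site_energies,
    spectrum: EnergySpectrum,
    fit: FitResult,
    n_subsamples: int = 64,
    seed: int = 0,
    grid: GridSpec | None = None,
) -> FitDiagnostics:
    """Hessian eigensystem and half-subsample refits around a UFD optimum.

    The Hessian of ln L is taken by central finite differences in the
    transformed coordinates (ln nu, ln beta, ln(1 - f0), mu), where the
    gamma degeneracy appears as a near-zero eigenvalue along the direction
    (1, 0, 1, 0)/sqrt(2).  If the optimum sits on the mesh boundary the
    Hessian is skipped with a warning.  Subsample refits draw
    ``n_subsamples`` random halves of the data and refit on a mesh with
    doubled grid spacing.
    """
    if fit.model != "UFD":
        raise ValueError("diagnostics are defined for UFD fits")
    grid = grid or GridSpec()
    E = np.asarray(site_energies, dtype=float)
    p = fit.params
    warning = None
    hess = eigvals = eigvecs = None
    names = ("ln_nu", "ln_beta", "ln_1mf0", "mu")

    mus = grid.mu_grid(spectrum)
    on_boundary = (
        np.isclose(p.beta, grid.beta[0]) or np.isclose(p.beta, grid.beta[-1])
        or np.isclose(p.nu, grid.nu[0]) or np.isclose(p.nu, grid.nu[-1])
        or np.isclose(p.mu, mus[0]) or np.isclose(p.mu, mus[-1])
        or np.isclose(p.f0, grid.f0.min()) or p.f0 >= F0_CAP - 1e-12
    )
    if on_boundary:
        warning = "optimum on mesh boundary; Hessian skipped"
    else:
        z0 = np.array([np.log(p.nu), np.log(p.beta), np.log(1.0 - p.f0), p.mu])
        h = np.array([0.05, 0.05, 0.05, 0.05])

        def f(z):
            # clip f0 into [0, cap]: near f0 ~ 0 the ln(1-f0) coordinate is
            # almost flat and finite steps can overshoot the domain
            params = FermiDiracParams(
                f0=float(np.clip(1.0 - np.exp(z[2]), 0.0, F0_CAP)),
                beta=np.exp(z[1]), mu=z[3], nu=np.exp(z[0]),
            )
            return fd_log_likelihood(E, spectrum, params)

        hess = np.empty((4, 4))
        f0v = f(z0)
        for i in range(4):
            ei = np.zeros(4); ei[i] = h[i]
            hess[i, i] = (f(z0 + ei) - 2 * f0v + f(z0 - ei)) / h[i] ** 2
            for j in range(i + 1, 4):
                ej = np.zeros(4); ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    f(z0 + ei + ej) - f(z0 + ei - ej) - f(z0 - ei + ej) + f(z0 - ei - ej)
                ) / (4 * h[i] * h[j])
        eigvals, eigvecs = np.linalg.eigh(hess)

    rng = np.random.default_rng(seed)
    coarse = grid.coarsen(2)
    half = E.size // 2
    subs = []
    for _ in range(n_subsamples):
        sub = rng.choice(E, size=half, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subs.append(fit_gridsearch(sub, spectrum, model="UFD", grid=coarse).params)
    return FitDiagnostics(hess, eigvals, eigvecs, names, subs, warning)


def exp_factorized_steady_state(
    mono: np.ndarray, matrix, rate: float
) -> np.ndarray:
    """Per-position base probabilities of the factorized exponential steady
    state: p_i(a) ~ b(a) exp(-rate * eps[i, a]) with per-position partition
    functions.  Valid for a mononucleotide (factorized) background only.
    """
    b = np.asarray(mono, dtype=float)
    w = b[None, :] * np.exp(-rate * matrix.epsilon)
    return w / w.sum(axis=1, keepdims=True)


def log_odds_matrix(
    obs_freqs: np.ndarray,
    mono: np.ndarray,
    beta_lo: float,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Energy-matrix estimate from observed per-position base frequencies.

    eps_hat[i, a] = -(1/beta_lo) ln(p_i(a) / b(a)), the log-odds score;
    inverts :func:`exp_factorized_steady_state` up to a per-position
    additive shift.  Zero observed frequencies require a pseudocount.
    """
    p = np.asarray(obs_freqs, dtype=float)
    if pseudocount > 0:
        p = p + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
    if (p <= 0).any():
        raise ValueError("zero observed frequency; set a pseudocount")
    b = np.asarray(mono, dtype=float)
    return -np.log(p / b[None, :]) / beta_lo
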