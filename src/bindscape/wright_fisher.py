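"""Forward Wright-Fisher simulation of binding-site evolution.

Used to validate the monomorphic steady-state theory: a haploid asexual
population of N sequences evolves by fitness-weighted multinomial
resampling (selection) followed by per-base mutation with equal rates
between all nucleotide pairs.  Each replicate starts from a monomorphic
population with a random background-drawn sequence; one randomly chosen
sequence per replicate per checkpoint builds the observed distribution
P_obs, which is compared against the monomorphic prediction
P ~ Q0 F^nu (nu = 2N - 2 for Wright-Fisher) via the total variation
distance on 100 equal energy bins spanning the matrix's allowed range.

The population is stored as genotype -> count, which makes the
near-monomorphic regime cheap: most generations carry a single genotype
and zero mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import MarkovBackground, neutral_energy_spectrum
from .energy import EnergyMatrix
from .fitness import FermiDiracParams, fd_fitness, log_fd_fitness
from .inference import steady_state_density

N_TVD_BINS = 100


def wf_exponent(N: int) -> float:
    """Scaling effective population size nu for the Wright-Fisher model."""
    return 2.0 * N - 2.0


@dataclass
class WFConfig:
    N: int
    matrix: EnergyMatrix
    fitness: FermiDiracParams
    mu_rate: float
    generations: int
    n_replicates: int = 1
    seed: int = 0
    background: MarkovBackground | None = None
    checkpoints: tuple = ()  # extra generations at which to sample
    #: 'background' starts each replicate from a random background-drawn
    #: sequence (the default); 'steady_state' starts from an exact draw of
    #: the monomorphic steady state, which makes stationarity checks and
    #: steady-state sampling affordable at low mutation rates (the
    #: relaxation from a random start takes many substitution times)
    start: str = "background"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 <= self.mu_rate <= 1.0:
            raise ValueError("mu_rate must be in [0, 1]")
        if self.background is None:
            self.background = MarkovBackground.uniform()


@dataclass
class SimResult:
    checkpoint_generations: np.ndarray
    sampled_sequences: list  # [checkpoint][replicate] encoded genotype tuples
    sampled_energies: np.ndarray  # (n_checkpoints, n_replicates)
    unique_counts: np.ndarray  # (n_replicates,) at final generation
    bin_edges: np.ndarray
    final_distribution: np.ndarray
    predicted_distribution: np.ndarray
    tvd_trace: np.ndarray  # TVD(P_obs, prediction) per checkpoint

    @property
    def tvd_final(self) -> float:
        return float(self.tvd_trace[-1])

    @property
    def mean_unique(self) -> float:
        return float(self.unique_counts.mean())


def tvd(p, q) -> float:
    """Total variation distance (1/2) Sum |p_i - q_i| on shared bins."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share the same bins")
    return 0.5 * float(np.abs(p - q).sum())


def energy_bin_edges(matrix: EnergyMatrix, n_bins: int = N_TVD_BINS) -> np.ndarray:
    """Equal bins over the matrix's allowed energy range."""
    return np.linspace(matrix.min_energy, matrix.max_energy, n_bins + 1)


def binned_energy_distribution(energies, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(np.asarray(energies, dtype=float), bins=edges)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def predicted_energy_distribution(
    matrix: EnergyMatrix,
    background: MarkovBackground,
    fitness: FermiDiracParams,
    nu: float,
    edges: np.ndarray,
    bin_width: float = 0.02,
) -> np.ndarray:
    """Monomorphic steady-state P(E) ~ Q0 F^nu, rebinned onto ``edges``."""
    spectrum = neutral_energy_spectrum(background, matrix, bin_width)
    fn = lambda E: log_fd_fitness(E, fitness.f0, fitness.beta, fitness.mu)
    dens = steady_state_density(spectrum, fn, nu)
    which = np.clip(np.digitize(spectrum.centers, edges) - 1, 0, edges.size - 2)
    out = np.bincount(which, weights=dens, minlength=edges.size - 1)
    return out / out.sum()


def _sample_background_genotype(bg: MarkovBackground, L: int, rng) -> tuple:
    t = bg.transition()
    seq = [rng.choice(4, p=bg.mono)]
    for _ in range(L - 1):
        row = t[seq[-1]]
        row = row / row.sum() if row.sum() > 0 else np.full(4, 0.25)
        seq.append(rng.choice(4, p=row))
    return tuple(int(x) for x in seq)


def _run_replicate(config: WFConfig, rng, checkpoints, start_genotype=None):
    """One replicate; returns (samples at checkpoints, final unique count)."""
    L = config.matrix.length
    N = config.N
    eps = config.matrix.epsilon
    fit_p = config.fitness
    energy_cache: dict = {}
    fitness_cache: dict = {}

    def fitness_of(g):
        f = fitness_cache.get(g)
        if f is None:
            e = energy_cache.get(g)
            if e is None:
                e = float(eps[np.arange(L), list(g)].sum())
                energy_cache[g] = e
            f = float(fd_fitness(e, fit_p))
            fitness_cache[g] = f
        return f

    if start_genotype is not None:
        pop = {tuple(int(x) for x in start_genotype): N}
    else:
        pop = {_sample_background_genotype(config.background, L, rng): N}
    samples = []
    ck = set(int(c) for c in checkpoints)
    nl = N * L
    # P(any mutation in the population in one generation); while the
    # population is monomorphic nothing changes between mutation events,
    # so those generations are skipped with a geometric jump
    p_any = -np.expm1(nl * np.log1p(-config.mu_rate)) if config.mu_rate > 0 else 0.0
    gen = 0
    sorted_ck = sorted(ck)
    while gen < config.generations:
        forced_mutation = False
        if len(pop) == 1 and config.mu_rate > 0:
            # next generation carrying at least one mutation event
            jump = int(rng.geometric(p_any))
            landing = gen + jump
            g = next(iter(pop))
            for c in sorted_ck:
                if gen < c < min(landing, config.generations + 1):
                    samples.append(g)
            if landing > config.generations:
                gen = config.generations
                break
            gen = landing
            forced_mutation = True
        else:
            gen += 1
        # selection: fitness-weighted multinomial resampling to size N
        if len(pop) > 1:
            genotypes = list(pop.keys())
            w = np.array([pop[g] * fitness_of(g) for g in genotypes])
            counts = rng.multinomial(N, w / w.sum())
            pop = {g: int(c) for g, c in zip(genotypes, counts) if c}
        # mutation: each base mutates with prob mu_rate, to one of 3 others
        n_mut = rng.binomial(nl, config.mu_rate) if config.mu_rate > 0 else 0
        if forced_mutation:
            n_mut = max(1, n_mut)  # conditioned on >= 1 event at landing
        if n_mut:
            genotypes = list(pop.keys())
            counts = np.fromiter((pop[g] for g in genotypes), dtype=float)
            per_genotype = rng.multinomial(n_mut, counts / counts.sum())
            positions = rng.integers(0, L, size=n_mut)
            steps = rng.integers(1, 4, size=n_mut)
            e = 0
            for g, m in zip(genotypes, per_genotype):
                # each event hits a distinct carrier of the original genotype
                for _ in range(min(int(m), pop.get(g, 0))):
                    pos = int(positions[e])
                    g_new = g[:pos] + ((g[pos] + int(steps[e])) % 4,) + g[pos + 1 :]
                    e += 1
                    pop[g] -= 1
                    if pop[g] == 0:
                        del pop[g]
                    pop[g_new] = pop.get(g_new, 0) + 1
        if gen in ck:
            genotypes = list(pop.keys())
            counts = np.fromiter((pop[g] for g in genotypes), dtype=float)
            g = genotypes[rng.choice(len(genotypes), p=counts / counts.sum())]
            samples.append(g)
    for g in pop:
        fitness_of(g)  # populate energy cache for sampled genotypes
    return samples, len(pop), energy_cache


def simulate(config: WFConfig) -> SimResult:
    """Run the replicate ensemble; deterministic under ``config.seed``."""
    checkpoints = sorted(set(list(config.checkpoints) + [config.generations]))
    rng = np.random.default_rng(config.seed)
    L = config.matrix.length
    eps = config.matrix.epsilon
    all_samples = [[] for _ in checkpoints]
    uniques = np.empty(config.n_replicates, dtype=int)
    starts = [None] * config.n_replicates
    if config.start == "steady_state":
        from .energy import BASE_INDEX
        from .synthetic import sample_steady_state_sites

        seqs = sample_steady_state_sites(
            config.matrix, config.background, config.fitness, wf_exponent(config.N),
            config.n_replicates, int(rng.integers(2**31 - 1)),
        )
        starts = [tuple(BASE_INDEX[b] for b in s) for s in seqs]
    for r in range(config.n_replicates):
        samples, n_unique, _ = _run_replicate(config, rng, checkpoints, starts[r])
        uniques[r] = n_unique
        for c, g in enumerate(samples):
            all_samples[c].append(g)

    def energies_of(genotypes):
        if not genotypes:
            return np.empty(0)
        arr = np.array(genotypes)
        return eps[np.arange(L), arr].sum(axis=1)

    edges = energy_bin_edges(config.matrix)
    nu = wf_exponent(config.N)
    predicted = predicted_energy_distribution(
        config.matrix, config.background, config.fitness, nu, edges
    )
    sampled_energies = np.stack([energies_of(s) for s in all_samples])
    trace = np.array(
        [tvd(binned_energy_distribution(e, edges), predicted) for e in sampled_energies]
    )
    return SimResult(
        checkpoint_generations=np.array(checkpoints),
        sampled_sequences=all_samples,
        sampled_energies=sampled_energies,
        unique_counts=uniques,
        bin_edges=edges,
        final_distribution=binned_energy_distribution(sampled_energies[-1], edges),
        predicted_distribution=predicted,
        tvd_trace=trace,
    )


def polymorphism_stats(unique_counts) -> float:
    """Mean number of unique sequences per population at the final
    generation; 1.0 for fully monomorphic replicates."""
    u = np.asarray(unique_counts, dtype=float)
    if u.size == 0:
        raise ValueError("no snapshots")
    return float(u.mean())


def expected_polymorphism(per_site_rate: float, L: int) -> float:
    """Expected unique-sequence count if each base is independently
    polymorphic (two alleles) with the given per-site proportion:
    1 + (1 - (1 - rate)^L)."""
    return 1.0 + (1.0 - (1.0 - per_site_rate) ** L)


def monomorphism_bound(N: int, L: int, form: str = "log_corrected") -> float:
    """Mutation-rate threshold below which populations stay monomorphic.

    'basic' gives 1/(N L); 'log_corrected' (default) includes the neutral
    fixation-time factor, 1/(N L ln N).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if form == "basic":
        return 1.0 / (N * L)
    if form == "log_corrected":
        return 1.0 / (N * L * np.log(N))
    raise ValueError(f"unknown form {form!r}")


@dataclass
class RecoveryPoint:
    sweep_value: float
    fitted: list  # FermiDiracParams per sample
    mean_gamma: float
    sd_gamma: float
    mean_beta: float
    sd_beta: float
    mean_mu: float
    sd_mu: float
    mean_nu: float
    sd_nu: float
    tvd: float = np.nan  # TVD(P_obs, monomorphic prediction) for the pool
    mean_unique: float = np.nan


def recovery_experiment(
    matrix: EnergyMatrix,
    fitness: FermiDiracParams,
    background: MarkovBackground,
    N: int,
    sweep: dict,
    n_pool: int,
    sample_size: int,
    n_samples: int,
    grid,
    seed: int = 0,
    spectrum_bin_width: float = 0.05,
    model: str = "CFD",
):
    """Sweep mutation rate or run length; fit each resampled pool.

    The default fits the constrained three-parameter model (f0 fixed;
    ``model='CFD'``): validation ensembles use a non-lethal landscape
    whose f0 is known, and freeing it lets the four-parameter fit wander
    the degeneracy ridge at these sample sizes.

    ``sweep`` is {'mu_rate': [...]} (steady-state runs sized from the
    relaxation time 1/(L mu)) or {'generations': [...], 'mu_rate': r}
    (fixed rate, varying run length).  For each sweep point, ``n_pool``
    replicates contribute one final sequence each; ``n_samples`` bootstrap
    samples of ``sample_size`` energies are fitted by grid search, and the
    mean and SD of the fitted parameters are reported against the truth.
    """
    import warnings as _w

    from .inference import fit_gridsearch

    spectrum = neutral_energy_spectrum(background, matrix, spectrum_bin_width)
    rng = np.random.default_rng(seed)
    results = []
    if "generations" in sweep and isinstance(sweep.get("generations"), (list, tuple, np.ndarray)):
        points = [("generations", g, sweep["mu_rate"]) for g in sweep["generations"]]
    else:
        points = [("mu_rate", m, None) for m in sweep["mu_rate"]]
    for kind, value, fixed_rate in points:
        if kind == "mu_rate":
            # steady-state sweep points start from exact steady-state draws
            # (relaxation from a random start takes many substitution times
            # at low mutation rates); run length covers ~2 substitution
            # times, capped to keep the ensemble affordable
            mu_rate = float(value)
            generations = int(
                np.clip(2.0 / (matrix.length * mu_rate), 1000, 8000)
            )
            start = "steady_state"
        else:
            mu_rate = float(fixed_rate)
            generations = int(value)
            start = "background"
        config = WFConfig(
            N=N, matrix=matrix, fitness=fitness, mu_rate=mu_rate,
            generations=generations, n_replicates=n_pool,
            seed=int(rng.integers(2**31 - 1)), background=background,
            start=start,
        )
        sim = simulate(config)
        # score the pooled sequences on the spectrum's quantized grid so
        # they register exactly with the fitted bins
        from .background import quantized_site_energies

        genotypes = np.array(sim.sampled_sequences[-1])
        pool = quantized_site_energies(matrix, spectrum, genotypes)
        support = spectrum.centers[spectrum.probs > 0]
        pool = np.clip(pool, support.min(), support.max())
        fitted = []
        for _ in range(n_samples):
            # draw distinct pool members when possible: bootstrap duplicates
            # shrink the effective sample and degrade the fits
            replace = pool.size < sample_size
            sample = rng.choice(pool, size=sample_size, replace=replace)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fitted.append(fit_gridsearch(sample, spectrum, model, grid=grid).params)
        g = np.array([p.gamma for p in fitted])
        b = np.array([p.beta for p in fitted])
        m = np.array([p.mu for p in fitted])
        n_ = np.array([p.nu for p in fitted])
        results.append(
            RecoveryPoint(
                float(value), fitted,
                g.mean(), g.std(), b.mean(), b.std(),
                m.mean(), m.std(), n_.mean(), n_.std(),
                tvd=sim.tvd_final, mean_unique=float(sim.unique_counts.mean()),
            )
        )
    return results
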