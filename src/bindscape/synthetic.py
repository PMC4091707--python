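"""Seeded synthetic fixtures for the whole pipeline.

Real inputs to this analysis are an energy matrix per TF, genomic site
collections, intergenic background sequence, gene attribute tables and
ortholog site pairs.  This module generates statistically matched stand-ins
for all of them: random unit-SD energy matrices, first-order-Markov
background sequence with yeast-like composition (AT-rich, mild dinucleotide
persistence; illustrative, not estimated from data), binding sites sampled
from the exact mutation-selection-drift steady state P ~ pi0 F^nu in a
chosen landscape regime, gene tables with null or planted site-specific
effects, and ortholog pairs at a set divergence.  Every fixture is fully
described by its truth record and reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import (
    MarkovBackground,
    enumerate_sequence_space,
    neutral_log_probs_encoded,
)
from .energy import AlignedSiteSet, EnergyMatrix, decode_sequence, random_energy_matrix
from .fitness import FermiDiracParams, classify_regime, log_fd_fitness

EXACT_SAMPLING_MAX_L = 10


def yeast_like_background(persistence: float = 0.2) -> MarkovBackground:
    """AT-rich background (A = T = 0.31, C = G = 0.19) with mild
    same-base dinucleotide persistence; the Markov chain's stationary
    distribution equals the mononucleotide frequencies."""
    mono = np.array([0.31, 0.19, 0.19, 0.31])
    transition = (1 - persistence) * np.tile(mono, (4, 1)) + persistence * np.eye(4)
    di = mono[:, None] * transition
    return MarkovBackground(mono, di)


def sample_background_sequences(
    bg: MarkovBackground, n_records: int, record_length: int, seed
) -> list[str]:
    """Draw sequences from the first-order Markov background chain."""
    rng = np.random.default_rng(seed)
    t = bg.transition()
    t = t / t.sum(axis=1, keepdims=True)
    records = []
    for _ in range(n_records):
        idx = np.empty(record_length, dtype=np.int8)
        idx[0] = rng.choice(4, p=bg.mono)
        for i in range(1, record_length):
            idx[i] = rng.choice(4, p=t[idx[i - 1]])
        records.append(decode_sequence(idx))
    return records


def sample_steady_state_sites(
    matrix: EnergyMatrix,
    background: MarkovBackground,
    params: FermiDiracParams,
    nu: float,
    n: int,
    seed,
    method: str = "auto",
    burn_in_factor: int = 200,
    thin_factor: int = 10,
) -> list[str]:
    """Sample site sequences from P(sigma) ~ pi0(sigma) F(sigma)^nu.

    For L <= 10 (``method='auto'`` or ``'exact'``) the 4^L sequence space
    is enumerated and sampled exactly.  For longer sites a single-site
    Metropolis chain over sequence space is used, with burn-in
    ``burn_in_factor * L`` sweeps and thinning ``thin_factor * L`` accepted
    proposals between samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = matrix.length
    lnF = lambda E: log_fd_fitness(E, params.f0, params.beta, params.mu)
    if method == "exact" or (method == "auto" and L <= EXACT_SAMPLING_MAX_L):
        idx = enumerate_sequence_space(L)
        energies = matrix.energies_encoded(idx)
        lw = neutral_log_probs_encoded(background, idx) + nu * lnF(energies)
        lw -= lw.max()
        w = np.exp(lw)
        p = w / w.sum()
        choice = rng.choice(idx.shape[0], size=n, p=p)
        return [decode_sequence(idx[c]) for c in choice]

    # Metropolis over sequence space: single-base proposals
    t = background.transition()
    with np.errstate(divide="ignore"):
        log_mono = np.log(background.mono)
        log_t = np.log(np.where(t > 0, t, 1e-300))

    def log_target(idx):
        lp = log_mono[idx[0]] + log_t[idx[:-1], idx[1:]].sum()
        return lp + nu * float(lnF(matrix.energies_encoded(idx)))

    state = np.array(
        [rng.choice(4, p=background.mono)]
        + [rng.choice(4, p=t[0] / t[0].sum()) for _ in range(L - 1)],
        dtype=np.int64,
    )
    current = log_target(state)
    samples = []
    steps_burn = burn_in_factor * L
    steps_thin = thin_factor * L
    step = 0
    while len(samples) < n:
        pos = int(rng.integers(L))
        new_base = (state[pos] + 1 + int(rng.integers(3))) % 4
        proposal = state.copy()
        proposal[pos] = new_base
        cand = log_target(proposal)
        if np.log(rng.random()) < cand - current:
            state, current = proposal, cand
        step += 1
        if step >= steps_burn and (step - steps_burn) % steps_thin == 0:
            samples.append(decode_sequence(state))
    return samples


def default_regime_params(
    matrix: EnergyMatrix, background: MarkovBackground, regime: str
) -> FermiDiracParams:
    """Landscape parameters that place the steady state in a target regime.

    Positions are chosen relative to the neutral energy distribution
    (mean m, SD s ~ 1 for unit-SD matrices): tail puts mu below the matrix
    minimum with a large gamma; threshold puts mu two SD below the neutral
    mean with order-one nu and near-lethal f0; plateau puts mu one SD above
    the mean with strong but non-lethal selection.
    """
    from .energy import background_energy_moments

    m, var = background_energy_moments(matrix, background.mono)
    s = float(np.sqrt(var))
    if regime in ("tail", "exponential_tail"):
        return FermiDiracParams(f0=0.99, beta=1.0, mu=matrix.min_energy - 3.0 * s, nu=20000.0)
    if regime == "threshold":
        return FermiDiracParams(f0=np.exp(-10.0), beta=2.512, mu=m - 1.0 * s, nu=6.0)
    if regime == "plateau":
        return FermiDiracParams(f0=0.4, beta=1.686, mu=m + 1.0 * s, nu=400.0)
    raise ValueError(f"unknown regime {regime!r}")


def synth_gene_annotations(
    site_seqs: list,
    energies: np.ndarray,
    effect: dict | None,
    seed,
    tf_name: str = "TF1",
    p_essential: float = 0.3,
    window: int = 700,
    gene_spacing: int = 2000,
) -> dict:
    """Build synthetic gene table, site coordinates, and annotated sites.

    One gene per site, laid out along a synthetic chromosome; each site is
    placed inside the ``window``-bp upstream region of its gene so the
    assignment rule applies.  Attribute columns are drawn independently of
    the energies (null) unless ``effect`` plants one; a planted
    ``{'essential_shift': delta}`` lowers the recorded energies of sites
    regulating essential genes by delta (kcal/mol) after sampling.
    """
    rng = np.random.default_rng(seed)
    n = len(site_seqs)
    L = len(site_seqs[0])
    energies = np.asarray(energies, dtype=float).copy()
    essential = np.where(rng.random(n) < p_essential, "essential", "nonessential")
    if effect and effect.get("essential_shift"):
        energies[essential == "essential"] -= float(effect["essential_shift"])

    genes, site_rows, annotated_rows = [], [], []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = (i + 1) * gene_spacing
        upstream = int(rng.integers(1, window - L))
        if strand == "+":
            start = tss - upstream - L
        else:
            start = tss + upstream
        end = start + L
        growth = {
            f"growth_{c}": float(np.clip(rng.normal(0.95, 0.05), 0, 1.2))
            for c in ("ypd", "ypdge", "ypg", "ype", "ypl")
        }
        if essential[i] == "essential":
            growth = {k: np.nan for k in growth}
        genes.append(
            {"gene_id": f"G{i:04d}", "chrom": "chrS", "tss": tss, "strand": strand,
             "essential": essential[i], **growth,
             "expression": float(rng.lognormal(2.0, 1.0)),
             "dnds": float(rng.lognormal(np.log(0.1), 0.5))}
        )
        site_rows.append(
            {"chrom": "chrS", "start": start, "end": end, "strand": strand,
             "seq": site_seqs[i], "posterior": 1.0, "tf": tf_name}
        )
        g = genes[-1]
        growth_vals = [v for k, v in g.items() if k.startswith("growth_")]
        annotated_rows.append(
            {"tf": tf_name, "site_index": i, "gene_id": g["gene_id"],
             "energy": energies[i], "essential": essential[i],
             "growth_rate": float(np.nanmin(growth_vals)) if essential[i] == "nonessential" else np.nan,
             "expression": g["expression"], "dnds": g["dnds"],
             "tss_distance": upstream}
        )
    return {
        "gene_table": pd.DataFrame(genes),
        "sites": pd.DataFrame(site_rows),
        "annotated": pd.DataFrame(annotated_rows),
        "energies": energies,
    }


def synth_ortholog_pairs(site_seqs: list, divergence: float, seed) -> pd.DataFrame:
    """Diverged partner for each site: every base substituted with
    probability ``divergence``, uniformly among the 3 alternatives."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    pairs = []
    for s in site_seqs:
        out = []
        for ch in s:
            if rng.random() < divergence:
                alts = [b for b in bases if b != ch]
                out.append(alts[int(rng.integers(3))])
            else:
                out.append(ch)
        pairs.append({"seq_a": s, "seq_b": "".join(out)})
    return pd.DataFrame(pairs)


@dataclass
class FixtureConfig:
    L: int = 8
    regime: str = "threshold"
    params: FermiDiracParams | None = None  # derived from regime if None
    n_sites: int = 500
    background: MarkovBackground | str = "yeast"
    genome_records: int = 10
    genome_record_length: int = 5000
    effect: dict | None = None  # e.g. {"essential_shift": 1.0}
    divergence: float = 0.05
    p_essential: float = 0.3
    seed: int = 0


@dataclass
class Fixture:
    config: FixtureConfig
    matrix: EnergyMatrix
    background: MarkovBackground
    background_records: list
    site_set: AlignedSiteSet
    sites: pd.DataFrame
    gene_table: pd.DataFrame
    annotated: pd.DataFrame
    ortholog_pairs: pd.DataFrame
    truth: dict = field(default_factory=dict)


def make_fixture(config: FixtureConfig) -> Fixture:
    """Generate a complete seeded fixture; raises if the requested regime
    is infeasible for the generated matrix and parameters."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31 - 1, size=5)
    bg = (
        yeast_like_background()
        if isinstance(config.background, str)
        else config.background
    )
    matrix = random_energy_matrix(config.L, int(seeds[0]), bg.mono, tf_name="TF1")
    params = config.params or default_regime_params(matrix, bg, config.regime)
    site_seqs = sample_steady_state_sites(
        matrix, bg, params, params.nu, config.n_sites, int(seeds[1])
    )
    energies = matrix.energies(site_seqs)
    observed = classify_regime(params, energies)
    want = "exponential_tail" if config.regime == "tail" else config.regime
    if observed != want:
        raise ValueError(
            f"regime {config.regime!r} infeasible for this matrix/parameters: "
            f"sampled sites classify as {observed!r}; adjust mu, beta or the "
            f"matrix energy range"
        )
    records = sample_background_sequences(
        bg, config.genome_records, config.genome_record_length, int(seeds[2])
    )
    ann = synth_gene_annotations(
        site_seqs, energies, config.effect, int(seeds[3]),
        p_essential=config.p_essential,
    )
    annotated = ann["annotated"]
    pairs = synth_ortholog_pairs(site_seqs, config.divergence, int(seeds[4]))
    pairs["essential"] = annotated["essential"].values
    site_set = AlignedSiteSet("TF1", site_seqs, energies)
    truth = {
        "seed": config.seed, "L": config.L, "regime": config.regime,
        "f0": params.f0, "beta": params.beta, "mu": params.mu, "nu": params.nu,
        "gamma": params.gamma, "n_sites": config.n_sites,
        "effect": config.effect, "divergence": config.divergence,
        "p_essential": config.p_essential,
    }
    return Fixture(
        config=config, matrix=matrix, background=bg, background_records=records,
        site_set=site_set, sites=ann["sites"], gene_table=ann["gene_table"],
        annotated=annotated, ortholog_pairs=pairs, truth=truth,
    )
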