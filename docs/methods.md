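# Methods

## The model

A transcription factor (TF) binds an L-bp site with probability given by
the Fermi-Dirac function of the binding free energy,

    p(E) = 1 / (1 + exp(beta (E - mu))),

where `beta` is an inverse temperature ((kcal/mol)^-1; 1.686 at 298 K) and
`mu` a chemical potential set by TF concentration.  Site energies are
additive over positions (energy-matrix model): `E(sigma) = sum_i
eps[i, sigma_i]`.  Fitness is assumed to depend on the sequence only
through occupancy, interpolating between 1 (always bound) and `f0` (never
bound):

    F(E) = f0 + (1 - f0) p(E),

with `beta`, `mu`, `f0` treated as *effective* parameters that a fit may
place far from their physical values.  For a haploid population in the
monomorphic (sequential-substitution) limit the stationary distribution of
the site sequence is

    P(sigma) ∝ pi0(sigma) F(sigma)^nu,

where `pi0` is the neutral (mutation-only) sequence distribution and `nu`
is the scaling effective population size (2N-2 for Wright-Fisher, used
throughout the validation code).  Projected into energy space this is
`P(E) ∝ Q0(E) F(E)^nu`, and inverted it gives the nonparametric estimator
`ln F = (1/nu)[ln P_obs - ln Q0]` up to an affine transform.

Two landscape families are fitted: the four-parameter Fermi-Dirac above
(UFD; a constrained variant, CFD, fixes `f0 = 0.99`), and a one-parameter
exponential with `F^nu = exp(-rate * E)`, for which only the product
`rate = nu * beta_s` is identifiable.  Model choice uses AICc,
`2k - 2 lnL + 2k(k+1)/(n-k-1)`, and Akaike weights.

### Parameter degeneracies

The likelihood surface has flat ridges that any fitting procedure must
respect rather than hide:

- **gamma degeneracy.**  When `f0 -> 1` (or uniformly small selection
  coefficients), the steady state depends on `(f0, nu)` only through
  `gamma = nu (1 - f0)`.
- **mu degeneracies.**  If all site energies sit far above `mu`
  (exponential tail) or far below it (occupancy plateau), `mu` can be
  shifted along the ridge with a compensating change of `gamma` without
  changing the steady state.

Fits are therefore reported with degeneracy flags (`f0` at its cap; `mu`
below/above all data) and a regime label — `exponential_tail`,
`threshold`, or `plateau` — assigned from the central 80% of
`beta (E - mu)` against a +-2 cutoff (a reporting convention, exposed in
configuration, not a fitted quantity).

### Selection strength and its beta-sensitivity

The per-unit-energy selection coefficient is `|s*| = |d ln F / dE| =
beta (1-f0) p (1-p) / F`.  Its derivative with respect to `beta` at fixed
`(E - mu, f0)` changes sign along curves `beta (E - mu) = x*`, where `x*`
solves a stationarity condition that depends on `x` alone; for `f0 = 0`
the single root is `x* = -(1 + W(1/e)) ≈ -1.2785` (Lambert W), recovered
here by bracketed root-finding rather than assumed.

## Numerical choices

- **Energy spectrum.**  `Q0(E)` is computed by a transfer-matrix dynamic
  program over (last base, discretized energy) states.  Matrix entries are
  rounded to the bin grid (default 0.02 kcal/mol), which makes the DP
  *exact* under that quantization (verified against 4^L enumeration);
  the worst-case energy shift is `L * bin_width / 2`.
- **Likelihood and Z.**  The likelihood drops the constant per-site
  `ln pi0` terms (they cancel in model comparison) and computes the
  normalization on the binned spectrum.  Inside the grid search the site
  energies are snapped to the same bins as the partition function, making
  the scanned objective an exact multinomial likelihood of the binned
  model; evaluating sites off-grid while normalizing on-grid lets very
  steep landscapes (large `nu * beta`) exploit the discretization error
  and run away along the degenerate ridge.  Fits use an effective bin
  width of 0.04 kcal/mol, kept below the occupancy-step width.
- **Site registration.**  Sites fitted against a quantized spectrum must
  be scored with the same quantized matrix
  (`background.quantized_site_energies`): binning *exact* energies leaves
  a ~1-bin mis-registration (SD `bin_width * sqrt(L/12)`) that does not
  average out with sample size and measurably biases the fitted
  parameters along the ridge.  All internal fitting paths do this.
- **Mesh.**  Exhaustive evaluation over a fixed mesh (gradient methods
  are avoided because of the ridges): `beta` in 10^[-1, 1] (0.1 dex),
  `nu` in 10^[0, 6] (0.1 dex), `f0 = exp(-x)` for `x = 0.01..10` step 0.2
  capped at 0.99, `mu` over the spectrum support +-5 kcal/mol step 0.1,
  exponential rate in 10^[-2, 3] (0.05 dex).  `f0` is capped/floored so
  that boundary values signal degeneracy rather than an estimate.  Ties
  break deterministically toward smaller `nu`, then smaller `beta`, then
  larger `mu`.
- **Diagnostics.**  The Hessian of `lnL` is taken by central differences
  in `(ln nu, ln beta, ln(1 - f0), mu)` (step 0.05); near `f0 ~ 0` the
  third coordinate is almost flat and steps are clipped into the domain.
  The gamma degeneracy appears as a near-zero eigenvalue along
  `(1, 0, -1, 0)/sqrt(2)`.  Half-subsample refits (default 64) rerun the
  search on a mesh with doubled spacing.
- **Landscape inversion.**  15 equal-width bins spanning the spectrum
  support; bins with zero observed or neutral mass are flagged, never
  interpolated.  The error bar on the per-bin ln-fitness is the binomial
  delta-method standard error `sqrt((1 - f)/(f N)) / nu` — a documented
  substitute for an unstated published formula.

## Wright-Fisher validation

The simulator is a haploid asexual Wright-Fisher process: fitness-weighted
multinomial resampling to size N, then per-base mutation with probability
`mu` per generation, uniform among the three alternatives.  The population
is stored as genotype -> count; while it is monomorphic, generations
without mutation events are skipped by a geometric jump (the dynamics are
unchanged; the event-free generations carry no randomness that matters).
The observed distribution `P_obs` collects one randomly chosen sequence
per replicate per checkpoint and is compared with the monomorphic
prediction by total variation distance on 100 equal energy bins spanning
the matrix range.  The monomorphism bound is `mu < 1/(N L ln N)`
(log-corrected form; the simpler `1/(N L)` is also available).

Relaxation to steady state from a random sequence takes many substitution
times (`1/(L mu)` each), which is unaffordable at mutation rates well
below the bound.  Steady-state sweep points in the recovery experiment
therefore start each replicate from an exact draw of the monomorphic
steady state and run for ~2 substitution times (2000–8000 generations):
below the bound this verifies that the predicted distribution is
*preserved* by the dynamics; above the bound the ensemble relaxes quickly
to its true polymorphic state, reproducing the downward bias of fitted
`nu` and `beta`.  Pre-steady-state runs (for the upward bias of fitted
`mu`) start from random monomorphic populations as in the original
design.  Recovery fits use the constrained three-parameter model (f0
fixed): the validation landscape's f0 is known by construction, and at
500-site samples the free-f0 fit wanders the gamma degeneracy ridge,
which would measure the ridge rather than the mutation-rate effects
under study.  Validation ensembles default to N = 1000, L = 10 with pools of
several hundred replicates and ~15 fitted samples of 500 sequences per
sweep point, drawn without replacement where the pool allows (bootstrap
duplicates shrink the effective sample and degrade the fits); these sizes
keep the full validation in minutes while leaving sampling error below
the effects being measured.

## Synthetic data

The generator emulates every real input: random unit-SD energy matrices
(uniform entries rescaled so a background-drawn sequence has unit energy
SD — verified analytically, not by sampling); an AT-rich first-order
Markov background (A = T = 0.31, C = G = 0.19, 20% same-base dinucleotide
persistence; illustrative of yeast intergenic composition, not estimated
from data); binding sites drawn from the exact steady state (4^L
enumeration for L <= 10, seeded single-site Metropolis beyond, burn-in
200L sweeps, thinning 10L); synthetic gene tables with essentiality
labels, five-condition knockout growth rates, expression and dN/dS
columns drawn independently of energy (null) or with planted effects;
and ortholog pairs diverged by independent per-base substitution.

The default threshold-regime landscape is `f0 = e^-10`, `beta = 2.512
(kcal/mol)^-1`, `mu` one neutral SD below the neutral mean energy,
`nu = 6`.  This placement was chosen (once, by a pre-registered
identifiability analysis on seeds disjoint from the test seeds) so that
the sampled sites populate both the flat high-occupancy side and the
exponential tail of the step: with `mu` deep in the neutral tail or weak
selection, `(gamma, mu)` ride the degeneracy ridges and no estimator can
recover them from 500 sites.  Tail and plateau fixtures use
`(f0 = 0.99, beta = 1, mu = E_min - 3, nu = 2e4)` and `(f0 = 0.4,
beta = 1.686, mu = mean + 1 SD, nu = 400)` respectively.

What passing tests on these fixtures show: the estimator chain
(spectrum -> likelihood -> mesh search -> model choice -> inversion) is
self-consistent, calibrated, and recovers generating parameters where
they are identifiable.  What they do not show: that real genomes satisfy
monomorphism, steady state, a single universal landscape per TF, or an
additive energy model — those are scientific assumptions the real-data
analysis must argue for separately.

## Known limitations

- Additive energies only; no dinucleotide or higher-order terms.
- One TF at a time; no promoter-level (multi-site) fitness.
- The exponential-family fit stores only the identifiable product
  `nu * beta_s`.
- Grid-search estimates inherit the mesh quantization (0.1 dex in `nu`
  and `beta`); quantities derived from ratios of mesh points can be off
  by ~12% even with perfect data.
- At realistic sample sizes the unconstrained Fermi-Dirac fit can land on
  a degenerate ridge far from the generating parameters even when the
  predicted energy distribution is essentially correct; parameter values
  should always be read together with the degeneracy flags.
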