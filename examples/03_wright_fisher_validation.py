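"""Validating the monomorphic steady-state theory by forward simulation.

Runs a haploid Wright-Fisher ensemble at mutation rates below and above
the monomorphism bound 1/(N L ln N) and compares the sampled energy
distribution with the analytic prediction P ~ Q0 F^(2N-2).
"""

import numpy as np

from bindscape import (
    FermiDiracParams,
    monomorphism_bound,
    random_energy_matrix,
    simulate,
    yeast_like_background,
)
from bindscape.energy import background_energy_moments
from bindscape.wright_fisher import WFConfig, polymorphism_stats

N, L = 300, 8
bg = yeast_like_background()
matrix = random_energy_matrix(L, seed=11, background=bg.mono)
mean, var = background_energy_moments(matrix, bg.mono)
fitness = FermiDiracParams(f0=0.99, beta=1.686, mu=mean - np.sqrt(var), nu=0.0)

bound = monomorphism_bound(N, L)
print(f"monomorphism bound for N={N}, L={L}: mu < {bound:.2e}")

# both ensembles start from exact steady-state draws: below the bound the
# dynamics should preserve the monomorphic prediction (stationarity);
# above it the population departs toward a polymorphic, more neutral state
for mu_rate in (bound / 10, bound * 20):
    generations = int(min(2 / (L * mu_rate), 4000))
    sim = simulate(WFConfig(
        N=N, matrix=matrix, fitness=fitness, mu_rate=mu_rate,
        generations=generations, n_replicates=500, seed=5, background=bg,
        start="steady_state",
    ))
    tag = "below" if mu_rate < bound else "above"
    print(f"mu={mu_rate:.1e} ({tag} bound), {generations} generations: "
          f"TVD(P_obs, prediction) = {sim.tvd_final:.3f}, "
          f"mean unique sequences = {polymorphism_stats(sim.unique_counts):.2f}")
print("Below the bound the monomorphic steady state is preserved by the "
      "dynamics (TVD at the sampling-noise floor); above it polymorphism "
      "grows and the observed distribution departs from the prediction.")
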