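"""Energy matrices and the neutral energy spectrum.

Builds a random unit-SD energy matrix, scores sequences against it, and
projects a yeast-like Markov background through the matrix to obtain the
neutral distribution of binding energies Q0(E).
"""

import numpy as np

from bindscape import (
    boltzmann_logo,
    neutral_energy_spectrum,
    random_energy_matrix,
    yeast_like_background,
)

bg = yeast_like_background()
matrix = random_energy_matrix(L=8, seed=42, background=bg.mono, tf_name="DEMO")

print(f"matrix length        : {matrix.length} bp")
print(f"consensus sequence   : {matrix.consensus}")
print(f"energy range         : [{matrix.min_energy:.2f}, {matrix.max_energy:.2f}] kcal/mol")
print(f"consensus energy     : {matrix.site_energy(matrix.consensus):.2f} kcal/mol")

# occupancy-weighted base frequencies at room temperature
logo = boltzmann_logo(matrix)
print(f"logo col 1 (A C G T) : {np.round(logo[0], 3)}")

spectrum = neutral_energy_spectrum(bg, matrix, bin_width=0.02)
centers = spectrum.centers
mean = float((centers * spectrum.probs).sum())
sd = float(np.sqrt(((centers - mean) ** 2 * spectrum.probs).sum()))
print(f"neutral spectrum     : mean {mean:.2f}, SD {sd:.3f} kcal/mol "
      f"({spectrum.probs.size} bins)")
print("The SD is ~1 because random matrices are rescaled so that a "
      "background-drawn sequence has unit energy SD.")
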