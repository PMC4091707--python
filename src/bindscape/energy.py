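"""Additive TF-DNA binding energy models.

A transcription factor's sequence preference is represented by an energy
matrix: a 4 x L table of additive contributions (kcal/mol) such that the
binding energy of an L-bp site is the sum of the entries selected by its
bases.  Lower energy means tighter binding; the consensus sequence is the
per-position minimum.  The module also converts position-specific affinity
matrices (PSAMs, multiplicative weights) to energy units, rescales matrices
so that the background-sequence energy distribution has unit standard
deviation, and aligns collections of genomic sites to a matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: Inverse temperature at room temperature (298 K), in (kcal/mol)^-1.
#: kB * 298 K = 0.593 kcal/mol, so beta = 1/0.593 = 1.686.
BETA_ROOM = 1.686


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to an int8 array of base indices.

    Ambiguity codes are rejected: curation of N-containing sequences is
    upstream of this package.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode_sequence(indices: np.ndarray) -> str:
    return "".join(BASES[i] for i in indices)


@dataclass
class EnergyMatrix:
    """Additive binding-energy model for one TF.

    Parameters
    ----------
    tf_name : str
        Label for the factor.
    epsilon : ndarray, shape (L, 4)
        Energy contribution (kcal/mol) of base A, C, G, T at each position.
    """

    tf_name: str
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.ndim != 2 or self.epsilon.shape[1] != 4:
            raise ValueError("epsilon must have shape (L, 4)")
        if not np.isfinite(self.epsilon).all():
            raise ValueError("energy matrix entries must be finite")

    @property
    def length(self) -> int:
        return self.epsilon.shape[0]

    @property
    def min_energy(self) -> float:
        """Energy of the consensus (best-binding) sequence."""
        return float(self.epsilon.min(axis=1).sum())

    @property
    def max_energy(self) -> float:
        return float(self.epsilon.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return decode_sequence(self.epsilon.argmin(axis=1))

    def site_energy(self, seq: str) -> float:
        """Binding energy of a single site, Sum_i eps[i, seq[i]]."""
        idx = encode_sequence(seq)
        if idx.size != self.length:
            raise ValueError(
                f"sequence length {idx.size} != matrix length {self.length}"
            )
        return float(self.epsilon[np.arange(self.length), idx].sum())

    def energies(self, seqs) -> np.ndarray:
        """Vectorized site energies for equal-length sequences."""
        return np.array([self.site_energy(s) for s in seqs])

    def energies_encoded(self, idx: np.ndarray) -> np.ndarray:
        """Energies for an (n, L) array of base indices."""
        idx = np.asarray(idx)
        return self.epsilon[np.arange(self.length), idx].sum(axis=-1)

    def reverse_complement(self) -> "EnergyMatrix":
        eps_rc = self.epsilon[::-1][:, COMPLEMENT_INDEX]
        return EnergyMatrix(self.tf_name, eps_rc)


@dataclass
class AlignedSiteSet:
    """Fixed-length binding sites aligned to one energy matrix."""

    tf_name: str
    sites: list
    energies: np.ndarray
    offset: int = 0
    strand: str = "+"
    per_site_provenance: list | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        lengths = {len(s) for s in self.sites}
        if len(lengths) > 1:
            raise ValueError("aligned sites must share one length")

    def __len__(self) -> int:
        return len(self.sites)


def site_energy(matrix: EnergyMatrix, seq: str) -> float:
    return matrix.site_energy(seq)


def psam_to_energy_matrix(
    psam: np.ndarray, beta_room: float = BETA_ROOM, tf_name: str = ""
) -> EnergyMatrix:
    """Convert multiplicative affinity weights w to energies.

    eps[i, a] = -(1/beta_room) * ln w[i, a]; a weight of 1 maps to 0 energy
    and larger weight (higher affinity) maps to lower energy.
    """
    psam = np.asarray(psam, dtype=float)
    if (psam <= 0).any():
        raise ValueError("PSAM weights must be strictly positive")
    return EnergyMatrix(tf_name, -np.log(psam) / beta_room)


def energy_matrix_to_psam(
    matrix: EnergyMatrix, beta_room: float = BETA_ROOM
) -> np.ndarray:
    """Inverse of :func:`psam_to_energy_matrix`."""
    return np.exp(-beta_room * matrix.epsilon)


def background_energy_moments(
    matrix: EnergyMatrix, background: np.ndarray
) -> tuple[float, float]:
    """Mean and variance of the site energy of a background-drawn sequence.

    Positions are independent under a mononucleotide background b(a), so the
    variance is the sum of per-position variances.
    """
    b = np.asarray(background, dtype=float)
    mean_i = matrix.epsilon @ b
    var_i = ((matrix.epsilon - mean_i[:, None]) ** 2) @ b
    return float(mean_i.sum()), float(var_i.sum())


def rescale_to_unit_sd(
    matrix: EnergyMatrix, background: np.ndarray | None = None
) -> tuple[EnergyMatrix, float]:
    """Divide the matrix by lambda so background energies have SD 1.

    lambda = sqrt(Sum_i Sum_a b(a) (eps[i,a] - mean_i)^2) with
    mean_i = Sum_a b(a) eps[i,a].  Returns the rescaled matrix and lambda.
    """
    if background is None:
        background = np.full(4, 0.25)
    _, var = background_energy_moments(matrix, background)
    lam = float(np.sqrt(var))
    if lam == 0.0:
        raise ValueError("degenerate matrix: background energy SD is zero")
    return EnergyMatrix(matrix.tf_name, matrix.epsilon / lam), lam


def random_energy_matrix(
    L: int,
    seed: int | np.random.Generator,
    background: np.ndarray | None = None,
    tf_name: str = "random",
) -> EnergyMatrix:
    """Uniform(0,1) entries rescaled to unit background-energy SD.

    Deterministic given the seed.  The energy of a background-drawn sequence
    is approximately Gaussian with SD 1 (sum of L independent per-position
    contributions).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    raw = EnergyMatrix(tf_name, rng.uniform(0.0, 1.0, size=(L, 4)))
    rescaled, _ = rescale_to_unit_sd(raw, background)
    return rescaled


def _window_energies(matrix: EnergyMatrix, idx: np.ndarray, offset: int) -> np.ndarray:
    L = matrix.length
    window = idx[:, offset : offset + L]
    return matrix.epsilon[np.arange(L), window].sum(axis=1)


def align_sites_to_matrix(
    matrix: EnergyMatrix,
    raw_sites,
    per_site: bool = False,
    tf_name: str | None = None,
) -> AlignedSiteSet:
    """Choose the (offset, strand) minimizing mean binding energy.

    One offset and one strand are chosen for the whole collection (the
    default); ties go to the smallest offset, forward strand first.  With
    ``per_site=True`` each site is aligned independently instead.
    """
    L = matrix.length
    encoded = [encode_sequence(s) for s in raw_sites]
    if not encoded:
        raise ValueError("empty site collection")
    min_len = min(e.size for e in encoded)
    if min_len < L:
        raise ValueError(f"site shorter than matrix length {L}")
    n_offsets = min_len - L + 1
    fwd = np.stack([e[:min_len] for e in encoded])
    rev = np.stack([COMPLEMENT_INDEX[e[::-1]][:min_len] for e in encoded])

    if per_site:
        sites, energies, prov = [], [], []
        for i in range(len(encoded)):
            best = None
            for strand, arr in (("+", fwd[i : i + 1]), ("-", rev[i : i + 1])):
                for off in range(n_offsets):
                    e = float(_window_energies(matrix, arr, off)[0])
                    key = (e, 0 if strand == "+" else 1, off)
                    if best is None or key < best[0]:
                        best = (key, strand, off, arr[0, off : off + L])
            _, strand, off, window = best
            sites.append(decode_sequence(window))
            energies.append(matrix.energies_encoded(window))
            prov.append((off, strand))
        return AlignedSiteSet(
            tf_name or matrix.tf_name, sites, np.array(energies),
            offset=-1, strand="*", per_site_provenance=prov,
        )

    best = None
    for strand, arr in (("+", fwd), ("-", rev)):
        for off in range(n_offsets):
            mean_e = float(_window_energies(matrix, arr, off).mean())
            key = (mean_e, 0 if strand == "+" else 1, off)
            if best is None or key < best[0]:
                best = (key, strand, off, arr)
    _, strand, off, arr = best
    windows = arr[:, off : off + L]
    sites = [decode_sequence(w) for w in windows]
    energies = matrix.energies_encoded(windows)
    return AlignedSiteSet(
        tf_name or matrix.tf_name, sites, energies, offset=off, strand=strand
    )


def boltzmann_logo(matrix: EnergyMatrix, beta: float = BETA_ROOM) -> np.ndarray:
    """Per-position base frequencies p_i(a) ~ exp(-beta * eps[i, a]).

    The softmax of the negated, beta-scaled matrix columns; beta = 0 gives
    uniform frequencies (infinite temperature).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = -beta * matrix.epsilon
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)
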