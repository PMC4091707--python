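"""Neutral (mutation-only) sequence model and its energy spectrum.

Background sequence statistics are summarized by mono- and dinucleotide
frequencies.  The neutral probability of a site sequence is a first-order
Markov chain,

    pi0(sigma) = b(sigma_1) * prod_{i>=2} b2(sigma_{i-1}, sigma_i) / b(sigma_{i-1}),

and its projection through an energy matrix gives Q0(E), the neutral
distribution of binding energies.  Q0 is computed by a transfer-matrix
dynamic program over (last base, discretized energy) states: matrix entries
are rounded to an energy grid so every sequence's discretized energy lies
exactly on a bin center, which makes the DP exact under that quantization
(worst-case energy shift L * bin_width / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import BASES, COMPLEMENT_INDEX, EnergyMatrix, encode_sequence


@dataclass
class MarkovBackground:
    """Mono- and dinucleotide background frequencies.

    ``mono`` is b(a) over A,C,G,T; ``di`` is the joint dinucleotide
    distribution b2(a, a') (rows: first base).
    """

    mono: np.ndarray
    di: np.ndarray

    def __post_init__(self) -> None:
        self.mono = np.asarray(self.mono, dtype=float)
        self.di = np.asarray(self.di, dtype=float)
        if self.mono.shape != (4,) or self.di.shape != (4, 4):
            raise ValueError("mono must be (4,), di must be (4, 4)")
        if not np.isclose(self.mono.sum(), 1.0):
            raise ValueError("mono frequencies must sum to 1")
        if not np.isclose(self.di.sum(), 1.0):
            raise ValueError("dinucleotide frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls(np.full(4, 0.25), np.full((4, 4), 1 / 16))

    @classmethod
    def from_mono(cls, mono) -> "MarkovBackground":
        """Factorized background: b2 = b (x) b (no dinucleotide structure)."""
        mono = np.asarray(mono, dtype=float)
        return cls(mono, np.outer(mono, mono))

    def transition(self) -> np.ndarray:
        """Conditional next-base probabilities b2(a, a') / b(a)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(self.mono[:, None] > 0, self.di / self.mono[:, None], 0.0)
        return t


def fit_background(sequences, pseudocount: float = 0.0) -> MarkovBackground:
    """Estimate mono/dinucleotide frequencies from sequences.

    Dinucleotides are counted overlapping within each record; counts do not
    wrap across records.  Non-ACGT characters are rejected.
    """
    seqs = [s if isinstance(s, str) else str(s) for s in sequences]
    if not seqs or sum(len(s) for s in seqs) < 2:
        raise ValueError("need at least 2 background bases")
    mono_counts = np.full(4, pseudocount, dtype=float)
    di_counts = np.full((4, 4), pseudocount, dtype=float)
    for s in seqs:
        idx = encode_sequence(s)
        mono_counts += np.bincount(idx, minlength=4)
        if idx.size >= 2:
            pair = idx[:-1] * 4 + idx[1:]
            di_counts += np.bincount(pair, minlength=16).reshape(4, 4)
    if di_counts.sum() == 0:
        raise ValueError("no dinucleotides in input")
    return MarkovBackground(mono_counts / mono_counts.sum(), di_counts / di_counts.sum())


def neutral_seq_prob(bg: MarkovBackground, seq: str) -> float:
    """First-order Markov probability pi0(sigma); 0 on missing transitions."""
    idx = encode_sequence(seq)
    if idx.size < 1:
        raise ValueError("empty sequence")
    p = bg.mono[idx[0]]
    t = bg.transition()
    for a, b in zip(idx[:-1], idx[1:]):
        p *= t[a, b]
        if p == 0.0:
            return 0.0
    return float(p)


@dataclass
class EnergySpectrum:
    """Discretized distribution over binding energies.

    Bin centers are ``(offset + k) * bin_width`` for k = 0..n-1; ``probs``
    holds the probability mass per bin.
    """

    bin_width: float
    offset: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return (self.offset + np.arange(self.probs.size)) * self.bin_width

    @property
    def edges(self) -> np.ndarray:
        return (self.offset + np.arange(self.probs.size + 1) - 0.5) * self.bin_width

    def bin_index(self, energies) -> np.ndarray:
        """Nearest-center bin index for each energy; may fall outside range."""
        return np.rint(np.asarray(energies, dtype=float) / self.bin_width).astype(
            int
        ) - self.offset

    def rebin(self, factor: int) -> "EnergySpectrum":
        """Merge ``factor`` adjacent bins (pads the tail with zero mass)."""
        if factor <= 1:
            return self
        n = self.probs.size
        pad = (-n) % factor
        probs = np.concatenate([self.probs, np.zeros(pad)]).reshape(-1, factor)
        # new centers approximate the mass-weighted position of merged bins
        centers = np.concatenate([self.centers, np.zeros(pad)]).reshape(-1, factor)
        with np.errstate(invalid="ignore"):
            new_centers = np.where(
                probs.sum(axis=1) > 0,
                (probs * centers).sum(axis=1) / np.maximum(probs.sum(axis=1), 1e-300),
                centers.mean(axis=1),
            )
        return _IrregularSpectrum(self.bin_width * factor, new_centers, probs.sum(axis=1))


@dataclass
class _IrregularSpectrum:
    """Spectrum with explicit (possibly mass-weighted) bin centers."""

    bin_width: float
    _centers: np.ndarray
    probs: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return self._centers

    def bin_index(self, energies) -> np.ndarray:
        edges_lo = self._centers[0] - 0.5 * self.bin_width
        return np.floor(
            (np.asarray(energies, dtype=float) - edges_lo) / self.bin_width
        ).astype(int)


def quantized_matrix(matrix: EnergyMatrix, bin_width: float) -> np.ndarray:
    """Integer energy-matrix entries on the bin grid (units of bin_width)."""
    return np.rint(matrix.epsilon / bin_width).astype(np.int64)


def quantized_site_energies(
    matrix: EnergyMatrix, spectrum: "EnergySpectrum", sites
) -> np.ndarray:
    """Site energies on the spectrum's quantized grid.

    Computes each site's energy with the same per-position rounding used
    to build the spectrum, so sites register exactly with the spectrum's
    bins.  Binning *exact* energies instead leaves a ~1-bin mis-registration
    (SD ~ bin_width * sqrt(L/12)) that does not average out and biases
    likelihood fits; always score sites with this helper when fitting
    against a quantized spectrum.  ``sites`` is a list of sequences or an
    (n, L) index array.
    """
    k = quantized_matrix(matrix, spectrum.bin_width)
    if not isinstance(sites, np.ndarray):
        sites = np.stack([encode_sequence(s) for s in sites])
    L = matrix.length
    return k[np.arange(L), sites].sum(axis=1) * spectrum.bin_width


def neutral_energy_spectrum(
    bg: MarkovBackground, matrix: EnergyMatrix, bin_width: float = 0.02
) -> EnergySpectrum:
    """Project the Markov background through the matrix to get Q0(E).

    Exact (to the quantization) transfer-matrix DP; mass is conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    k = quantized_matrix(matrix, bin_width)  # (L, 4) integer increments
    lo = int(k.min(axis=1).cumsum()[-1])
    hi = int(k.max(axis=1).cumsum()[-1])
    n_bins = hi - lo + 1
    t = bg.transition()

    # state[a, j]: prob of (last base a, energy index lo+j) after i positions
    lo_i = 0
    state = np.zeros((4, 1))
    width_i = 1
    for i in range(matrix.length):
        new_lo = lo_i + int(k[i].min())
        new_hi = lo_i + width_i - 1 + int(k[i].max())
        new_state = np.zeros((4, new_hi - new_lo + 1))
        for a_next in range(4):
            shift = lo_i + int(k[i, a_next]) - new_lo
            if i == 0:
                new_state[a_next, shift] += bg.mono[a_next]
            else:
                contrib = (t[:, a_next][:, None] * state).sum(axis=0)
                new_state[a_next, shift : shift + width_i] += contrib
        state = new_state
        lo_i, width_i = new_lo, state.shape[1]
    probs = state.sum(axis=0)
    full = np.zeros(n_bins)
    full[lo_i - lo : lo_i - lo + width_i] = probs
    total = full.sum()
    if not np.isclose(total, 1.0, atol=1e-10):
        raise AssertionError(f"spectrum mass {total} not conserved")
    return EnergySpectrum(bin_width, lo, full / total)


def enumerate_sequence_space(L: int) -> np.ndarray:
    """All 4^L sequences as an (4^L, L) array of base indices."""
    n = 4**L
    codes = np.arange(n)
    out = np.empty((n, L), dtype=np.int8)
    for i in range(L - 1, -1, -1):
        out[:, i] = codes % 4
        codes //= 4
    return out


def neutral_log_probs_encoded(bg: MarkovBackground, idx: np.ndarray) -> np.ndarray:
    """log pi0 for an (n, L) array of base indices (vectorized)."""
    with np.errstate(divide="ignore"):
        log_mono = np.log(bg.mono)
        log_t = np.log(bg.transition())
    lp = log_mono[idx[:, 0]]
    for i in range(1, idx.shape[1]):
        lp = lp + log_t[idx[:, i - 1], idx[:, i]]
    return lp


def scan_background_energies(
    matrix: EnergyMatrix,
    sequences,
    bg: MarkovBackground,
    both_strands: bool = True,
    bin_width: float = 0.02,
):
    """Slide an L-window over records and compare to the neutral spectrum.

    Returns ``(empirical, neutral, percent_deviation, n_windows, n_skipped)``
    where the two spectra share the neutral spectrum's bins and
    percent_deviation = 100 * (empirical - neutral) / neutral (NaN where the
    neutral mass is zero).  Windows containing non-ACGT characters are
    skipped and counted.
    """
    L = matrix.length
    k = quantized_matrix(matrix, bin_width)
    neutral = neutral_energy_spectrum(bg, matrix, bin_width)
    counts = np.zeros(neutral.probs.size, dtype=float)
    n_windows = 0
    n_skipped = 0
    for s in sequences:
        s = s if isinstance(s, str) else str(s)
        try:
            idx = encode_sequence(s)
            skip_mask = None
        except ValueError:
            arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
            idx = np.zeros(arr.size, dtype=np.int8)
            ok = np.zeros(arr.size, dtype=bool)
            for b, j in zip("ACGT", range(4)):
                hit = arr == ord(b)
                idx[hit] = j
                ok |= hit
            skip_mask = ~ok
        if idx.size < L:
            continue
        strands = [idx]
        if both_strands:
            strands.append(COMPLEMENT_INDEX[idx[::-1]].astype(np.int8))
        for strand_idx in strands:
            # quantized energies of all windows via per-position lookup
            per_pos = k[np.arange(L)[None, :], np.lib.stride_tricks.sliding_window_view(strand_idx, L)]
            window_e = per_pos.sum(axis=1)
            if skip_mask is not None:
                bad = np.lib.stride_tricks.sliding_window_view(
                    skip_mask if strand_idx is strands[0] else skip_mask[::-1], L
                ).any(axis=1)
                n_skipped += int(bad.sum())
                window_e = window_e[~bad]
            n_windows += window_e.size
            counts += np.bincount(window_e - neutral.offset, minlength=counts.size)
    empirical = EnergySpectrum(
        bin_width, neutral.offset, counts / max(counts.sum(), 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (empirical.probs - neutral.probs) / neutral.probs
    return empirical, neutral, pct, n_windows, n_skipped
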