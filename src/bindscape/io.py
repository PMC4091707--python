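"""Readers and writers for the package's plain-text formats.

Energy matrices are whitespace-delimited text: a ``#`` header line with
``tf_name=... units=kcal/mol type=energy|psam`` followed by L rows of four
columns (A C G T).  Sites come as FASTA (sequences) or a BED-like TSV with
0-based half-open coordinates, a strand column and a ``posterior`` column
filtered at > 0.9 by default.  Gene tables and ortholog pairs are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import BETA_ROOM, EnergyMatrix, psam_to_energy_matrix

DEFAULT_POSTERIOR_MIN = 0.9


def write_energy_matrix(path, matrix: EnergyMatrix, kind: str = "energy") -> None:
    header = f"# tf_name={matrix.tf_name} units=kcal/mol type={kind}\n"
    body = "\n".join(
        " ".join(f"{v:.6f}" for v in row) for row in matrix.epsilon
    )
    Path(path).write_text(header + body + "\n")


def read_energy_matrix(path, beta_room: float = BETA_ROOM) -> EnergyMatrix:
    """Read the 4-column matrix text format; PSAM variants (flagged in the
    header) are converted to energy units on the fly."""
    lines = Path(path).read_text().strip().splitlines()
    meta = {}
    rows = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            continue
        vals = [float(x) for x in line.split()]
        if len(vals) != 4:
            raise ValueError(f"matrix row must have 4 columns, got {len(vals)}")
        rows.append(vals)
    arr = np.array(rows)
    name = meta.get("tf_name", Path(path).stem)
    if meta.get("type") == "psam":
        return psam_to_energy_matrix(arr, beta_room=beta_room, tf_name=name)
    return EnergyMatrix(name, arr)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_sites_table(
    path, posterior_min: float = DEFAULT_POSTERIOR_MIN
) -> pd.DataFrame:
    """BED-like site table: chrom, start, end, strand, posterior, seq?, tf?.

    Coordinates are 0-based half-open.  Rows with posterior <= the cutoff
    are dropped (curated-site convention).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if "posterior" in df.columns:
        df = df[df["posterior"] > posterior_min].reset_index(drop=True)
    return df


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("gene table must have a gene_id column")
    return df


def read_ortholog_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"seq_a", "seq_b"} <= set(df.columns):
        raise ValueError("ortholog table needs seq_a and seq_b columns")
    return df


def write_spectrum_tsv(path, spectrum) -> None:
    edges = spectrum.centers - spectrum.bin_width / 2
    df = pd.DataFrame(
        {"bin_lo": edges, "bin_hi": edges + spectrum.bin_width, "prob": spectrum.probs}
    )
    df.to_csv(path, sep="\t", index=False)


def write_fit_json(path, fits: dict, weights: dict) -> None:
    out = {}
    for name, fit in fits.items():
        p = fit.params
        params = {k: float(v) for k, v in vars(p).items()}
        if hasattr(p, "gamma"):
            params["gamma"] = float(p.gamma)
        out[name] = {
            "params": params,
            "log_likelihood": fit.log_likelihood,
            "aicc": fit.aicc,
            "k": fit.k,
            "n": fit.n,
            "regime": fit.regime,
            "flags": fit.flags,
            "akaike_weight": float(weights[name]),
        }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def write_landscape_tsv(path, landscape) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": landscape.bin_edges[:-1],
            "bin_hi": landscape.bin_edges[1:],
            "log_fitness": landscape.log_fitness,
            "se": landscape.se,
            "n_sites": landscape.counts,
            "neutral_mass": landscape.neutral_mass,
            "defined": landscape.defined.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
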