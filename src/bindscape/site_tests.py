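"""Tests for site-specific selection.

If all sites of a TF evolve on one universal landscape, their binding
energies should not correlate with biological attributes of the regulated
genes.  This module assigns sites to genes by a strand-aware upstream
window, compares groups (essential vs nonessential) with label-permutation
nulls, screens rank correlations between energy and gene attributes
(knockout growth rate, expression, dN/dS, TSS distance), measures
ortholog divergence (Hamming distance and squared energy difference), and
computes per-TF binding-site sequence entropy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .energy import EnergyMatrix

GENE_COLUMNS = ("gene_id", "tss", "strand", "essential")
GROWTH_CONDITIONS = ("ypd", "ypdge", "ypg", "ype", "ypl")


def growth_summary(gene_table: pd.DataFrame) -> pd.Series:
    """Fitness effect of a knockout: the lowest available condition growth
    rate (relative to wild type)."""
    cols = [c for c in gene_table.columns if c.startswith("growth_")]
    if not cols:
        raise ValueError("no growth_* columns in gene table")
    return gene_table[cols].min(axis=1, skipna=True)


def assign_sites_to_genes(
    sites: pd.DataFrame, gene_table: pd.DataFrame, window: int = 700
) -> pd.DataFrame:
    """Assign each site to every gene whose upstream window contains it.

    ``sites`` needs 0-based half-open ``start``/``end`` (and optionally
    ``chrom``); ``gene_table`` needs ``gene_id``, ``tss``, ``strand``.  A
    site regulates a gene if it lies within ``window`` bp upstream of the
    TSS on the gene's strand (for a - strand gene the window is on the
    higher-coordinate side).  Returns one row per (site, gene) pair with
    the distance from the site to that TSS; a site may regulate several
    genes.
    """
    bad = set(gene_table["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"malformed strand value(s): {bad}")
    rows = []
    has_chrom = "chrom" in sites.columns and "chrom" in gene_table.columns
    for si, site in sites.iterrows():
        for _, gene in gene_table.iterrows():
            if has_chrom and site["chrom"] != gene["chrom"]:
                continue
            tss = int(gene["tss"])
            if gene["strand"] == "+":
                lo, hi = tss - window, tss
                inside = site["start"] >= lo and site["end"] <= hi
                dist = tss - site["end"]
            else:
                lo, hi = tss, tss + window
                inside = site["start"] >= lo and site["end"] <= hi
                dist = site["start"] - tss
            if inside:
                rows.append(
                    {"site_index": si, "gene_id": gene["gene_id"], "tss_distance": int(dist)}
                )
    assigned = pd.DataFrame(rows, columns=["site_index", "gene_id", "tss_distance"])
    if len(assigned):
        assigned = assigned.merge(
            sites.reset_index().rename(columns={"index": "site_index"}),
            on="site_index",
        ).merge(gene_table, on="gene_id", suffixes=("", "_gene"))
    return assigned


def permutation_group_test(
    values,
    group_labels,
    statistic: str = "mean_diff",
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Two-group label-permutation test.

    The null randomly re-categorizes observations into the two groups,
    preserving group sizes.  The two-sided p-value uses the add-one
    estimator p = (#{|stat_perm| >= |stat_obs|} + 1) / (n_perm + 1), so
    p >= 1/(n_perm + 1) always.  ``statistic`` is 'mean_diff' or
    'var_diff' (group A minus group B).
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    mask = labels == groups[0]
    n_a = int(mask.sum())
    if n_a == 0 or n_a == v.size:
        raise ValueError("both groups must be nonempty")

    def stat(m):
        if statistic == "mean_diff":
            return v[m].mean() - v[~m].mean()
        if statistic == "var_diff":
            return v[m].var(ddof=1) - v[~m].var(ddof=1)
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat(mask)
    rng = np.random.default_rng(seed)
    # vectorized permutation of the mean difference; var_diff falls back
    if statistic == "mean_diff":
        total = v.sum()
        idx = np.argsort(rng.random((n_perm, v.size)), axis=1)[:, :n_a]
        sum_a = v[idx].sum(axis=1)
        perm = sum_a / n_a - (total - sum_a) / (v.size - n_a)
    else:
        perm = np.empty(n_perm)
        for i in range(n_perm):
            m = np.zeros(v.size, dtype=bool)
            m[rng.choice(v.size, size=n_a, replace=False)] = True
            perm[i] = stat(m)
    p = (np.sum(np.abs(perm) >= abs(obs)) + 1) / (n_perm + 1)
    return float(obs), float(p)


def rank_correlation_screen(
    annotated: pd.DataFrame,
    attribute: str,
    energy_col: str = "energy",
    tf_col: str = "tf",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman correlation between site energy and a gene attribute per TF.

    Ties are mid-ranked (scipy default).  TFs with fewer than ``min_pairs``
    complete pairs are skipped with a note; a constant attribute gives an
    undefined rho, flagged.  The summary row reports the unweighted mean
    p-value across testable TFs (the cross-TF summary statistic).
    """
    rows = []
    for tf, sub in annotated.groupby(tf_col):
        pairs = sub[[energy_col, attribute]].dropna()
        if len(pairs) < min_pairs:
            rows.append({"tf": tf, "n": len(pairs), "rho": np.nan, "p": np.nan,
                         "note": "skipped: too few pairs"})
            continue
        if pairs[attribute].nunique() == 1 or pairs[energy_col].nunique() == 1:
            rows.append({"tf": tf, "n": len(pairs), "rho": np.nan, "p": np.nan,
                         "note": "undefined: constant values"})
            continue
        rho, p = spearmanr(pairs[energy_col], pairs[attribute])
        rows.append({"tf": tf, "n": len(pairs), "rho": float(rho), "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    out.attrs["mean_p"] = float(out["p"].mean()) if out["p"].notna().any() else np.nan
    return out


def ortholog_divergence(
    pairs: pd.DataFrame,
    matrix: EnergyMatrix,
    group_col: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Hamming distance and squared energy difference between ortholog pairs.

    ``pairs`` needs aligned, equal-length ``seq_a``/``seq_b`` columns.
    Returns a per-pair DataFrame plus summary dict; with ``group_col`` the
    two groups are compared by the mean-difference permutation test.
    """
    hams, de2 = [], []
    for _, row in pairs.iterrows():
        a, b = row["seq_a"], row["seq_b"]
        if len(a) != len(b):
            raise ValueError("ortholog pair length mismatch")
        hams.append(sum(x != y for x, y in zip(a, b)))
        de2.append((matrix.site_energy(a) - matrix.site_energy(b)) ** 2)
    per_pair = pairs.copy()
    per_pair["hamming"] = hams
    per_pair["delta_energy_sq"] = de2
    summary = {
        "mean_hamming": float(np.mean(hams)),
        "mean_delta_energy_sq": float(np.mean(de2)),
    }
    if group_col is not None:
        for col in ("hamming", "delta_energy_sq"):
            obs, p = permutation_group_test(
                per_pair[col], per_pair[group_col], "mean_diff", n_perm, seed
            )
            summary[f"{col}_group_diff"] = obs
            summary[f"{col}_p"] = p
    return per_pair, summary


def tf_site_entropy(sites) -> float:
    """Sequence entropy (bits): sum over positions of column entropies of
    the observed base frequencies (no pseudocount)."""
    seqs = list(sites)
    if not seqs:
        raise ValueError("need at least one site")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sites must share one length")
    total = 0.0
    for i in range(L):
        _, counts = np.unique([s[i] for s in seqs], return_counts=True)
        f = counts / counts.sum()
        total -= float((f * np.log2(f)).sum())
    return total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported as an extension
    alongside the raw per-TF p-values and their cross-TF mean)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def selection_battery(
    annotated: pd.DataFrame,
    matrix: EnergyMatrix | None = None,
    ortholog_pairs: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Run the full site-specific selection screen on annotated sites.

    ``annotated`` needs columns tf, energy, essential, and optionally
    growth_rate, expression, dnds, tss_distance.  Returns a dict with the
    essentiality permutation tests (mean and variance differences), the
    per-attribute rank-correlation tables (with BH-adjusted columns), and
    ortholog-divergence comparisons when pairs are given.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    ess_rows = []
    for tf, sub in annotated.groupby("tf"):
        labels = sub["essential"].astype(str)
        usable = labels.isin(["essential", "nonessential"])
        sub = sub[usable]
        labels = labels[usable]
        if labels.nunique() < 2:
            continue
        row = {"tf": tf, "n": len(sub)}
        for statistic in ("mean_diff", "var_diff"):
            obs, p = permutation_group_test(
                sub["energy"], labels, statistic, n_perm, int(rng.integers(2**31 - 1))
            )
            row[statistic], row[f"{statistic}_p"] = obs, p
        ess_rows.append(row)
    ess = pd.DataFrame(ess_rows)
    if len(ess):
        ess["mean_diff_p_bh"] = bh_adjust(ess["mean_diff_p"])
        ess.attrs["mean_p"] = float(ess["mean_diff_p"].mean())
    out["essentiality"] = ess

    for attr in ("growth_rate", "expression", "dnds", "tss_distance"):
        if attr in annotated.columns:
            table = rank_correlation_screen(annotated, attr)
            table["p_bh"] = bh_adjust(table["p"])
            out[attr] = table
    if ortholog_pairs is not None and matrix is not None:
        _, summary = ortholog_divergence(
            ortholog_pairs, matrix, group_col="essential",
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        out["ortholog"] = summary
    return out
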