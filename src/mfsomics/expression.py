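"""RPKM quantification, extreme-group differential expression, and
methylation-expression correlation.

Differential expression follows the extreme-group design: for each gene,
the k = round(0.20 * n) highest-expressing samples (respectively lowest)
are compared with the remaining n - k by Welch's unequal-variance t-test;
on a 29-sample cohort this is six versus twenty-three.  BH q values are
computed across genes within each direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .smg import bh_adjust

EXTREME_FRACTION = 0.20


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM values plus the quantities needed to recompute them."""

    rpkm: pd.DataFrame
    gene_lengths: pd.Series
    total_mapped: pd.Series

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("negative RPKM")
        if (self.gene_lengths <= 0).any():
            raise ValueError("non-positive gene length")


def compute_rpkm(counts, gene_length_bases, total_mapped):
    """RPKM = count / ((length/1e3) * (total_mapped/1e6)).

    ``counts`` may be a vector per gene (scalar length) or a gene x sample
    DataFrame with per-gene lengths and per-sample totals.
    """
    if isinstance(counts, pd.DataFrame):
        lengths = pd.Series(gene_length_bases).reindex(counts.index)
        totals = pd.Series(total_mapped).reindex(counts.columns)
        if (lengths <= 0).any():
            raise ValueError("zero gene length")
        if (totals <= 0).any():
            raise ValueError("total mapped reads must be positive")
        return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    counts = np.asarray(counts, dtype=float)
    if np.any(np.asarray(gene_length_bases) <= 0):
        raise ValueError("zero gene length")
    if np.any(np.asarray(total_mapped) <= 0):
        raise ValueError("total mapped reads must be positive")
    return counts / ((np.asarray(gene_length_bases) / 1e3) * (np.asarray(total_mapped) / 1e6))


def filter_unexpressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero reads in strictly more than 50% of samples."""
    zero_frac = (counts == 0).sum(axis=1) / counts.shape[1]
    return counts.loc[zero_frac <= 0.5]


def extreme_group_size(n_samples: int, fraction: float = EXTREME_FRACTION) -> int:
    """Per-tail group size: nearest integer of fraction x n (29 -> 6)."""
    return int(round(fraction * n_samples))


def extreme_group_de(
    log2_rpkm: pd.DataFrame, fraction: float = EXTREME_FRACTION
) -> pd.DataFrame:
    """Welch's t-test of the k extreme samples against the rest, per gene.

    Returns one row per gene and direction ("up": k highest vs rest;
    "down": k lowest vs rest) with t, p and BH q within each direction.
    Genes with zero variance in both groups get p = 1.
    """
    n = log2_rpkm.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples")
    k = extreme_group_size(n, fraction)
    # stable tie-break: order by value then sample id
    cols = np.array(log2_rpkm.columns)
    rows = []
    for gene, vals in log2_rpkm.iterrows():
        v = vals.values.astype(float)
        order = np.lexsort((cols, v))
        for direction in ("up", "down"):
            idx = order[-k:] if direction == "up" else order[:k]
            rest = order[:-k] if direction == "up" else order[k:]
            a, b = v[idx], v[rest]
            if np.var(a) == 0 and np.var(b) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"gene": gene, "direction": direction, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = 1.0
    for direction in ("up", "down"):
        mask = out["direction"] == direction
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].values)
    return out


def methylation_expression_correlation(
    beta_or_m: pd.DataFrame,
    log2_rpkm: pd.DataFrame,
    gene_probe_map: dict[str, str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of promoter methylation with expression per gene.

    Genes need >= 3 shared samples; constant vectors are skipped.  The
    ``silenced`` flag marks rho < 0 with BH q below ``q_threshold``.
    """
    samples = [s for s in log2_rpkm.columns if s in beta_or_m.columns]
    rows = []
    for gene, probe in gene_probe_map.items():
        if gene not in log2_rpkm.index or probe not in beta_or_m.index:
            continue
        x = beta_or_m.loc[probe, samples].values.astype(float)
        y = log2_rpkm.loc[gene, samples].values.astype(float)
        if len(x) < 3:
            continue
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue  # rho undefined for constant vectors
        rho, p = stats.spearmanr(x, y)
        rows.append({"gene": gene, "probe": probe, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].values)
        out["silenced"] = (out["rho"] < 0) & (out["q"] < q_threshold)
    return out


def log2_transform(rpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM + 1); the pseudocount keeps zero-RPKM genes finite."""
    return np.log2(rpkm + 1.0)
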