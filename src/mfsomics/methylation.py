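"""Methylation analysis: β→M transform, variable-probe selection,
Ward hierarchical clustering into methylation subtypes, and per-cluster
differential (hyper-)methylation.

β is the methylated fraction at a CpG probe, in [0, 1]; M is its logit,
M = log2(β/(1-β)), which is closer to homoscedastic and is the working
scale for clustering and testing.  Probe selection keeps probes whose
|coefficient of variation| of M exceeds 60 (per cent scale); because the
CV diverges as the mean M approaches zero, near-zero-mean probes are
handled by a standard-deviation floor instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats

from .smg import bh_adjust

CV_THRESHOLD = 60.0
DIFF_METH_Q = 0.2

log = logging.getLogger(__name__)


@dataclass
class MethylationMatrix:
    """Probe x sample β values with optional probe annotations."""

    beta: pd.DataFrame
    probe_annot: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.values
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("beta values must lie in [0, 1]")

    def m_values(self, eps: float = 1e-6) -> pd.DataFrame:
        return pd.DataFrame(
            beta_to_m(self.beta.values, eps=eps),
            index=self.beta.index,
            columns=self.beta.columns,
        )


@dataclass
class ClusterAssignment:
    labels: pd.Series         # sample -> letter label
    linkage_tree: np.ndarray
    k: int

    def as_int(self) -> np.ndarray:
        return np.array([ord(l) - ord("A") for l in self.labels.values])


def beta_to_m(beta, eps: float = 1e-6):
    """M = log2(β'/(1-β')) with β' clamped into [eps, 1-eps]."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse logit: β = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0**-m)
    return float(out) if out.ndim == 0 else out


def select_variable_probes(
    m_matrix: pd.DataFrame,
    cv_threshold: float = CV_THRESHOLD,
    mean_eps: float = 0.05,
    sd_floor: float = 1.0,
) -> pd.Index:
    """Probes with |CV of M| = 100 x sd/|mean| above ``cv_threshold``.

    Probes whose |mean M| is below ``mean_eps`` escape the diverging
    denominator and are kept when their sd exceeds ``sd_floor``.
    """
    if m_matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    mean = m_matrix.mean(axis=1)
    sd = m_matrix.std(axis=1, ddof=1)
    near_zero = mean.abs() < mean_eps
    cv = 100.0 * sd / mean.abs().where(~near_zero)
    keep = (cv > cv_threshold) & ~near_zero
    keep |= near_zero & (sd > sd_floor)
    return m_matrix.index[keep]


def hierarchical_cluster(m_subset: pd.DataFrame, k: int = 3) -> ClusterAssignment:
    """Agglomerative clustering of samples: Euclidean metric, Ward linkage
    (Ward.D2 convention), tree cut at k; labels A, B, C... ordered by the
    first sample carrying each label."""
    n = m_subset.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    X = m_subset.values.T  # samples x probes
    tree = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel so the first occurrence order defines A, B, C...
    mapping: dict[int, str] = {}
    for r in raw:
        if r not in mapping:
            mapping[r] = chr(ord("A") + len(mapping))
    labels = pd.Series([mapping[r] for r in raw], index=m_subset.columns, name="cluster")
    return ClusterAssignment(labels=labels, linkage_tree=tree, k=k)


def gap_statistic_k(m_subset: pd.DataFrame, k_max: int = 6, n_ref: int = 10,
                    seed: int = 0) -> int:
    """Gap-statistic helper for choosing k (not used by the default pipeline)."""
    rng = np.random.default_rng(seed)
    X = m_subset.values.T
    mins, maxs = X.min(axis=0), X.max(axis=0)

    def within_dispersion(data, k):
        tree = linkage(data, method="ward")
        lab = fcluster(tree, t=k, criterion="maxclust")
        w = 0.0
        for c in np.unique(lab):
            pts = data[lab == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return max(w, 1e-12)

    gaps = []
    for k in range(1, k_max + 1):
        ref = np.log(
            [
                within_dispersion(rng.uniform(mins, maxs, size=X.shape), k)
                for _ in range(n_ref)
            ]
        ).mean()
        gaps.append(ref - np.log(within_dispersion(X, k)))
    return int(np.argmax(gaps) + 1)


def differential_methylation(
    m_matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    q_threshold: float = DIFF_METH_Q,
) -> pd.DataFrame:
    """One-vs-rest hypermethylation per probe per cluster.

    A one-sided (greater) Wilcoxon rank-sum test compares each cluster's M
    values with all other samples; q is BH-adjusted per cluster; rows with
    q below ``q_threshold`` carry ``significant=True``.  Constant probes get
    p = 1; singleton clusters are skipped.
    """
    labels = assignment.labels.reindex(m_matrix.columns)
    if labels.nunique() < 2:
        raise ValueError("need at least two clusters")
    out_frames = []
    for cluster in sorted(labels.unique()):
        in_mask = (labels == cluster).values
        if in_mask.sum() < 2:
            log.warning("cluster %s has <2 samples; skipped", cluster)
            continue
        a = m_matrix.values[:, in_mask]
        b = m_matrix.values[:, ~in_mask]
        pvals = np.ones(m_matrix.shape[0])
        for i in range(m_matrix.shape[0]):
            row = m_matrix.values[i]
            if np.all(row == row[0]):
                continue  # constant probe: p stays 1
            pvals[i] = stats.mannwhitneyu(a[i], b[i], alternative="greater").pvalue
        q = bh_adjust(pvals)
        out_frames.append(
            pd.DataFrame(
                {
                    "probe": m_matrix.index,
                    "cluster": cluster,
                    "p": pvals,
                    "q": q,
                    "significant": q < q_threshold,
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)
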