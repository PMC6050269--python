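"""Integration statistics: cluster/driver associations, mutual exclusivity,
Kaplan-Meier survival with log-rank tests, cohort frequency summaries, and
mutation-burden comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .types import SurvivalRecord


@dataclass
class AlterationMatrix:
    """Sample x gene binary alteration indicators with pathway groupings."""

    data: pd.DataFrame  # bool/0-1, samples as rows
    pathways: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        vals = self.data.values
        if not np.isin(vals, (0, 1, True, False)).all():
            raise ValueError("alteration matrix must be binary")

    def vector(self, gene_or_pathway: str) -> pd.Series:
        if gene_or_pathway in self.data.columns:
            return self.data[gene_or_pathway].astype(bool)
        if self.pathways and gene_or_pathway in self.pathways:
            genes = [g for g in self.pathways[gene_or_pathway] if g in self.data.columns]
            return self.data[genes].any(axis=1)
        raise KeyError(gene_or_pathway)


def cohort_frequency(
    alterations: AlterationMatrix, gene_or_pathway: str
) -> tuple[int, int, int]:
    """(count, total, percent) with percent rounded to the nearest integer."""
    vec = alterations.vector(gene_or_pathway)
    count, total = int(vec.sum()), int(len(vec))
    return count, total, frequency_percent(count, total)


def frequency_percent(count: int, total: int) -> int:
    if total <= 0:
        raise ValueError("empty cohort")
    return int(round(100.0 * count / total))


def chi2_association(
    grouping, alteration_vector, collapse_group: str | None = None
) -> tuple[float, int, float]:
    """Pearson χ² of a groups x {altered, not} contingency table.

    ``collapse_group`` switches to a designated-group-vs-rest 2x2 table;
    the default is the full k x 2 table.  Fisher's exact test is used as a
    fallback on 2x2 tables when any expected cell is below 1.
    """
    g = pd.Series(grouping).astype(str)
    a = pd.Series(alteration_vector).astype(bool)
    if len(g) != len(a):
        raise ValueError("length mismatch")
    if collapse_group is not None:
        g = (g == collapse_group).map({True: collapse_group, False: "rest"})
    table = pd.crosstab(g.values, a.values)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table.values, correction=False)
    if table.shape == (2, 2) and (expected < 1).any():
        _, p = stats.fisher_exact(table.values)
    return float(chi2), int(dof), float(p)


def mutual_exclusivity_report(
    alterations: AlterationMatrix,
    gene_set: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise co-alteration counts with permutation p values.

    Sample labels of one gene are shuffled (preserving per-gene totals);
    the p value is the fraction of permutations with co-alteration count
    at most the observed one (small p: fewer overlaps than chance, i.e.
    mutual exclusivity).
    """
    if len(gene_set) < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in combinations(gene_set, 2):
        v1 = alterations.vector(g1).values
        v2 = alterations.vector(g2).values
        observed = int((v1 & v2).sum())
        perm = np.array(
            [(rng.permutation(v1) & v2).sum() for _ in range(n_permutations)]
        )
        p = float((perm <= observed).mean())
        rows.append(
            {"gene1": g1, "gene2": g2, "n_co_altered": observed, "perm_p": p}
        )
    return pd.DataFrame(rows)


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate; columns time, survival."""
    if not records:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [r.event for r in records])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
    )


def logrank_test(records: list[SurvivalRecord], grouping) -> tuple[float, float]:
    """Log-rank statistic and χ²(k-1) p value across groups."""
    groups = pd.Series(list(grouping))
    if groups.nunique() < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(
        [r.time for r in records], groups.values, [r.event for r in records]
    )
    return float(res.test_statistic), float(res.p_value)


def burden_comparison(mutation_counts, assignment) -> pd.DataFrame:
    """Pairwise Student's t-tests (equal variance) of per-sample non-silent
    mutation counts between clusters; groups of size < 2 are skipped."""
    counts = pd.Series(mutation_counts, dtype=float)
    groups = pd.Series(assignment).reindex(counts.index)
    rows = []
    labels = sorted(groups.dropna().unique())
    for g1, g2 in combinations(labels, 2):
        a = counts[groups == g1].values
        b = counts[groups == g2].values
        if len(a) < 2 or len(b) < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"group1": g1, "group2": g2, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
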