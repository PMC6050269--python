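"""Significantly-mutated-gene (SMG) detection.

Three per-gene significance tests are combined:

* the aggregated mutation test — the observed count of non-silent
  substitutions/indels plus focal amplifications and homozygous deletions
  in a gene, against a Poisson expectation built from the cohort-wide
  background mutation rate and the gene's CDS length;
* an activation-bias test — recurrence of mutations at a single position,
  scored as a binomial tail under uniform placement with Bonferroni
  correction over positions;
* an inactivation-bias test — enrichment of truncating classes (nonsense,
  frameshift, splice site) over the cohort truncating fraction, scored as
  a binomial tail.

Each test family is Benjamini-Hochberg adjusted across genes, the three q
values are combined as their geometric mean, and genes whose allele
fractions are consistently low (subclonal bias, one-sided rank-sum p <
0.01 with >= 3 VAFs) are removed.  Final calls require combined q < 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MutationRecord, TRUNCATING_CLASSES, GeneModel

COMBINED_Q_THRESHOLD = 0.1
SUBCLONAL_ALPHA = 0.01
SUBCLONAL_MIN_VAFS = 3
_Q_FLOOR = 1e-300  # avoid zero annihilation in the geometric mean


@dataclass
class BackgroundModel:
    """Cohort-wide per-class mutation rates (per base per sample)."""

    class_rates: dict[str, float]
    n_samples: int
    cds_lengths: dict[str, int]
    #: expected focal CNA events per gene per sample
    cna_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("negative class rate")
        if any(l <= 0 for l in self.cds_lengths.values()):
            raise ValueError("non-positive CDS length")

    @property
    def total_rate(self) -> float:
        return sum(self.class_rates.values())

    def truncating_fraction(self) -> float:
        total = self.total_rate
        if total == 0:
            return 0.0
        return sum(
            r for c, r in self.class_rates.items() if c in TRUNCATING_CLASSES
        ) / total

    def expected_count(self, gene: str) -> float:
        """λ for the aggregated test: mutation plus focal-event expectation."""
        lam = self.total_rate * self.cds_lengths[gene] * self.n_samples
        return lam + self.cna_rate * self.n_samples


@dataclass
class SMGResult:
    gene: str
    observed: int
    expected: float
    p_amm: float
    p_act: float
    p_inact: float
    q_amm: float = 1.0
    q_act: float = 1.0
    q_inact: float = 1.0
    combined_q: float = 1.0
    subclonal_flag: bool = False
    final_call: bool = False


def estimate_background(
    mutations: list[MutationRecord],
    gene_models: list[GeneModel],
    n_samples: int,
    exclude_genes: set[str] | frozenset[str] = frozenset(),
    strict: bool = False,
) -> BackgroundModel:
    """Per-class rate = cohort class count / (Σ CDS length × n_samples).

    ``exclude_genes`` removes candidate drivers from both the numerator and
    the CDS exposure, so planted signal does not inflate the background.
    """
    if not gene_models or n_samples < 1:
        raise ValueError("need at least one gene and one sample")
    cds_lengths = {g.gene: g.cds_length for g in gene_models}
    exposure_len = sum(
        l for g, l in cds_lengths.items() if g not in exclude_genes
    )
    if exposure_len <= 0:
        raise ValueError("no CDS exposure outside excluded genes")
    counted = [
        m for m in mutations if m.is_non_silent and m.gene not in exclude_genes
    ]
    if not counted and strict:
        raise ValueError("empty mutation table in strict mode")
    class_counts: dict[str, int] = {}
    for m in counted:
        class_counts[m.mclass] = class_counts.get(m.mclass, 0) + 1
    denom = exposure_len * n_samples
    class_rates = {c: k / denom for c, k in class_counts.items()}
    return BackgroundModel(
        class_rates=class_rates, n_samples=n_samples, cds_lengths=cds_lengths
    )


def amm_test(observed: int, lam: float) -> float:
    """Upper-tail Poisson p: P(X >= observed | X ~ Poisson(λ))."""
    if observed < 0 or lam < 0:
        raise ValueError("negative inputs to the aggregated mutation test")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def activation_bias_test(positions, cds_length: int) -> float:
    """Recurrence p: binomial tail on the maximum per-position count under
    uniform placement of n mutations over L positions, Bonferroni over L."""
    if cds_length <= 0:
        raise ValueError("CDS length must be positive")
    positions = list(positions)
    n = len(positions)
    if n == 0:
        raise ValueError("need at least one mutation")
    _, counts = np.unique(positions, return_counts=True)
    m = int(counts.max())
    if m <= 1:
        return 1.0
    p_single = float(stats.binom.sf(m - 1, n, 1.0 / cds_length))
    return min(1.0, cds_length * p_single)


def inactivation_bias_test(
    class_counts: dict[str, int], background_truncating_fraction: float
) -> float:
    """Binomial upper tail for the observed truncating count."""
    if not 0.0 < background_truncating_fraction < 1.0:
        raise ValueError("background truncating fraction must lie in (0, 1)")
    total = sum(class_counts.values())
    if total < 1:
        raise ValueError("need at least one mutation")
    k = sum(v for c, v in class_counts.items() if c in TRUNCATING_CLASSES)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, total, background_truncating_fraction))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (order preserving, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_q(q_amm: float, q_act: float, q_inact: float) -> float:
    """Geometric mean of the three per-test q values (zeros floored)."""
    qs = np.maximum([q_amm, q_act, q_inact], _Q_FLOOR)
    if np.any(qs > 1):
        raise ValueError("q values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(qs))))


def subclonal_bias_filter(
    gene_vafs, cohort_vafs, alpha: float = SUBCLONAL_ALPHA
) -> bool:
    """True (remove gene) when gene VAFs are rank-sum shifted below the
    cohort at level alpha; genes with < 3 VAFs are never flagged."""
    gene_vafs = np.asarray(gene_vafs, dtype=float)
    cohort_vafs = np.asarray(cohort_vafs, dtype=float)
    if cohort_vafs.size == 0:
        raise ValueError("cohort VAFs must be non-empty")
    if gene_vafs.size < SUBCLONAL_MIN_VAFS:
        return False
    p = stats.mannwhitneyu(gene_vafs, cohort_vafs, alternative="less").pvalue
    return bool(p < alpha)


def call_smgs(
    mutations: list[MutationRecord],
    gene_models: list[GeneModel],
    n_samples: int,
    cn_gene_events: dict[str, list[str]] | None = None,
    background: BackgroundModel | None = None,
    exclude_genes: set[str] | frozenset[str] = frozenset(),
    combined_q_threshold: float = COMBINED_Q_THRESHOLD,
    subclonal_alpha: float = SUBCLONAL_ALPHA,
    apply_subclonal_filter: bool = True,
) -> list[SMGResult]:
    """Run the full SMG procedure and return results sorted by combined q.

    ``cn_gene_events`` maps gene -> list of focal event calls ("AMP"/"HD")
    aggregated over samples; these counts enter the aggregated test.  The
    expected focal-event rate is the cohort total over genes x samples.
    """
    cn_gene_events = cn_gene_events or {}
    non_silent = [m for m in mutations if m.is_non_silent]
    if background is None:
        background = estimate_background(
            non_silent, gene_models, n_samples, exclude_genes=exclude_genes
        )
    total_focal = sum(len(v) for v in cn_gene_events.values())
    background.cna_rate = total_focal / (len(gene_models) * n_samples)

    by_gene: dict[str, list[MutationRecord]] = {g.gene: [] for g in gene_models}
    for m in non_silent:
        if m.gene in by_gene:
            by_gene[m.gene].append(m)
    cohort_vafs = np.array([m.vaf for m in non_silent])
    trunc_frac = background.truncating_fraction()
    # degenerate background -> fall back to the canonical cohort mix
    if not 0.0 < trunc_frac < 1.0:
        from .synthdata import BACKGROUND_TRUNCATING_FRACTION

        trunc_frac = BACKGROUND_TRUNCATING_FRACTION

    results: list[SMGResult] = []
    for g in gene_models:
        muts = by_gene[g.gene]
        events = cn_gene_events.get(g.gene, [])
        observed = len(muts) + len(events)
        lam = background.expected_count(g.gene)
        p_amm = amm_test(observed, lam)
        if muts:
            p_act = activation_bias_test([m.pos for m in muts], g.cds_length)
            counts: dict[str, int] = {}
            for m in muts:
                counts[m.mclass] = counts.get(m.mclass, 0) + 1
            p_inact = inactivation_bias_test(counts, trunc_frac)
        else:
            p_act = p_inact = 1.0
        sub = (
            subclonal_bias_filter(
                [m.vaf for m in muts], cohort_vafs, alpha=subclonal_alpha
            )
            if (muts and apply_subclonal_filter)
            else False
        )
        results.append(
            SMGResult(
                gene=g.gene,
                observed=observed,
                expected=lam,
                p_amm=p_amm,
                p_act=p_act,
                p_inact=p_inact,
                subclonal_flag=sub,
            )
        )

    q_amm = bh_adjust([r.p_amm for r in results])
    q_act = bh_adjust([r.p_act for r in results])
    q_inact = bh_adjust([r.p_inact for r in results])
    for r, qa, qc, qi in zip(results, q_amm, q_act, q_inact):
        r.q_amm, r.q_act, r.q_inact = float(qa), float(qc), float(qi)
        r.combined_q = combine_q(r.q_amm, r.q_act, r.q_inact)
        r.final_call = bool(r.combined_q < combined_q_threshold and not r.subclonal_flag)
    results.sort(key=lambda r: (r.combined_q, r.gene))
    return results
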