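"""Copy-number estimation from tumor/normal depth ratios.

The total copy number at a probe is recovered from the depth ratio R(x)
through the purity/ploidy correction

    adjusted CN = [1 - (1 - R(x)) / purity] * ploidy

so a neutral probe (R = 1) maps to the sample ploidy for any purity.  Focal
amplifications are segments with adjusted CN >= 6; homozygous deletions are
segments with adjusted CN <= 0, except that apparent HDs whose raw
(pre-adjustment) ratio exceeds 0.5 are discarded as purity artifacts: 0.5
is exactly the raw ratio of a true HD at the cohort-average purity of 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CNSegment, MutationRecord

AMP_THRESHOLD = 6.0       # adjusted CN >= 6 -> focal amplification
HD_THRESHOLD = 0.0        # adjusted CN <= 0 -> homozygous deletion
HD_RAW_RATIO_MAX = 0.5    # raw R > 0.5 disqualifies an HD call
STRAND_BIAS_MAX = 0.95    # strict: > 0.95 removed


@dataclass
class DepthProfile:
    """Per-probe tumor and normal read depth along one chromosome."""

    chrom: str
    positions: np.ndarray
    tumor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.tumor) == len(self.normal)):
            raise ValueError("depth profile vectors must have equal length")
        if np.any(self.tumor < 0) or np.any(self.normal < 0):
            raise ValueError("negative read depth")


@dataclass
class PurityPloidy:
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


def compute_depth_ratio(
    tumor_depths: np.ndarray, normal_depths: np.ndarray
) -> np.ndarray:
    """R(x) = tumor/normal per probe after median-normalizing each vector.

    Median normalization removes library-size differences.  Probes with
    zero normal depth are masked (NaN).
    """
    t = np.asarray(tumor_depths, dtype=float)
    n = np.asarray(normal_depths, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumor and normal depth vectors differ in length")
    n_med = np.median(n[n > 0]) if np.any(n > 0) else 0.0
    if n_med <= 0:
        raise ValueError("normal depth is zero everywhere")
    t_med = np.median(t[t > 0]) if np.any(t > 0) else 0.0
    if t_med <= 0:
        raise ValueError("tumor depth is zero everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (t / t_med) / (n / n_med)
    r[n == 0] = np.nan
    return r


def adjust_cn(r, purity: float, ploidy: float):
    """adjusted CN = [1 - (1 - R) / purity] * ploidy."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("depth ratio must be >= 0")
    out = (1.0 - (1.0 - r) / purity) * ploidy
    return float(out) if out.ndim == 0 else out


def raw_ratio_at_adjusted_cn(
    adjusted: float, purity: float, ploidy: float = 2.0
) -> float:
    """Invert the adjustment: the raw ratio R giving this adjusted CN.

    Solving adjusted = [1 - (1 - R)/purity] * ploidy for R gives
    R = 1 - purity * (1 - adjusted/ploidy).  The HD-filter cutoff is this
    value at adjusted CN 0 and purity 0.5 (where ploidy drops out): R = 0.5.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return 1.0 - purity * (1.0 - adjusted / ploidy)


# ---------------------------------------------------------------------------
# segmentation (circular binary segmentation with a Z-statistic criterion)
# ---------------------------------------------------------------------------

def _noise_sd(x: np.ndarray) -> float:
    """Robust per-probe noise scale: MAD of first differences, insensitive
    to the few large jumps contributed by true breakpoints."""
    if len(x) < 2:
        return 1e-8
    diffs = np.abs(np.diff(x))
    return max(float(np.median(diffs)) / 0.6745 / np.sqrt(2.0), 1e-8)


def _best_window(
    x: np.ndarray, min_size: int, resid_sd: float
) -> tuple[int, int, float]:
    """Best interior window (i, j) and its |Z| for window-vs-rest mean shift.

    Searching over breakpoint pairs (the circular variant of binary
    segmentation) keeps power for short focal events embedded in long
    neutral stretches, where a single split statistic is diluted.
    """
    n = len(x)
    if n < 2 * min_size:
        return -1, -1, 0.0
    csum = np.concatenate([[0.0], np.cumsum(x)])
    total = csum[-1]
    best = (-1, -1, 0.0)
    for i in range(0, n - min_size + 1):
        j = np.arange(i + min_size, n + 1)
        n_in = j - i
        n_out = n - n_in
        ok = (n_out >= min_size) | (n_out == 0)
        # full-length window is no split at all
        ok &= n_out > 0
        if not ok.any():
            continue
        j, n_in, n_out = j[ok], n_in[ok], n_out[ok]
        sum_in = csum[j] - csum[i]
        mean_in = sum_in / n_in
        mean_out = (total - sum_in) / n_out
        z = np.abs(mean_in - mean_out) / (
            resid_sd * np.sqrt(1.0 / n_in + 1.0 / n_out)
        )
        k = int(np.argmax(z))
        if z[k] > best[2]:
            best = (i, int(j[k]), float(z[k]))
    return best


def _segment_one(
    x: np.ndarray, offset: int, min_size: int, z_threshold: float,
    resid_sd: float, cuts: list[int]
) -> None:
    i, j, z = _best_window(x, min_size, resid_sd)
    if i < 0 or z < z_threshold:
        return
    parts = []
    if i > 0:
        cuts.append(offset + i)
        parts.append((0, i))
    if j < len(x):
        cuts.append(offset + j)
        parts.append((j, len(x)))
    parts.append((i, j))
    for a, b in parts:
        _segment_one(x[a:b], offset + a, min_size, z_threshold, resid_sd, cuts)


def segment(
    log2_adjusted_cn: np.ndarray,
    positions: np.ndarray,
    chrom: str = "chr1",
    raw_r: np.ndarray | None = None,
    adjusted_cn: np.ndarray | None = None,
    min_size: int = 5,
    z_threshold: float = 6.0,
) -> list[CNSegment]:
    """Recursive binary segmentation of the log2 adjusted-CN profile.

    Splits are accepted when the mean-shift Z statistic (noise scaled from
    first differences) exceeds ``z_threshold``; segments never shrink below
    ``min_size`` probes.  Segment means of the raw ratio and the adjusted CN
    are carried for downstream focal calling.
    """
    x = np.asarray(log2_adjusted_cn, dtype=float)
    positions = np.asarray(positions)
    if len(x) == 0:
        raise ValueError("cannot segment an empty profile")
    mask = np.isfinite(x)
    x, positions = x[mask], positions[mask]
    if raw_r is not None:
        raw_r = np.asarray(raw_r, dtype=float)[mask]
    if adjusted_cn is not None:
        adjusted_cn = np.asarray(adjusted_cn, dtype=float)[mask]
    if len(x) == 0:
        raise ValueError("no finite probes to segment")
    cuts: list[int] = []
    _segment_one(x, 0, min_size, z_threshold, _noise_sd(x), cuts)
    bounds = [0] + sorted(cuts) + [len(x)]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = CNSegment(
            chrom=chrom,
            start=int(positions[a]),
            end=int(positions[b - 1]) + 1,
            n_probes=b - a,
            mean_raw_r=float(np.mean(raw_r[a:b])) if raw_r is not None else float("nan"),
            mean_adjusted_cn=(
                float(np.mean(adjusted_cn[a:b]))
                if adjusted_cn is not None
                else float(np.mean(2.0 ** x[a:b]))
            ),
        )
        segments.append(seg)
    return segments


def segment_by_chrom(
    log2_adjusted_cn: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    **kwargs,
) -> list[CNSegment]:
    """Segment each chromosome independently; segments never span boundaries."""
    chroms = np.asarray(chroms)
    out: list[CNSegment] = []
    for c in pd.unique(chroms):
        mask = chroms == c
        out.extend(
            segment(
                np.asarray(log2_adjusted_cn)[mask],
                np.asarray(positions)[mask],
                chrom=str(c),
                **kwargs,
            )
        )
    return out


def segment_profile(
    profile: DepthProfile,
    purity: float,
    ploidy: float,
    min_size: int = 5,
    z_threshold: float = 6.0,
    log_floor: float = 0.01,
) -> list[CNSegment]:
    """Ratio -> adjusted CN -> log2 -> segmentation for one depth profile."""
    r = compute_depth_ratio(profile.tumor, profile.normal)
    adj = adjust_cn(r, purity, ploidy)
    log2 = np.log2(np.maximum(adj, log_floor))
    return segment(
        log2,
        profile.positions,
        chrom=profile.chrom,
        raw_r=r,
        adjusted_cn=adj,
        min_size=min_size,
        z_threshold=z_threshold,
    )


def call_focal_events(segments: list[CNSegment]) -> list[CNSegment]:
    """Apply the AMP >= 6 / HD <= 0 thresholds and the raw-ratio HD filter."""
    for seg in segments:
        if seg.mean_adjusted_cn >= AMP_THRESHOLD:
            seg.call = "AMP"
        elif seg.mean_adjusted_cn <= HD_THRESHOLD:
            seg.call = "HD" if seg.mean_raw_r <= HD_RAW_RATIO_MAX else "HD_filtered"
        else:
            seg.call = "neutral"
    return segments


def call_sample(
    profile: DepthProfile, purity: float, ploidy: float, **kwargs
) -> list[CNSegment]:
    return call_focal_events(segment_profile(profile, purity, ploidy, **kwargs))


def events_per_gene(
    segments: list[CNSegment], gene_models
) -> dict[str, str]:
    """Map focal calls onto genes by maximal-|adjusted CN| overlapping segment."""
    out: dict[str, str] = {}
    for g in gene_models:
        hit = None
        for seg in segments:
            if seg.chrom != g.chrom or seg.call in ("neutral", "HD_filtered"):
                continue
            if seg.start < g.end and g.start < seg.end:
                if hit is None or abs(seg.mean_adjusted_cn - 2.0) > abs(
                    hit.mean_adjusted_cn - 2.0
                ):
                    hit = seg
        if hit is not None:
            out[g.gene] = hit.call
    return out


# ---------------------------------------------------------------------------
# targeted-panel per-gene copy number
# ---------------------------------------------------------------------------

def targeted_gene_cn(
    per_gene_depths_tumor: pd.Series, per_gene_depths_normal: pd.Series
) -> pd.Series:
    """Per-gene CN ratio from a targeted panel.

    Each sample's gene value is its coding-region mean depth divided by the
    mean depth over all coding regions; the CN ratio is the tumor value over
    the normal value.
    """
    t = pd.Series(per_gene_depths_tumor, dtype=float)
    n = pd.Series(per_gene_depths_normal, dtype=float).reindex(t.index)
    if len(t) == 0:
        raise ValueError("empty panel")
    if t.mean() <= 0 or n.mean() <= 0:
        raise ValueError("zero panel-wide depth")
    t_norm = t / t.mean()
    n_norm = n / n.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t_norm / n_norm
    return ratio


def targeted_gene_calls(
    per_gene_depths_tumor: pd.Series,
    per_gene_depths_normal: pd.Series,
    purity: float,
    ploidy: float = 2.0,
) -> pd.DataFrame:
    """Targeted-panel ratio -> adjusted CN -> AMP/HD calls (WES thresholds)."""
    ratio = targeted_gene_cn(per_gene_depths_tumor, per_gene_depths_normal)
    adj = adjust_cn(ratio.values, purity, ploidy)
    call = np.where(
        adj >= AMP_THRESHOLD,
        "AMP",
        np.where(
            adj <= HD_THRESHOLD,
            np.where(ratio.values <= HD_RAW_RATIO_MAX, "HD", "HD_filtered"),
            "neutral",
        ),
    )
    return pd.DataFrame(
        {"raw_ratio": ratio, "adjusted_cn": adj, "call": call}, index=ratio.index
    )


def estimate_purity_from_vaf(somatic_vafs) -> float:
    """purity = min(1, 2 x mean VAF) under a heterozygous diploid clonal model."""
    v = np.asarray(somatic_vafs, dtype=float)
    if v.size == 0:
        raise ValueError("no VAFs supplied")
    return float(min(1.0, 2.0 * v.mean()))


def strand_bias_filter(
    records: list[MutationRecord], log=None
) -> list[MutationRecord]:
    """Drop records with max(fwd, rev)/(fwd+rev) strictly above 0.95.

    Records with zero total alt reads are removed with a warning.
    """
    kept = []
    for rec in records:
        total = rec.fwd_alt_reads + rec.rev_alt_reads
        if total == 0:
            if log is not None:
                log.warning("record %s:%d has zero alt reads; removed", rec.gene, rec.pos)
            continue
        if max(rec.fwd_alt_reads, rec.rev_alt_reads) / total > STRAND_BIAS_MAX:
            continue
        kept.append(rec)
    if log is not None:
        log.info("strand_bias_filter: %d in, %d out", len(records), len(kept))
    return kept
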