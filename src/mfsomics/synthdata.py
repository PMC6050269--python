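"""Seeded synthetic cohort generator.

Produces cohorts with the statistical structure each downstream stage
assumes: Poisson background mutations over gene coding lengths with planted
drivers (elevated rate, hotspot recurrence, truncation bias, subclonally
biased passengers), tumor/normal depth profiles carrying focal
amplification/homozygous-deletion events under a chosen purity and ploidy,
paired-end RNA reads spanning a planted in-frame fusion together with
paralog-duplication decoys, a clustered methylation β matrix with
promoter-methylation-anticorrelated expression, and cluster-dependent
survival.  Every generator is deterministic given the cohort seed.

Defaults mirror a discovery cohort of 41 tumors (29 with RNA data) with
average tumor purity 0.5 and diploid genomes; see docs/methods.md.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cna import DepthProfile
from .types import (
    AlignedEnd,
    GeneModel,
    MutationRecord,
    PairedEndAlignment,
)

# Non-silent mutation class mix observed in a 41-tumor WES discovery set
# (1676 missense, 116 nonsense, 42 splice site, 136 indel, 8 read-through);
# indels split 80/20 frameshift/in-frame.
_CLASS_COUNTS = {
    "missense": 1676.0,
    "nonsense": 116.0,
    "splice_site": 42.0,
    "frameshift_indel": 108.8,
    "inframe_indel": 27.2,
    "read_through": 8.0,
}
_TOTAL = sum(_CLASS_COUNTS.values())
CLASS_FRACTIONS = {k: v / _TOTAL for k, v in _CLASS_COUNTS.items()}
#: cohort-level fraction of truncating (nonsense/frameshift/splice) calls
BACKGROUND_TRUNCATING_FRACTION = (
    _CLASS_COUNTS["nonsense"]
    + _CLASS_COUNTS["splice_site"]
    + _CLASS_COUNTS["frameshift_indel"]
) / _TOTAL

_BASES = np.array(list("ACGT"))


class InvalidSpecError(ValueError):
    """A cohort specification violates its invariants."""


@dataclass
class DriverSpec:
    gene: str
    rate_multiplier: float = 50.0
    hotspot: bool = False
    truncation_bias: bool = False
    subclonal: bool = False
    #: fraction of this gene's mutations placed on the hotspot position
    hotspot_fraction: float = 0.6
    #: truncating-class probability when truncation_bias is set
    truncating_fraction: float = 0.8


@dataclass
class CNEvent:
    chrom: str
    start: int
    end: int
    true_cn: float


@dataclass
class FusionSpec:
    gene5: str
    gene3: str
    breakpoint5: int  # transcript coordinate in gene5 (junction, half-open)
    breakpoint3: int  # transcript coordinate in gene3
    n_support_pairs: int = 5
    n_decoy_pairs: int = 3


@dataclass
class MethylSpec:
    n_clusters: int = 3
    n_probes: int = 2000
    n_differential: int = 300
    separation: float = 0.4
    #: genes whose expression anticorrelates with their promoter probe
    n_anticorrelated: int = 50


@dataclass
class SurvivalSpec:
    #: per-cluster exponential hazards (events per day), one per cluster
    hazards: tuple[float, ...] = (0.0001, 0.0004, 0.0012)
    censor_time: float = 2000.0


@dataclass
class CohortSpec:
    n_samples: int
    gene_models: list[GeneModel]
    background_rate: float = 1.6e-6  # mutations / base / sample
    driver_specs: list[DriverSpec] = field(default_factory=list)
    purity: float = 0.5
    ploidy: float = 2.0
    cn_events: list[CNEvent] = field(default_factory=list)
    fusion_spec: FusionSpec | None = None
    methyl_spec: MethylSpec = field(default_factory=MethylSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    n_expression_samples: int = 29
    n_expression_genes: int = 500
    #: fraction of mutation records drawn with >95% strand imbalance
    strand_violation_fraction: float = 0.02
    #: Beta concentration of clonal VAFs around purity/2
    vaf_concentration: float = 50.0
    subclonal_vaf_mean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidSpecError("n_samples must be >= 1")
        if not self.gene_models:
            raise InvalidSpecError("at least one gene model is required")
        if not 0.0 < self.purity <= 1.0:
            raise InvalidSpecError("purity must lie in (0, 1]")
        if self.ploidy <= 0:
            raise InvalidSpecError("ploidy must be positive")
        if self.background_rate < 0:
            raise InvalidSpecError("background_rate must be >= 0")
        if not 0.0 < self.methyl_spec.separation < 1.0 and self.methyl_spec.separation != 0.0:
            raise InvalidSpecError("beta separation must lie in [0, 1)")
        known = {g.gene for g in self.gene_models}
        for d in self.driver_specs:
            if d.gene not in known:
                raise InvalidSpecError(f"driver gene {d.gene!r} not in gene models")
        if self.fusion_spec is not None:
            for g in (self.fusion_spec.gene5, self.fusion_spec.gene3):
                if g not in known:
                    raise InvalidSpecError(f"fusion gene {g!r} not in gene models")
        self.n_expression_samples = min(self.n_expression_samples, self.n_samples)

    @property
    def samples(self) -> list[str]:
        return [f"MFS_{i + 1:03d}" for i in range(self.n_samples)]

    def gene(self, name: str) -> GeneModel:
        for g in self.gene_models:
            if g.gene == name:
                return g
        raise KeyError(name)


def _rng(spec: CohortSpec, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stage]))


def make_gene_models(
    n_genes: int,
    transcript_length: int = 2400,
    utr5: int = 300,
    cds_length: int = 1500,
    spacing: int = 1000,
    chrom: str = "chr1",
    seed: int = 0,
    start: int = 0,
) -> list[GeneModel]:
    """Build single-exon + strand gene models tiled along one chromosome.

    Each gene is one exon of ``transcript_length`` bases whose CDS spans
    [utr5, utr5 + cds_length) in transcript coordinates.
    """
    if utr5 + cds_length > transcript_length:
        raise InvalidSpecError("CDS does not fit in transcript")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    models = []
    pos = start
    for i in range(n_genes):
        seq = "".join(rng.choice(_BASES, size=transcript_length))
        g = GeneModel(
            gene=f"G{i + 1:04d}",
            chrom=chrom,
            exons=[(pos, pos + transcript_length)],
            cds=[(pos + utr5, pos + utr5 + cds_length)],
            strand="+",
            seq=seq,
        )
        models.append(g)
        pos += transcript_length + spacing
    return models


def default_cohort_spec(seed: int = 0, n_genes: int = 300, n_samples: int = 41) -> CohortSpec:
    """The standard synthetic study cohort used throughout the test-bench.

    Plants one 50x driver with hotspot recurrence and truncation bias
    (G0001), one subclonally biased 20x passenger (G0002), a focal
    amplification (true CN 8) over G0011-G0012, a homozygous deletion over
    G0021-G0022, and an in-frame fusion G0005::G0010 with paralog decoys.
    """
    genes = make_gene_models(n_genes, seed=seed)
    by_name = {g.gene: g for g in genes}
    amp_region = CNEvent(
        "chr1", by_name["G0011"].start, by_name["G0012"].end, true_cn=8.0
    )
    hd_region = CNEvent(
        "chr1", by_name["G0021"].start, by_name["G0022"].end, true_cn=0.0
    )
    fusion = FusionSpec("G0005", "G0010", breakpoint5=900, breakpoint3=600)
    return CohortSpec(
        n_samples=n_samples,
        gene_models=genes,
        background_rate=1.6e-6,
        driver_specs=[
            DriverSpec("G0001", rate_multiplier=50.0, hotspot=True, truncation_bias=True),
            DriverSpec("G0002", rate_multiplier=20.0, subclonal=True),
        ],
        purity=0.5,
        ploidy=2.0,
        cn_events=[amp_region, hd_region],
        fusion_spec=fusion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def _draw_vaf(rng, mean: float, conc: float) -> float:
    a = max(mean * conc, 1e-3)
    b = max((1.0 - mean) * conc, 1e-3)
    return float(np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4))


def generate_mutation_table(spec: CohortSpec) -> list[MutationRecord]:
    """Draw the somatic mutation table for the cohort.

    Per gene and sample, counts are Poisson(rate x CDS length) with the
    driver rate multiplier applied; hotspot drivers concentrate a fixed
    fraction of their mutations on a single CDS position; truncation-bias
    drivers draw truncating classes with elevated probability; clonal VAFs
    sit around purity/2 and subclonal-flagged genes around a low mean; a
    configurable record fraction violates the 95% strand-balance rule.
    """
    rng = _rng(spec, 1)
    drivers = {d.gene: d for d in spec.driver_specs}
    classes = list(CLASS_FRACTIONS)
    class_p = np.array([CLASS_FRACTIONS[c] for c in classes])
    trunc_idx = [i for i, c in enumerate(classes) if c in ("nonsense", "splice_site", "frameshift_indel")]
    records: list[MutationRecord] = []
    samples = spec.samples
    for g in spec.gene_models:
        d = drivers.get(g.gene)
        mult = d.rate_multiplier if d else 1.0
        lam = spec.background_rate * mult * g.cds_length
        counts = rng.poisson(lam, size=spec.n_samples)
        if not counts.any():
            continue
        cds_pos = np.array(g.cds_positions())
        hotspot_pos = int(cds_pos[len(cds_pos) // 2])
        for si in np.nonzero(counts)[0]:
            for _ in range(int(counts[si])):
                if d and d.truncation_bias:
                    if rng.random() < d.truncating_fraction:
                        mclass = classes[trunc_idx[rng.integers(len(trunc_idx))]]
                    else:
                        mclass = "missense"
                else:
                    mclass = classes[rng.choice(len(classes), p=class_p)]
                if d and d.hotspot and rng.random() < d.hotspot_fraction:
                    pos = hotspot_pos
                else:
                    pos = int(cds_pos[rng.integers(len(cds_pos))])
                if d and d.subclonal:
                    vaf = _draw_vaf(rng, spec.subclonal_vaf_mean, spec.vaf_concentration)
                else:
                    vaf = _draw_vaf(rng, spec.purity / 2.0, spec.vaf_concentration)
                n_alt = int(rng.poisson(100 * vaf)) + 1
                if rng.random() < spec.strand_violation_fraction:
                    fwd, rev = n_alt, 0
                else:
                    fwd = int(rng.binomial(n_alt, 0.5))
                    rev = n_alt - fwd
                    # keep balanced draws inside the 95% rule
                    if max(fwd, rev) / n_alt > 0.95:
                        fwd = n_alt // 2
                        rev = n_alt - fwd
                ref = g.seq[g.to_transcript_pos(pos)] if g.seq else "A"
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                records.append(
                    MutationRecord(
                        sample=samples[si],
                        gene=g.gene,
                        chrom=g.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        mclass=mclass,
                        vaf=vaf,
                        fwd_alt_reads=fwd,
                        rev_alt_reads=rev,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def expected_depth_ratio(spec: CohortSpec, positions: np.ndarray) -> np.ndarray:
    """E[R(x)] = 1 - purity * (1 - trueCN/ploidy) over events, 1 elsewhere."""
    r = np.ones(len(positions))
    for ev in spec.cn_events:
        mask = (positions >= ev.start) & (positions < ev.end)
        r[mask] = 1.0 - spec.purity * (1.0 - ev.true_cn / spec.ploidy)
    return r


def generate_depth_profiles(
    spec: CohortSpec,
    probe_spacing: int = 500,
    base_depth: float = 100.0,
) -> dict[str, DepthProfile]:
    """Poisson tumor/normal depth per probe; tumor depth scaled by E[R(x)]."""
    if base_depth <= 0:
        raise InvalidSpecError("base depth must be positive")
    chrom_end = max(g.end for g in spec.gene_models)
    for ev in spec.cn_events:
        if ev.start < 0 or ev.end > chrom_end:
            raise InvalidSpecError(
                f"CN event {ev.start}-{ev.end} outside modeled chromosome (0-{chrom_end})"
            )
    rng = _rng(spec, 2)
    positions = np.arange(0, chrom_end, probe_spacing)
    r_expected = expected_depth_ratio(spec, positions)
    chrom = spec.gene_models[0].chrom
    out: dict[str, DepthProfile] = {}
    for s in spec.samples:
        normal = rng.poisson(base_depth, size=len(positions)).astype(float)
        tumor = rng.poisson(base_depth * r_expected).astype(float)
        out[s] = DepthProfile(
            chrom=chrom, positions=positions.copy(), tumor=tumor, normal=normal
        )
    return out


# ---------------------------------------------------------------------------
# fusion read pairs
# ---------------------------------------------------------------------------

_DECOY_BLOCK = 300  # bases duplicated from the 5' partner into the 3' partner


def _mutate(seq: str, n: int, rng) -> str:
    s = list(seq)
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


def plant_paralog_block(
    gene5: GeneModel, gene3: GeneModel, block_start: int, dup_start: int = 0
) -> int:
    """Copy a 300-bp block of gene5's transcript into gene3's with 1 substitution.

    Returns the position (within the block) of the substituted base.  This
    creates the paralog-like duplicated context that makes reads cross-map
    between the two genes, which the realignment filter must detect.
    """
    block = gene5.seq[block_start : block_start + _DECOY_BLOCK]
    sub_at = _DECOY_BLOCK // 2
    base = block[sub_at]
    repl = "A" if base != "A" else "G"
    block = block[:sub_at] + repl + block[sub_at + 1 :]
    gene3.seq = gene3.seq[:dup_start] + block + gene3.seq[dup_start + _DECOY_BLOCK :]
    return sub_at


def generate_fusion_read_pairs(
    spec: CohortSpec,
    read_length: int = 100,
    n_background_pairs: int = 30,
) -> list[PairedEndAlignment]:
    """Paired-end alignments supporting the planted fusion plus decoys.

    Support pairs have their forward end in the 5' gene upstream of the
    breakpoint and their reverse end in the 3' gene downstream, with at
    least one zero-mismatch pair.  Decoy pairs arise from a duplicated
    block of the 5' gene planted in the 3' gene's reference.  Background
    intra-gene proper pairs are added.  End sequences are stored
    reference-oriented.
    """
    rng = _rng(spec, 3)
    fs = spec.fusion_spec
    pairs: list[PairedEndAlignment] = []
    pid = 0

    def emit(e1: AlignedEnd, e2: AlignedEnd) -> None:
        nonlocal pid
        pid += 1
        pairs.append(PairedEndAlignment(f"P{pid:05d}", e1, e2))

    if fs is not None:
        g5 = spec.gene(fs.gene5)
        g3 = spec.gene(fs.gene3)
        for bp, g in ((fs.breakpoint5, g5), (fs.breakpoint3, g3)):
            if not 0 <= bp <= g.transcript_length:
                raise InvalidSpecError(
                    f"breakpoint {bp} outside transcript of {g.gene}"
                )
        if fs.breakpoint5 < read_length + _DECOY_BLOCK + 400:
            raise InvalidSpecError("breakpoint5 too close to transcript start")
        # support pairs: fwd end fully upstream of bp5, rev end downstream of
        # bp3; the first pair abuts the junction exactly, so the cluster-edge
        # breakpoint estimate sits at a fixed offset from the true junction
        for i in range(fs.n_support_pairs):
            if i == 0:
                p1 = fs.breakpoint5 - read_length
                p2 = fs.breakpoint3
            else:
                p1 = fs.breakpoint5 - read_length - int(rng.integers(1, 150))
                p2 = fs.breakpoint3 + int(rng.integers(1, 150))
            mm1 = 0 if i == 0 else int(rng.integers(0, 3))
            mm2 = 0 if i == 0 else int(rng.integers(0, 3))
            s1 = _mutate(g5.seq[p1 : p1 + read_length], mm1, rng)
            s2 = _mutate(g3.seq[p2 : p2 + read_length], mm2, rng)
            emit(
                AlignedEnd(g5.gene, p1, "+", mm1, read_length, seq=s1),
                AlignedEnd(g3.gene, p2, "-", mm2, read_length, seq=s2),
            )
        # decoy pairs from the duplicated block context
        if fs.n_decoy_pairs > 0:
            block_start = fs.breakpoint5 - read_length - 300 - _DECOY_BLOCK
            sub_at = plant_paralog_block(g5, g3, block_start, dup_start=0)
            for _ in range(fs.n_decoy_pairs):
                # true source: gene5 fragment [p, p + insert + read]; one end
                # reported on gene3's duplicated block, avoiding the substituted base
                off1 = int(rng.integers(0, max(sub_at - read_length, 1)))
                off2 = sub_at + 1 + int(
                    rng.integers(0, max(_DECOY_BLOCK - sub_at - 1 - read_length, 1))
                )
                p1 = block_start + off1
                s1 = g5.seq[p1 : p1 + read_length]
                s2 = g5.seq[block_start + off2 : block_start + off2 + read_length]
                emit(
                    AlignedEnd(g5.gene, p1, "+", 0, read_length, seq=s1),
                    AlignedEnd(g3.gene, off2, "-", 0, read_length, seq=s2),
                )
    # background intra-gene proper pairs
    eligible = [g for g in spec.gene_models if g.transcript_length >= read_length + 250]
    for _ in range(n_background_pairs):
        g = eligible[int(rng.integers(len(eligible)))]
        p1 = int(rng.integers(0, g.transcript_length - read_length - 220))
        p2 = p1 + 200 + int(rng.integers(0, 20))
        emit(
            AlignedEnd(g.gene, p1, "+", int(rng.integers(0, 2)), read_length,
                       seq=g.seq[p1 : p1 + read_length]),
            AlignedEnd(g.gene, p2, "-", int(rng.integers(0, 2)), read_length,
                       seq=g.seq[p2 : p2 + read_length]),
        )
    return pairs


# ---------------------------------------------------------------------------
# methylation / expression / survival
# ---------------------------------------------------------------------------

@dataclass
class SyntheticOmics:
    """Methylation, expression and clinical layers of a synthetic cohort."""

    beta: pd.DataFrame            # probe x sample
    probe_annot: pd.DataFrame     # probe -> gene, promoter flag, diff cluster
    counts: pd.DataFrame          # gene x sample read counts
    gene_lengths: pd.Series       # exonic length per expression gene
    total_mapped: pd.Series       # per-sample mapped reads
    labels: pd.Series             # sample -> true cluster label (A, B, C...)
    clinical: pd.DataFrame        # sample, time, event, status
    anticorrelated_genes: list[str]


def generate_methylation_and_expression(spec: CohortSpec) -> SyntheticOmics:
    """β matrix with planted clusters, expression with promoter-methylation
    anticorrelation, and cluster-dependent survival.

    Differential probes draw from cluster-specific Beta distributions whose
    means differ by the configured separation; non-differential probes share
    one per-probe distribution.  A designated gene subset's log2 expression
    decreases linearly in its promoter-probe β plus Gaussian noise.
    """
    ms = spec.methyl_spec
    if ms.n_clusters < 1:
        raise InvalidSpecError("n_clusters must be >= 1")
    rng = _rng(spec, 4)
    samples = spec.samples
    n = spec.n_samples
    k = ms.n_clusters
    letters = [chr(ord("A") + i) for i in range(k)]
    lab_idx = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(lab_idx)
    labels = pd.Series([letters[i] for i in lab_idx], index=samples, name="cluster")

    n_probes = ms.n_probes
    n_diff = min(ms.n_differential, n_probes)
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    beta = np.empty((n_probes, n))

    base_mean = rng.uniform(0.15, 0.45, size=n_diff)
    hyper_mean = base_mean + ms.separation
    if np.any(hyper_mean >= 1.0):
        raise InvalidSpecError("beta separation pushes probe means outside (0, 1)")
    diff_cluster = np.arange(n_diff) % k
    conc = 40.0
    for p in range(n_diff):
        m = np.where(lab_idx == diff_cluster[p], hyper_mean[p], base_mean[p])
        beta[p] = rng.beta(m * conc, (1.0 - m) * conc)
    shared = rng.uniform(0.1, 0.9, size=n_probes - n_diff)
    for j, p in enumerate(range(n_diff, n_probes)):
        m = shared[j]
        beta[p] = rng.beta(m * 150.0, (1.0 - m) * 150.0, size=n)
    np.clip(beta, 1e-4, 1 - 1e-4, out=beta)

    # expression layer (first n_expression_samples samples)
    ne = spec.n_expression_samples
    expr_samples = samples[:ne]
    n_genes = spec.n_expression_genes
    gene_ids = [f"E{i + 1:04d}" for i in range(n_genes)]
    lengths = pd.Series(
        rng.integers(500, 5000, size=n_genes).astype(float), index=gene_ids, name="length"
    )
    total = pd.Series(np.full(ne, 5e6), index=expr_samples, name="total_mapped")

    n_anti = min(ms.n_anticorrelated, n_genes, n_probes - n_diff)
    anti_genes = gene_ids[:n_anti]
    # promoter probes for the anticorrelated genes: high-variance β
    promoter_probes = probe_ids[n_diff : n_diff + n_anti]
    for j in range(n_anti):
        m = rng.uniform(0.3, 0.7)
        beta[n_diff + j] = rng.beta(m * 8.0, (1.0 - m) * 8.0, size=n)
    np.clip(beta, 1e-4, 1 - 1e-4, out=beta)

    log2rpkm = rng.normal(3.0, 1.0, size=n_genes)[:, None] + rng.normal(
        0.0, 0.5, size=(n_genes, ne)
    )
    for j in range(n_anti):
        b = beta[n_diff + j, :ne]
        log2rpkm[j] = 6.0 - 4.0 * b + rng.normal(0.0, 0.5, size=ne)
    # a handful of unexpressed genes to exercise the zero-read filter
    n_zero = max(n_genes // 50, 1)
    log2rpkm[-n_zero:] = -np.inf
    rpkm = np.where(np.isfinite(log2rpkm), 2.0**log2rpkm, 0.0)
    counts = np.rint(
        rpkm * (lengths.values[:, None] / 1e3) * (total.values[None, :] / 1e6)
    )

    annot = pd.DataFrame(
        {
            "probe": probe_ids,
            "gene": [""] * n_probes,
            "promoter": False,
            "diff_cluster": [""] * n_probes,
        }
    ).set_index("probe")
    for p in range(n_diff):
        annot.iloc[p, annot.columns.get_loc("diff_cluster")] = letters[diff_cluster[p]]
    for j, probe in enumerate(promoter_probes):
        annot.loc[probe, "gene"] = anti_genes[j]
        annot.loc[probe, "promoter"] = True

    # survival, cluster-dependent exponential hazards with uniform censoring
    haz = spec.survival_spec.hazards
    if len(haz) < k:
        raise InvalidSpecError("survival_spec must provide a hazard per cluster")
    t_event = rng.exponential(1.0 / np.array([haz[i] for i in lab_idx]))
    t_cens = rng.uniform(100.0, spec.survival_spec.censor_time, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    status = np.array(["primary"] * n, dtype=object)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time": np.round(time, 1),
            "event": event,
            "status": status,
            "cluster": labels.values,
        }
    )

    return SyntheticOmics(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        probe_annot=annot,
        counts=pd.DataFrame(counts, index=gene_ids, columns=expr_samples),
        gene_lengths=lengths,
        total_mapped=total,
        labels=labels,
        clinical=clinical,
        anticorrelated_genes=list(anti_genes),
    )


# ---------------------------------------------------------------------------
# cohort writer
# ---------------------------------------------------------------------------

def write_cohort(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate every layer and write the on-disk cohort plus truth sidecar."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pairs = generate_fusion_read_pairs(spec) if spec.fusion_spec else []
    # note: fusion generation first, so the paralog block is planted before
    # transcripts are written
    muts = generate_mutation_table(spec)
    depth = generate_depth_profiles(spec)
    omics = generate_methylation_and_expression(spec)

    paths["mutations"] = outdir / "mutations.tsv"
    mio.write_mutation_table(muts, paths["mutations"])
    paths["depth"] = outdir / "depth.tsv"
    mio.write_depth_profiles(depth, paths["depth"])
    paths["pairs"] = outdir / "pairs.tsv"
    mio.write_pairs(pairs, paths["pairs"])
    paths["genes_bed"] = outdir / "genes.bed"
    paths["genes_fasta"] = outdir / "transcripts.fasta"
    mio.write_gene_models(spec.gene_models, paths["genes_bed"], paths["genes_fasta"])
    paths["beta"] = outdir / "beta.tsv"
    omics.beta.to_csv(paths["beta"], sep="\t", index_label="probe")
    paths["probe_annot"] = outdir / "probe_annot.tsv"
    omics.probe_annot.to_csv(paths["probe_annot"], sep="\t")
    paths["expr_counts"] = outdir / "expr_counts.tsv"
    counts = omics.counts.copy()
    counts.insert(0, "length", omics.gene_lengths)
    counts.to_csv(paths["expr_counts"], sep="\t", index_label="gene")
    paths["clinical"] = outdir / "clinical.tsv"
    omics.clinical.to_csv(paths["clinical"], sep="\t", index=False)

    truth = {
        "seed": spec.seed,
        "purity": spec.purity,
        "ploidy": spec.ploidy,
        "drivers": [asdict(d) for d in spec.driver_specs],
        "cn_events": [asdict(e) for e in spec.cn_events],
        "fusion": asdict(spec.fusion_spec) if spec.fusion_spec else None,
        "cluster_labels": omics.labels.to_dict(),
        "anticorrelated_genes": omics.anticorrelated_genes,
        "hazards": list(spec.survival_spec.hazards),
    }
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
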