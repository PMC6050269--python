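"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; BED is written natively and
SEG is written 1-based inclusive, per the conventions of each format.
Every writer emits a stable column order and every reader reproduces the
in-memory objects exactly.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cna import DepthProfile
from .types import (
    AlignedEnd,
    CNSegment,
    FormatError,
    GeneModel,
    MutationRecord,
    PairedEndAlignment,
)

log = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "VAF",
    "fwd_alt_reads",
    "rev_alt_reads",
]


@dataclass
class PipelineConfig:
    """All stage thresholds, with defaults at their canonical values."""

    combined_q_threshold: float = 0.1
    subclonal_alpha: float = 0.01
    amp_threshold: float = 6.0
    hd_threshold: float = 0.0
    hd_raw_ratio_max: float = 0.5
    strand_bias_max: float = 0.95
    cluster_gap_max: int = 300
    cluster_span_max: int = 1000
    max_mismatches: int = 2
    min_support_in_frame: int = 2
    min_support_other: int = 3
    insert_max: int = 500
    extreme_fraction: float = 0.20
    cv_threshold: float = 60.0
    diff_meth_q: float = 0.2
    k_clusters: int = 3
    purity: float = 0.5
    ploidy: float = 2.0
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "class": r.mclass,
                "VAF": r.vaf,
                "fwd_alt_reads": r.fwd_alt_reads,
                "rev_alt_reads": r.rev_alt_reads,
            }
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )
    # default float repr is shortest-round-trip: re-reading is exact
    df.to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in MUTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table missing column {col!r}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        vaf = float(row["VAF"])
        if not 0.0 <= vaf <= 1.0:
            raise FormatError(f"line {i}: VAF {vaf} outside [0, 1]")
        try:
            records.append(
                MutationRecord(
                    sample=str(row["sample"]),
                    gene=str(row["gene"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    mclass=str(row["class"]),
                    vaf=vaf,
                    fwd_alt_reads=int(row["fwd_alt_reads"]),
                    rev_alt_reads=int(row["rev_alt_reads"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {i}: {exc}") from exc
    log.info("read %d mutation records from %s", len(records), path)
    return records


# ---------------------------------------------------------------------------
# methylation matrix
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, annot_path: str | Path | None = None):
    from .methylation import MethylationMatrix

    beta = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    vals = beta.values
    if np.any((vals < 0) | (vals > 1)):
        bad = np.argwhere((vals < 0) | (vals > 1))[0]
        raise FormatError(
            f"beta value {vals[tuple(bad)]} at probe {beta.index[bad[0]]} outside [0, 1]"
        )
    annot = pd.read_csv(annot_path, sep="\t", index_col=0) if annot_path else None
    return MethylationMatrix(beta=beta, probe_annot=annot)


# ---------------------------------------------------------------------------
# SEG (1-based inclusive on disk)
# ---------------------------------------------------------------------------

SEG_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "nprobes",
    "segmean",
    "mean_raw_r",
    "mean_adjusted_cn",
    "call",
]


def write_seg(
    segments: dict[str, list[CNSegment]] | list[CNSegment],
    path: str | Path,
    sample: str = "NA",
    log_floor: float = 0.01,
) -> None:
    if isinstance(segments, list):
        segments = {sample: segments}
    rows = []
    for s, segs in segments.items():
        for seg in segs:
            rows.append(
                {
                    "sample": s,
                    "chrom": seg.chrom,
                    "start": seg.start + 1,  # SEG is 1-based inclusive
                    "end": seg.end,
                    "nprobes": seg.n_probes,
                    "segmean": float(
                        np.log2(max(seg.mean_adjusted_cn, log_floor))
                    ),
                    "mean_raw_r": seg.mean_raw_r,
                    "mean_adjusted_cn": seg.mean_adjusted_cn,
                    "call": seg.call,
                }
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> dict[str, list[CNSegment]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in SEG_COLUMNS[:6]:
        if col not in df.columns:
            raise FormatError(f"SEG file missing column {col!r}")
    out: dict[str, list[CNSegment]] = {}
    for row in df.itertuples(index=False):
        seg = CNSegment(
            chrom=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            n_probes=int(row.nprobes),
            mean_raw_r=float(getattr(row, "mean_raw_r", np.nan)),
            mean_adjusted_cn=float(
                getattr(row, "mean_adjusted_cn", 2.0 ** row.segmean)
            ),
            call=str(getattr(row, "call", "neutral")),
        )
        out.setdefault(str(row.sample), []).append(seg)
    return out


# ---------------------------------------------------------------------------
# gene models (BED12 + FASTA)
# ---------------------------------------------------------------------------

def write_gene_models(
    models: list[GeneModel], bed_path: str | Path, fasta_path: str | Path
) -> None:
    with open(bed_path, "w") as bed:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            thick_s = g.cds[0][0] if g.cds else g.start
            thick_e = g.cds[-1][1] if g.cds else g.start
            bed.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            g.start,
                            g.end,
                            g.gene,
                            0,
                            g.strand,
                            thick_s,
                            thick_e,
                            "0",
                            len(g.exons),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )
    SeqIO.write(
        [SeqRecord(Seq(g.seq), id=g.gene, description="") for g in models if g.seq],
        str(fasta_path),
        "fasta",
    )


def read_gene_models(
    bed_path: str | Path, fasta_path: str | Path | None = None
) -> list[GeneModel]:
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    models = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{bed_path} line {ln}: expected BED12")
            chrom, start, end, name, _, strand = parts[:6]
            start, end = int(start), int(end)
            thick_s, thick_e = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offs = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offs) != n_blocks:
                raise FormatError(f"{bed_path} line {ln}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            cds = []
            for s, e in exons:
                cs, ce = max(s, thick_s), min(e, thick_e)
                if cs < ce:
                    cds.append((cs, ce))
            seq = seqs.get(name, "")
            try:
                g = GeneModel(
                    gene=name, chrom=chrom, exons=exons, cds=cds, strand=strand,
                    seq=seq,
                )
            except ValueError as exc:
                raise FormatError(f"{bed_path} line {ln}: {exc}") from exc
            models.append(g)
    return models


# ---------------------------------------------------------------------------
# depth profiles and alignment pairs
# ---------------------------------------------------------------------------

def write_depth_profiles(profiles: dict[str, DepthProfile], path: str | Path) -> None:
    frames = []
    for sample, prof in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "chrom": prof.chrom,
                    "pos": prof.positions,
                    "tumor_depth": prof.tumor,
                    "normal_depth": prof.normal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_profiles(path: str | Path) -> dict[str, DepthProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = {}
    for sample, sub in df.groupby("sample", sort=False):
        out[str(sample)] = DepthProfile(
            chrom=str(sub["chrom"].iloc[0]),
            positions=sub["pos"].to_numpy(),
            tumor=sub["tumor_depth"].to_numpy(dtype=float),
            normal=sub["normal_depth"].to_numpy(dtype=float),
        )
    return out


PAIR_COLUMNS = [
    "pair_id",
    "gene1", "pos1", "strand1", "mismatches1", "length1", "unique1", "seq1",
    "gene2", "pos2", "strand2", "mismatches2", "length2", "unique2", "seq2",
]


def write_pairs(pairs: list[PairedEndAlignment], path: str | Path) -> None:
    rows = []
    for p in pairs:
        row = {"pair_id": p.pair_id}
        for i, e in enumerate(p.ends, start=1):
            row.update(
                {
                    f"gene{i}": e.gene,
                    f"pos{i}": e.pos,
                    f"strand{i}": e.strand,
                    f"mismatches{i}": e.mismatches,
                    f"length{i}": e.length,
                    f"unique{i}": int(e.unique),
                    f"seq{i}": e.seq,
                }
            )
        rows.append(row)
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[PairedEndAlignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in PAIR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"pairs table missing column {col!r}")
    pairs = []
    for row in df.itertuples(index=False):
        ends = []
        for i in (1, 2):
            ends.append(
                AlignedEnd(
                    gene=str(getattr(row, f"gene{i}")),
                    pos=int(getattr(row, f"pos{i}")),
                    strand=str(getattr(row, f"strand{i}")),
                    mismatches=int(getattr(row, f"mismatches{i}")),
                    length=int(getattr(row, f"length{i}")),
                    unique=bool(int(getattr(row, f"unique{i}"))),
                    seq=str(getattr(row, f"seq{i}")),
                )
            )
        pairs.append(PairedEndAlignment(str(row.pair_id), ends[0], ends[1]))
    return pairs


# ---------------------------------------------------------------------------
# expression / clinical
# ---------------------------------------------------------------------------

def read_expression_counts(path: str | Path):
    """expr_counts.tsv: gene, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise FormatError("expression table missing column 'length'")
    lengths = df["length"].astype(float)
    counts = df.drop(columns=["length"]).astype(float)
    return counts, lengths


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}")
    if (df["time"] < 0).any():
        raise FormatError("negative survival time")
    return df
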