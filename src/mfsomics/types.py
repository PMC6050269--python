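"""Core domain types shared across the pipeline stages.

Coordinates are 0-based half-open throughout; one linear pseudo-chromosome
coordinate system is used by the simulator, but nothing below assumes it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_indel",
    "inframe_indel",
    "read_through",
    "silent",
)

#: classes expected to truncate the protein product
TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift_indel", "splice_site"})

#: classes counted as non-silent in burden and driver analyses
NON_SILENT_CLASSES = frozenset(MUTATION_CLASSES) - {"silent"}


class FormatError(ValueError):
    """Raised when an on-disk table violates its declared format."""


@dataclass
class MutationRecord:
    """One somatic call: sample, gene, locus, class, VAF and strand evidence."""

    sample: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mclass: str
    vaf: float
    fwd_alt_reads: int
    rev_alt_reads: int

    def __post_init__(self) -> None:
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.fwd_alt_reads < 0 or self.rev_alt_reads < 0:
            raise ValueError("negative strand read counts")

    @property
    def is_truncating(self) -> bool:
        return self.mclass in TRUNCATING_CLASSES

    @property
    def is_non_silent(self) -> bool:
        return self.mclass != "silent"


def _check_intervals(ivals: list[tuple[int, int]], label: str) -> None:
    prev_end = -1
    for start, end in ivals:
        if start >= end:
            raise ValueError(f"{label} interval ({start}, {end}) is empty or inverted")
        if start < prev_end:
            raise ValueError(f"{label} intervals overlap or are unsorted")
        prev_end = end


@dataclass
class GeneModel:
    """A transcript model: exon/CDS intervals on a chromosome plus sequence.

    ``seq`` is the spliced transcript sequence (exons concatenated, given in
    the genomic orientation of a + strand gene; the simulator only emits +
    strand models, but coordinate conversion honours the intervals).
    """

    gene: str
    chrom: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    strand: str = "+"
    seq: str = ""

    def __post_init__(self) -> None:
        _check_intervals(self.exons, "exon")
        if self.cds:
            _check_intervals(self.cds, "CDS")
            if self.cds_length % 3 != 0:
                raise ValueError(
                    f"{self.gene}: CDS length {self.cds_length} not divisible by 3"
                )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.seq and len(self.seq) != self.transcript_length:
            raise ValueError(
                f"{self.gene}: sequence length {len(self.seq)} != spliced "
                f"exon length {self.transcript_length}"
            )

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def to_transcript_pos(self, gpos: int) -> int:
        """Map a genomic position inside an exon to transcript coordinates."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        raise ValueError(f"{self.gene}: genomic position {gpos} not exonic")

    def cds_transcript_span(self) -> tuple[int, int]:
        """(start, end) of the CDS in transcript coordinates, half-open."""
        if not self.cds:
            raise ValueError(f"{self.gene} has no CDS")
        t0 = self.to_transcript_pos(self.cds[0][0])
        return t0, t0 + self.cds_length

    def cds_positions(self) -> list[int]:
        """All genomic positions covered by the CDS (sorted)."""
        out: list[int] = []
        for s, e in self.cds:
            out.extend(range(s, e))
        return out


@dataclass
class CNSegment:
    """A contiguous copy-number segment with raw-ratio and adjusted-CN means."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_raw_r: float
    mean_adjusted_cn: float
    call: str = "neutral"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty segment")
        if self.call not in {"neutral", "AMP", "HD", "HD_filtered"}:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class SurvivalRecord:
    sample: str
    time: float
    event: int
    endpoint: str = "overall"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("negative survival time")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0/1")


@dataclass
class AlignedEnd:
    """One end of a paired-end RNA alignment, in transcript coordinates."""

    gene: str
    pos: int
    strand: str
    mismatches: int
    length: int
    unique: bool = True
    seq: str = ""
    short_flag: bool = False

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class PairedEndAlignment:
    pair_id: str
    end1: AlignedEnd
    end2: AlignedEnd

    @property
    def ends(self) -> tuple[AlignedEnd, AlignedEnd]:
        return self.end1, self.end2
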