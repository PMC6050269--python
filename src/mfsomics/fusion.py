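"""Fusion-transcript detection from paired-end RNA alignments.

The caller groups discordant read ends into forward and reverse clusters
per gene (single-linkage chaining, 300-bp neighbour gap, 1000-bp maximum
span), pairs a forward cluster in one gene with a reverse cluster in
another when at least one read pair links them, and then filters:

* perfect-match filter — at least one supporting pair with zero mismatches
  on both ends;
* realignment-artifact filter — candidates whose supporting pairs can be
  explained by a single transcript (both ends realign with proper spacing
  and orientation, e.g. across paralog-like duplicated sequence) are
  removed;
* support thresholds — two or more pairs for in-frame candidates, three or
  more otherwise.

Read ends carry transcript coordinates and reference-oriented sequences.
100-bp ends are cropped to their 5'-most 50 bases before clustering, since
shorter ends leave a longer spacer across the junction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Align import PairwiseAligner

from .types import AlignedEnd, GeneModel, PairedEndAlignment

CLUSTER_GAP_MAX = 300      # inclusive: ends <= 300 bp apart co-cluster
CLUSTER_SPAN_MAX = 1000    # clusters spanning > 1000 bp are discarded
MAX_MISMATCHES = 2         # inclusive per-end mismatch ceiling
CROP_LENGTH = 50
MIN_SUPPORT_IN_FRAME = 2
MIN_SUPPORT_OTHER = 3
DEFAULT_INSERT_MAX = 500   # "proper spacing" window for the artifact filter

log = logging.getLogger(__name__)


@dataclass
class ReadCluster:
    gene: str
    direction: str                      # "forward" | "reverse"
    positions: list[int]
    pair_ids: list[str]

    @property
    def leftmost(self) -> int:
        return self.positions[0]

    @property
    def rightmost(self) -> int:
        return self.positions[-1]

    @property
    def span(self) -> int:
        return self.rightmost - self.leftmost


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    forward_cluster: ReadCluster
    reverse_cluster: ReadCluster
    pairs: list[PairedEndAlignment]
    frame: str = "undetermined"
    artifact_flag: bool = False
    breakpoint5: int | None = None
    breakpoint3: int | None = None

    @property
    def n_support(self) -> int:
        return len(self.pairs)

    @property
    def n_perfect(self) -> int:
        return sum(
            1 for p in self.pairs if p.end1.mismatches == 0 and p.end2.mismatches == 0
        )

    @property
    def has_perfect_pair(self) -> bool:
        return self.n_perfect > 0


# ---------------------------------------------------------------------------
# read preparation
# ---------------------------------------------------------------------------

def _crop_end(end: AlignedEnd, crop: int) -> AlignedEnd:
    if end.length <= crop:
        return replace(end, short_flag=end.length < crop)
    if end.strand == "+":
        # 5'-most bases are the low-coordinate half
        return replace(end, length=crop, seq=end.seq[:crop] if end.seq else "")
    # minus strand: 5'-most bases sit at the high-coordinate end
    shift = end.length - crop
    return replace(
        end,
        pos=end.pos + shift,
        length=crop,
        seq=end.seq[shift:] if end.seq else "",
    )


def crop_pairs_to_50bp(
    pairs: list[PairedEndAlignment], crop: int = CROP_LENGTH
) -> list[PairedEndAlignment]:
    """Truncate each end to its 5'-most ``crop`` bases, updating coordinates."""
    return [
        PairedEndAlignment(p.pair_id, _crop_end(p.end1, crop), _crop_end(p.end2, crop))
        for p in pairs
    ]


def select_candidate_pairs(
    pairs: list[PairedEndAlignment], max_mismatches: int = MAX_MISMATCHES
) -> list[PairedEndAlignment]:
    """Keep uniquely mapped inter-gene pairs with <= 2 mismatches per end."""
    kept = [
        p
        for p in pairs
        if p.end1.gene != p.end2.gene
        and p.end1.unique
        and p.end2.unique
        and p.end1.mismatches <= max_mismatches
        and p.end2.mismatches <= max_mismatches
    ]
    log.info("select_candidate_pairs: %d in, %d out", len(pairs), len(kept))
    return kept


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def build_clusters(
    read_ends: list[tuple[str, AlignedEnd]],
    gap_max: int = CLUSTER_GAP_MAX,
    span_max: int = CLUSTER_SPAN_MAX,
) -> list[ReadCluster]:
    """Single-linkage chaining of read ends into clusters per gene/direction.

    Neighbouring ends at most ``gap_max`` apart (inclusive) join one
    cluster; chained clusters whose left-to-rightmost span exceeds
    ``span_max`` are discarded.
    """
    groups: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for pair_id, end in read_ends:
        direction = "forward" if end.strand == "+" else "reverse"
        groups.setdefault((end.gene, direction), []).append((end.pos, pair_id))
    clusters: list[ReadCluster] = []
    for (gene, direction), members in groups.items():
        members.sort()
        run: list[tuple[int, str]] = [members[0]]
        for item in members[1:]:
            if item[0] - run[-1][0] <= gap_max:
                run.append(item)
            else:
                clusters.append(_finish(gene, direction, run, span_max))
                run = [item]
        clusters.append(_finish(gene, direction, run, span_max))
    return [c for c in clusters if c is not None]


def _finish(gene, direction, run, span_max) -> ReadCluster | None:
    if run[-1][0] - run[0][0] > span_max:
        return None
    return ReadCluster(
        gene=gene,
        direction=direction,
        positions=[p for p, _ in run],
        pair_ids=[i for _, i in run],
    )


def pair_clusters(
    forward_clusters: list[ReadCluster],
    reverse_clusters: list[ReadCluster],
    pairs: list[PairedEndAlignment],
) -> list[FusionCandidate]:
    """Link forward and reverse clusters that share at least one read pair."""
    fwd_of: dict[tuple[str, str], ReadCluster] = {}
    for c in forward_clusters:
        for pid in c.pair_ids:
            fwd_of[(pid, c.gene)] = c
    rev_of: dict[tuple[str, str], ReadCluster] = {}
    for c in reverse_clusters:
        for pid in c.pair_ids:
            rev_of[(pid, c.gene)] = c
    grouped: dict[tuple[int, int], FusionCandidate] = {}
    for p in pairs:
        fe, re_ = (
            (p.end1, p.end2) if p.end1.strand == "+" else (p.end2, p.end1)
        )
        if fe.strand != "+" or re_.strand != "-":
            continue
        fc = fwd_of.get((p.pair_id, fe.gene))
        rc = rev_of.get((p.pair_id, re_.gene))
        if fc is None or rc is None:
            continue
        key = (id(fc), id(rc))
        if key not in grouped:
            grouped[key] = FusionCandidate(
                gene5=fc.gene,
                gene3=rc.gene,
                forward_cluster=fc,
                reverse_cluster=rc,
                pairs=[],
            )
        grouped[key].pairs.append(p)
    out = list(grouped.values())
    out.sort(key=lambda c: (c.gene5, c.gene3, c.forward_cluster.leftmost))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def perfect_match_filter(candidates: list[FusionCandidate]) -> list[FusionCandidate]:
    """Keep candidates with >= 1 pair perfectly matched on both ends."""
    kept = [c for c in candidates if c.has_perfect_pair]
    log.info("perfect_match_filter: %d in, %d out", len(candidates), len(kept))
    return kept


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _best_local(aligner, seq: str, ref: str):
    """(score, ref_start, ref_end) of the best local alignment, or None."""
    if not seq or not ref:
        return None
    aln = aligner.align(ref, seq)
    if len(aln) == 0:
        return None
    best = aln[0]
    start = int(best.aligned[0][0][0])
    end = int(best.aligned[0][-1][1])
    return float(best.score), start, end


def realignment_artifact_filter(
    candidates: list[FusionCandidate],
    transcriptome: dict[str, str],
    insert_max: int = DEFAULT_INSERT_MAX,
    min_score_fraction: float = 0.6,
) -> list[FusionCandidate]:
    """Remove candidates explainable by a single transcript.

    For every supporting pair, both end sequences are locally realigned
    against each partner transcript with a permissive score cutoff
    (``min_score_fraction`` of the maximum attainable score, so ends with
    lowered similarity, e.g. across paralog duplications carrying nucleotide
    variations, still align).  If both ends of any pair align to one
    transcript with proper spacing (forward end upstream, fragment span
    within ``insert_max``) and orientation, the candidate is flagged as an
    artifact and removed.
    """
    aligner = _make_aligner()
    kept = []
    for cand in candidates:
        refs = []
        for g in (cand.gene5, cand.gene3):
            if g in transcriptome:
                refs.append(transcriptome[g])
            else:
                log.warning("no transcript for %s; candidate kept unchecked", g)
        artifact = False
        for p in cand.pairs:
            fe, re_ = (p.end1, p.end2) if p.end1.strand == "+" else (p.end2, p.end1)
            if not fe.seq or not re_.seq:
                continue
            for ref in refs:
                a1 = _best_local(aligner, fe.seq, ref)
                a2 = _best_local(aligner, re_.seq, ref)
                if a1 is None or a2 is None:
                    continue
                ok1 = a1[0] >= min_score_fraction * 2 * len(fe.seq)
                ok2 = a2[0] >= min_score_fraction * 2 * len(re_.seq)
                if not (ok1 and ok2):
                    continue
                span = a2[2] - a1[1]  # fragment: fwd start to rev end
                if 0 < span <= insert_max and a1[1] <= a2[1]:
                    artifact = True
                    break
            if artifact:
                break
        cand.artifact_flag = artifact
        if not artifact:
            kept.append(cand)
    log.info("realignment_artifact_filter: %d in, %d out", len(candidates), len(kept))
    return kept


# ---------------------------------------------------------------------------
# frame annotation and final calling
# ---------------------------------------------------------------------------

def frame_from_offsets(offset5: int, offset3: int) -> str:
    """In-frame iff the 5' codon-phase surplus plus the 3' bases-to-next-codon
    sum to a multiple of three."""
    return "in-frame" if (offset5 + offset3) % 3 == 0 else "out-of-frame"


def annotate_frame(
    candidate: FusionCandidate, gene_models: dict[str, GeneModel]
) -> str:
    """Infer breakpoints from cluster edges and classify the reading frame.

    The 5' breakpoint is the forward cluster's rightmost end position and
    the 3' breakpoint the reverse cluster's leftmost; both are transcript
    coordinates.  offset5 is the codon phase at the 5' breakpoint, offset3
    the distance from the 3' breakpoint to the next codon boundary; the
    junction is in-frame when they cancel mod 3.  Breakpoints outside the
    CDS give "undetermined".
    """
    bp5 = candidate.forward_cluster.rightmost
    bp3 = candidate.reverse_cluster.leftmost
    candidate.breakpoint5, candidate.breakpoint3 = bp5, bp3
    g5 = gene_models.get(candidate.gene5)
    g3 = gene_models.get(candidate.gene3)
    if g5 is None or g3 is None or not g5.cds or not g3.cds:
        candidate.frame = "undetermined"
        return candidate.frame
    c5_start, c5_end = g5.cds_transcript_span()
    c3_start, c3_end = g3.cds_transcript_span()
    if not (c5_start <= bp5 < c5_end) or not (c3_start <= bp3 < c3_end):
        candidate.frame = "undetermined"
        return candidate.frame
    offset5 = (bp5 - c5_start) % 3
    offset3 = (3 - (bp3 - c3_start) % 3) % 3
    candidate.frame = frame_from_offsets(offset5, offset3)
    return candidate.frame


def call_fusions(
    candidates: list[FusionCandidate],
    min_support_in_frame: int = MIN_SUPPORT_IN_FRAME,
    min_support_other: int = MIN_SUPPORT_OTHER,
) -> list[FusionCandidate]:
    """Apply support thresholds and sort the final report."""
    final = [
        c
        for c in candidates
        if c.n_support
        >= (min_support_in_frame if c.frame == "in-frame" else min_support_other)
    ]
    final.sort(key=lambda c: (-c.n_support, c.gene5, c.gene3))
    return final


def detect_fusions(
    pairs: list[PairedEndAlignment],
    gene_models: dict[str, GeneModel],
    crop: int = CROP_LENGTH,
    insert_max: int = DEFAULT_INSERT_MAX,
) -> list[FusionCandidate]:
    """The full pipeline: crop, select, cluster, pair, filter, annotate, call."""
    cropped = crop_pairs_to_50bp(pairs, crop=crop)
    selected = select_candidate_pairs(cropped)
    ends = [(p.pair_id, e) for p in selected for e in p.ends]
    clusters = build_clusters(ends)
    fwd = [c for c in clusters if c.direction == "forward"]
    rev = [c for c in clusters if c.direction == "reverse"]
    candidates = pair_clusters(fwd, rev, selected)
    candidates = perfect_match_filter(candidates)
    transcriptome = {g.gene: g.seq for g in gene_models.values() if g.seq}
    candidates = realignment_artifact_filter(
        candidates, transcriptome, insert_max=insert_max
    )
    for c in candidates:
        annotate_frame(c, gene_models)
    return call_fusions(candidates)
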