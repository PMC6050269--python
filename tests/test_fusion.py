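"""Fusion caller: cropping arithmetic, cluster chaining rules, paired-cluster
construction, the three filters, frame annotation, and end-to-end recovery."""
import random

import pytest

from mfsomics import fusion
from mfsomics.synthdata import default_cohort_spec, generate_fusion_read_pairs
from mfsomics.types import AlignedEnd, GeneModel, PairedEndAlignment


def _end(gene="G1", pos=0, strand="+", mm=0, length=50, unique=True, seq=""):
    return AlignedEnd(gene, pos, strand, mm, length, unique, seq)


def _pair(pid, e1, e2):
    return PairedEndAlignment(pid, e1, e2)


class TestCrop:
    def test_plus_strand_anchor_unchanged(self):
        p = _pair("a", _end(pos=200, length=100), _end(gene="G2", pos=50,
                                                       strand="-", length=100))
        c = fusion.crop_pairs_to_50bp([p])[0]
        assert c.end1.pos == 200 and c.end1.length == 50

    def test_minus_strand_start_shifts(self):
        p = _pair("a", _end(pos=200, length=100),
                  _end(gene="G2", pos=50, strand="-", length=100))
        c = fusion.crop_pairs_to_50bp([p])[0]
        # 5'-most 50 bases of a minus-strand read sit at the high end
        assert c.end2.pos == 100 and c.end2.length == 50

    def test_sequence_cropped_consistently(self):
        seq = "A" * 60 + "C" * 40
        p = _pair("a", _end(pos=0, length=100, seq=seq),
                  _end(gene="G2", pos=0, strand="-", length=100, seq=seq))
        c = fusion.crop_pairs_to_50bp([p])[0]
        assert c.end1.seq == seq[:50]
        assert c.end2.seq == seq[50:]

    def test_fifty_bp_input_unchanged(self):
        p = _pair("a", _end(pos=10, length=50), _end(gene="G2", pos=5,
                                                     strand="-", length=50))
        c = fusion.crop_pairs_to_50bp([p])[0]
        assert c.end1 == p.end1 and c.end2 == p.end2

    def test_short_end_kept_with_flag(self):
        p = _pair("a", _end(pos=10, length=30), _end(gene="G2", pos=5,
                                                     strand="-", length=50))
        c = fusion.crop_pairs_to_50bp([p])[0]
        assert c.end1.length == 30 and c.end1.short_flag


class TestSelectCandidatePairs:
    def test_intra_gene_pair_dropped(self):
        p = _pair("a", _end(gene="G1"), _end(gene="G1", strand="-"))
        assert fusion.select_candidate_pairs([p]) == []

    def test_two_mismatches_inclusive(self):
        p = _pair("a", _end(gene="G1", mm=2), _end(gene="G2", strand="-", mm=2))
        assert fusion.select_candidate_pairs([p]) == [p]

    def test_three_mismatches_dropped(self):
        p = _pair("a", _end(gene="G1", mm=3), _end(gene="G2", strand="-", mm=0))
        assert fusion.select_candidate_pairs([p]) == []

    def test_non_unique_dropped(self):
        p = _pair("a", _end(gene="G1", unique=False), _end(gene="G2", strand="-"))
        assert fusion.select_candidate_pairs([p]) == []


class TestBuildClusters:
    def _ends(self, positions, gene="G1", strand="+"):
        return [(f"p{i}", _end(gene=gene, pos=p, strand=strand))
                for i, p in enumerate(positions)]

    def test_gap_300_joins(self):
        clusters = fusion.build_clusters(self._ends([100, 400]))
        assert len(clusters) == 1

    def test_gap_301_splits(self):
        clusters = fusion.build_clusters(self._ends([100, 401]))
        assert len(clusters) == 2

    def test_chained_overlong_cluster_discarded(self):
        clusters = fusion.build_clusters(self._ends([0, 300, 600, 900, 1200]))
        assert clusters == []

    def test_span_exactly_1000_kept(self):
        clusters = fusion.build_clusters(self._ends([0, 250, 500, 750, 1000]))
        assert len(clusters) == 1 and clusters[0].span == 1000

    def test_all_outputs_satisfy_invariants(self, rng):
        positions = sorted(int(x) for x in rng.integers(0, 10000, 200))
        for c in fusion.build_clusters(self._ends(positions)):
            assert c.span <= 1000
            gaps = [b - a for a, b in zip(c.positions, c.positions[1:])]
            assert all(g <= 300 for g in gaps)


class TestPairClusters:
    def _candidate_set(self, n_fusions):
        pairs = []
        for f in range(n_fusions):
            g5, g3 = f"A{f}", f"B{f}"
            for i in range(3):
                pairs.append(
                    _pair(f"{g5}_{i}", _end(gene=g5, pos=100 + 10 * i),
                          _end(gene=g3, pos=500 + 10 * i, strand="-"))
                )
        ends = [(p.pair_id, e) for p in pairs for e in p.ends]
        clusters = fusion.build_clusters(ends)
        fwd = [c for c in clusters if c.direction == "forward"]
        rev = [c for c in clusters if c.direction == "reverse"]
        return fusion.pair_clusters(fwd, rev, pairs)

    def test_single_planted_fusion_single_candidate(self):
        cands = self._candidate_set(1)
        assert len(cands) == 1 and cands[0].n_support == 3

    def test_no_pairs_empty_output(self):
        assert fusion.pair_clusters([], [], []) == []

    def test_two_fusions_two_disjoint_candidates(self):
        cands = self._candidate_set(2)
        assert len(cands) == 2
        assert {(c.gene5, c.gene3) for c in cands} == {("A0", "B0"), ("A1", "B1")}


class TestPerfectMatchFilter:
    def _cand(self, mismatch_pairs):
        pairs = [
            _pair(f"p{i}", _end(mm=a), _end(gene="G2", strand="-", mm=b))
            for i, (a, b) in enumerate(mismatch_pairs)
        ]
        cluster = fusion.ReadCluster("G1", "forward", [0], ["p0"])
        rcluster = fusion.ReadCluster("G2", "reverse", [0], ["p0"])
        return fusion.FusionCandidate("G1", "G2", cluster, rcluster, pairs)

    def test_no_perfect_pair_dropped(self):
        assert fusion.perfect_match_filter([self._cand([(1, 0), (2, 2)])]) == []

    def test_one_perfect_among_many_kept(self):
        c = self._cand([(1, 1), (0, 0), (2, 0)])
        assert fusion.perfect_match_filter([c]) == [c]

    def test_half_perfect_pair_not_enough(self):
        assert fusion.perfect_match_filter([self._cand([(0, 1)])]) == []


class TestRealignmentFilter:
    def test_decoy_candidates_removed_true_fusion_kept(self, spec0):
        pairs = generate_fusion_read_pairs(spec0)
        genes = {g.gene: g for g in spec0.gene_models}
        calls = fusion.detect_fusions(pairs, genes)
        assert len(calls) == 1
        c = calls[0]
        assert (c.gene5, c.gene3) == ("G0005", "G0010")
        assert not c.artifact_flag

    def test_distant_realignment_is_proper_spacing_violation(self):
        # both ends realign to one long transcript but 10 kb apart: kept
        rng = random.Random(0)
        ref = "".join(rng.choice("ACGT") for _ in range(11000))
        s1, s2 = ref[100:150], ref[10400:10450]
        g1 = GeneModel("L1", "chr1", [(0, 11000)], [], seq=ref)
        g2 = GeneModel("L2", "chr1", [(0, 50)], [], seq=s2)
        p = _pair("a", _end(gene="L1", pos=100, seq=s1),
                  _end(gene="L2", pos=0, strand="-", seq=s2))
        fc = fusion.ReadCluster("L1", "forward", [100], ["a"])
        rc = fusion.ReadCluster("L2", "reverse", [0], ["a"])
        cand = fusion.FusionCandidate("L1", "L2", fc, rc, [p])
        kept = fusion.realignment_artifact_filter(
            [cand], {"L1": ref, "L2": s2}
        )
        assert kept == [cand] and not cand.artifact_flag

    def test_shared_context_with_proper_spacing_removed(self):
        rng = random.Random(1)
        ref = "".join(rng.choice("ACGT") for _ in range(1000))
        s1, s2 = ref[100:150], ref[300:350]
        p = _pair("a", _end(gene="X1", pos=100, seq=s1),
                  _end(gene="X2", pos=0, strand="-", seq=s2))
        fc = fusion.ReadCluster("X1", "forward", [100], ["a"])
        rc = fusion.ReadCluster("X2", "reverse", [0], ["a"])
        cand = fusion.FusionCandidate("X1", "X2", fc, rc, [p])
        kept = fusion.realignment_artifact_filter([cand], {"X1": ref, "X2": s2})
        assert kept == [] and cand.artifact_flag


class TestFrameAnnotation:
    def _models(self):
        # CDS spans [300, 1800) in transcript coordinates of a 2400-bp gene
        from mfsomics.synthdata import make_gene_models

        models = make_gene_models(2, seed=0)
        return {g.gene: g for g in models}

    def _cand(self, bp5, bp3):
        fc = fusion.ReadCluster("G0001", "forward", [bp5], ["a"])
        rc = fusion.ReadCluster("G0002", "reverse", [bp3], ["a"])
        return fusion.FusionCandidate("G0001", "G0002", fc, rc, [])

    def test_codon_boundaries_in_frame(self):
        cand = self._cand(300 + 300, 300 + 600)  # both at codon starts
        assert fusion.annotate_frame(cand, self._models()) == "in-frame"

    def test_offset_sum_two_out_of_frame(self):
        assert fusion.frame_from_offsets(1, 1) == "out-of-frame"
        cand = self._cand(300 + 301, 300 + 602)  # phase 1 donor, phase 2 acceptor
        assert fusion.annotate_frame(cand, self._models()) == "out-of-frame"

    def test_equal_phase_in_frame(self):
        cand = self._cand(300 + 301, 300 + 601)
        assert fusion.annotate_frame(cand, self._models()) == "in-frame"

    def test_utr_breakpoint_undetermined(self):
        cand = self._cand(100, 900)
        assert fusion.annotate_frame(cand, self._models()) == "undetermined"


class TestCallFusions:
    def _cand(self, n, frame):
        pairs = [
            _pair(f"p{i}", _end(), _end(gene="G2", strand="-")) for i in range(n)
        ]
        fc = fusion.ReadCluster("G1", "forward", [0], ["p0"])
        rc = fusion.ReadCluster("G2", "reverse", [0], ["p0"])
        c = fusion.FusionCandidate("G1", "G2", fc, rc, pairs)
        c.frame = frame
        return c

    @pytest.mark.parametrize(
        "n,frame,reported",
        [
            (2, "in-frame", True),
            (1, "in-frame", False),
            (3, "out-of-frame", True),
            (2, "out-of-frame", False),
            (3, "undetermined", True),
        ],
    )
    def test_support_thresholds(self, n, frame, reported):
        assert bool(fusion.call_fusions([self._cand(n, frame)])) is reported


class TestEndToEnd:
    def test_planted_fusion_recovered_with_exact_support(self):
        for seed in range(3):
            spec = default_cohort_spec(seed=seed)
            pairs = generate_fusion_read_pairs(spec)
            genes = {g.gene: g for g in spec.gene_models}
            calls = fusion.detect_fusions(pairs, genes)
            assert len(calls) == 1
            c = calls[0]
            assert (c.gene5, c.gene3) == ("G0005", "G0010")
            assert c.n_support == spec.fusion_spec.n_support_pairs
            assert c.frame == "in-frame"

    def test_invariant_to_pair_order(self, spec0):
        pairs = generate_fusion_read_pairs(spec0)
        genes = {g.gene: g for g in spec0.gene_models}
        ref = fusion.detect_fusions(pairs, genes)
        shuffled = pairs.copy()
        random.Random(99).shuffle(shuffled)
        out = fusion.detect_fusions(shuffled, genes)
        assert [(c.gene5, c.gene3, c.n_support, c.frame) for c in ref] == [
            (c.gene5, c.gene3, c.n_support, c.frame) for c in out
        ]
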