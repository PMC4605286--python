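"""Fusion candidate detection: structural conditions, ambiguity and strand
filters, gene labeling, grouping — with brute-force oracle equivalence."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longfuse.annotation import AnnotationIndex
from longfuse.candidates import (
    assign_gene_labels,
    detect_candidates,
    enumerate_candidate_pairs,
    group_candidates_to_fusion_genes,
    identity_difference_filter,
    strand_consistency_filter,
)
from longfuse.model import DetectionConfig, FusionCandidate, GeneModel, GenomeInterval

from conftest import make_fragment, make_read

CFG = DetectionConfig()


def gene(name, chrom, start, end, strand="+", exons=None, iso="t1"):
    return GeneModel(
        gene_name=name,
        isoform_name=f"{name}.{iso}",
        interval=GenomeInterval(chrom, start, end, strand),
        exons=exons or [(start, end)],
        source="test",
    )


class TestStructuralConditions:
    def test_interchromosomal_pair_passes_all(self):
        aln = make_read([
            make_fragment(read_start=0, read_end=150, chrom="chr1"),
            make_fragment(read_start=160, read_end=320, chrom="chr2", g_start=5000, g_end=6000),
        ])
        (cand,) = enumerate_candidate_pairs(aln, CFG)
        assert cand.flags.all_pass()

    def test_fragment_of_exactly_threshold_length_fails(self):
        # condition (i) is strict: > 100 bp
        aln = make_read([
            make_fragment(read_start=0, read_end=95, chrom="chr1"),
            make_fragment(read_start=100, read_end=300, chrom="chr2"),
        ])
        assert enumerate_candidate_pairs(aln, CFG) == []
        aln100 = make_read([
            make_fragment(read_start=0, read_end=100, chrom="chr1"),
            make_fragment(read_start=100, read_end=300, chrom="chr2"),
        ])
        assert enumerate_candidate_pairs(aln100, CFG) == []
        aln101 = make_read([
            make_fragment(read_start=0, read_end=101, chrom="chr1"),
            make_fragment(read_start=101, read_end=300, chrom="chr2"),
        ])
        assert len(enumerate_candidate_pairs(aln101, CFG)) == 1

    def test_same_chromosome_close_pair_rejected_without_annotation(self):
        aln = make_read([
            make_fragment(read_start=0, read_end=150, g_start=10_000, g_end=11_000),
            make_fragment(read_start=160, read_end=320, g_start=61_000, g_end=62_000),  # 50 kb gap
        ])
        assert enumerate_candidate_pairs(aln, CFG) == []

    def test_same_chromosome_two_annotated_genes_overrides_distance(self):
        ann = AnnotationIndex([
            gene("A", "chr1", 9_000, 12_000),
            gene("B", "chr1", 60_000, 63_000),
        ])
        aln = make_read([
            make_fragment(read_start=0, read_end=150, g_start=10_000, g_end=11_000),
            make_fragment(read_start=160, read_end=320, g_start=61_000, g_end=62_000),
        ])
        assert len(enumerate_candidate_pairs(aln, CFG, ann)) == 1

    def test_read_span_overlap_above_threshold_rejected(self):
        aln = make_read([
            make_fragment(read_start=0, read_end=200, chrom="chr1"),
            make_fragment(read_start=90, read_end=300, chrom="chr2"),  # overlap 110
        ])
        assert enumerate_candidate_pairs(aln, CFG) == []

    def test_unaligned_gap_above_threshold_rejected(self):
        aln = make_read([
            make_fragment(read_start=0, read_end=150, chrom="chr1"),
            make_fragment(read_start=260, read_end=400, chrom="chr2"),  # gap 110
        ])
        assert enumerate_candidate_pairs(aln, CFG) == []


class TestIdentityDifferenceFilter:
    def pair(self):
        left = make_fragment(read_start=0, read_end=150, chrom="chr1", identity=0.95)
        right = make_fragment(read_start=160, read_end=320, chrom="chr2", identity=0.95)
        return FusionCandidate(read_id="r1", left=left, right=right)

    def test_large_gap_passes(self):
        cand = self.pair()
        alts = {
            id(cand.left): [make_fragment(identity=0.70, rank=1)],
            id(cand.right): [make_fragment(identity=0.70, rank=1)],
        }
        assert identity_difference_filter(cand, alts, CFG)

    def test_small_gap_on_one_fragment_fails(self):
        cand = self.pair()
        alts = {id(cand.left): [make_fragment(identity=0.80, rank=1)]}
        assert not identity_difference_filter(cand, alts, CFG)
        assert not cand.flags.identity_diff_ok

    def test_unique_alignment_passes(self):
        cand = self.pair()
        assert identity_difference_filter(cand, {}, CFG)


class TestStrandConsistency:
    """The right fragment overlaps an annotated gene; the left fragment has a
    canonical splice on '+'.  Of the four (gene strand, alignment
    orientation) combinations, only the co-directional ones pass."""

    @pytest.fixture
    def spliced_genome(self):
        # chr1 with a GT..AG intron at [10100, 10200) supporting '+' strand
        seq1 = list("A" * 20_000)
        seq1[10_100:10_102] = "GT"
        seq1[10_198:10_200] = "AG"
        return {"chr1": "".join(seq1), "chr2": "C" * 20_000}

    @pytest.mark.parametrize("gene_strand,orientation,should_pass", [
        ("+", "+", True),
        ("-", "-", True),
        ("-", "+", False),
        ("+", "-", False),
    ])
    def test_four_combinations(self, spliced_genome, gene_strand, orientation, should_pass):
        left = make_fragment(
            read_start=0, read_end=250, chrom="chr1", g_start=10_000, g_end=10_400,
            gaps=[(10_099, 10_200)],
        )
        right = make_fragment(
            read_start=260, read_end=500, chrom="chr2", g_start=5_000, g_end=6_000,
            strand=orientation,
        )
        ann = AnnotationIndex([gene("G3", "chr2", 4_000, 7_000, strand=gene_strand)])
        cand = FusionCandidate(read_id="r1", left=left, right=right)
        assert strand_consistency_filter(cand, ann, spliced_genome) == should_pass

    def test_both_unknown_passes_with_unknown_strand(self):
        cand = FusionCandidate(
            read_id="r1",
            left=make_fragment(read_start=0, read_end=150, chrom="chr1"),
            right=make_fragment(read_start=160, read_end=320, chrom="chr2"),
        )
        assert strand_consistency_filter(cand, None, None)
        assert not cand.swapped

    def test_both_reverse_passes_and_swaps_roles(self, spliced_genome):
        # left fragment has CT..AC motifs (transcript on '-') but aligns '+':
        # the read is the reverse complement of the transcript
        seq1 = list(spliced_genome["chr1"])
        seq1[10_100:10_102] = "CT"
        seq1[10_198:10_200] = "AC"
        genome = {"chr1": "".join(seq1), "chr2": spliced_genome["chr2"]}
        left = make_fragment(read_start=0, read_end=250, chrom="chr1",
                             g_start=10_000, g_end=10_400, gaps=[(10_099, 10_200)])
        right = make_fragment(read_start=260, read_end=500, chrom="chr2",
                              g_start=5_000, g_end=6_000, strand="+")
        ann = AnnotationIndex([gene("G3", "chr2", 4_000, 7_000, strand="-")])
        cand = FusionCandidate(read_id="r1", left=left, right=right)
        assert strand_consistency_filter(cand, ann, genome)
        assert cand.swapped
        assert cand.frag5 is right


class TestGeneLabels:
    def test_splice_matching_annotated_intron_wins(self):
        g = gene("G", "chr1", 9_000, 12_000, exons=[(9_000, 10_100), (10_200, 12_000)])
        ann = AnnotationIndex([g, gene("H", "chr1", 8_000, 13_000)])
        cand = FusionCandidate(
            read_id="r1",
            left=make_fragment(read_start=0, read_end=150, g_start=9_500, g_end=10_500,
                               gaps=[(10_099, 10_200)]),
            right=make_fragment(read_start=160, read_end=320, chrom="chr2"),
        )
        assign_gene_labels(cand, ann)
        assert cand.gene5_label == "G"

    def test_splice_free_fragment_labeled_by_overlap(self):
        ann = AnnotationIndex([gene("H", "chr1", 9_000, 12_000)])
        cand = FusionCandidate(
            read_id="r1",
            left=make_fragment(read_start=0, read_end=150),
            right=make_fragment(read_start=160, read_end=320, chrom="chr2"),
        )
        assign_gene_labels(cand, ann)
        assert cand.gene5_label == "H"

    def test_intergenic_fragment_gets_locus_label(self):
        cand = FusionCandidate(
            read_id="r1",
            left=make_fragment(read_start=0, read_end=150, chrom="chr1", g_start=107_078_406, g_end=107_079_000),
            right=make_fragment(read_start=160, read_end=320, chrom="chr2"),
        )
        assign_gene_labels(cand, None)
        assert cand.gene5_label == "chr1:107078407"


class TestGrouping:
    def cand(self, g5, g3, read_id="r"):
        c = FusionCandidate(
            read_id=read_id,
            left=make_fragment(read_id=read_id, read_start=0, read_end=150, chrom="chr1"),
            right=make_fragment(read_id=read_id, read_start=160, read_end=320, chrom="chr2"),
        )
        c.gene5_label, c.gene3_label = g5, g3
        return c

    def test_six_candidates_one_group(self):
        cands = [
            self.cand("AIB1", f"chr1:{107_078_407 + d}", read_id=f"r{i}")
            for i, d in enumerate((0, 10, -12, 30, 5, 2))
        ]
        (group,) = group_candidates_to_fusion_genes(cands)
        assert group.n_long_reads == 6

    def test_unordered_pair_grouping(self):
        groups = group_candidates_to_fusion_genes([self.cand("A", "B", "r1"), self.cand("B", "A", "r2")])
        assert len(groups) == 1

    def test_distant_locus_labels_stay_separate(self):
        groups = group_candidates_to_fusion_genes(
            [self.cand("A", "chr1:100000", "r1"), self.cand("A", "chr1:250000", "r2")]
        )
        assert len(groups) == 2


# ---------------------------------------------------------------------------
# oracle equivalence and properties
# ---------------------------------------------------------------------------

def brute_force_pairs(aln, cfg):
    """Literal re-statement of conditions (i)-(iv) over all read-ordered pairs."""
    frags = sorted(aln.fragments, key=lambda f: f.read_start)
    out = []
    for i in range(len(frags)):
        for j in range(len(frags)):
            if i >= j:
                continue
            a, b = frags[i], frags[j]
            if not (b.read_end - b.read_start > cfg.min_fragment_len
                    and a.read_end - a.read_start > cfg.min_fragment_len):
                continue
            if a.genome_span.chrom == b.genome_span.chrom:
                gap = max(a.genome_span.start, b.genome_span.start) - min(a.genome_span.end, b.genome_span.end)
                if gap < cfg.min_intrachrom_distance:
                    continue
            if min(a.read_end, b.read_end) - max(a.read_start, b.read_start) > cfg.max_fragment_overlap:
                continue
            if b.read_start - a.read_end > cfg.max_unaligned_gap:
                continue
            out.append((a.read_start, b.read_start))
    return sorted(out)


def random_alignment_set(r):
    n = int(r.integers(1, 7))
    frags = []
    cursor = 0
    for k in range(n):
        cursor += int(r.integers(-80, 180))
        cursor = max(cursor, 0)
        length = int(r.integers(20, 400))
        chrom = f"chr{int(r.integers(1, 4))}"
        g_start = int(r.integers(0, 2_000_000))
        frags.append(
            make_fragment(
                read_start=cursor, read_end=cursor + length, chrom=chrom,
                g_start=g_start, g_end=g_start + length,
            )
        )
        cursor += length
    return make_read(frags)


def test_enumerate_pairs_matches_brute_force_on_random_instances(rng):
    for _ in range(1000):
        aln = random_alignment_set(rng)
        got = sorted((c.left.read_start, c.right.read_start) for c in enumerate_candidate_pairs(aln, CFG))
        assert got == brute_force_pairs(aln, CFG)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(0, 400), st.integers(0, 300_000))
def test_tightening_thresholds_never_adds_candidates(seed, extra_len, extra_dist):
    r = np.random.default_rng(seed)
    aln = random_alignment_set(r)
    loose = DetectionConfig()
    tight = DetectionConfig(
        min_fragment_len=loose.min_fragment_len + extra_len,
        min_intrachrom_distance=loose.min_intrachrom_distance + extra_dist,
    )
    assert len(enumerate_candidate_pairs(aln, tight)) <= len(enumerate_candidate_pairs(aln, loose))


def test_filters_commute(rng, small_genome):
    """Structural, identity and strand filters select the same surviving set
    regardless of application order."""
    for _ in range(50):
        aln = random_alignment_set(rng)
        # attach a random alternative to a random fragment
        if aln.fragments and rng.random() < 0.5:
            i = int(rng.integers(0, len(aln.fragments)))
            aln.alternatives[i] = [make_fragment(identity=float(rng.uniform(0.5, 1.0)), rank=1)]
        pairs = enumerate_candidate_pairs(aln, CFG)
        surviving_a = [
            c for c in pairs
            if identity_difference_filter(c, aln, CFG) and strand_consistency_filter(c, None, small_genome)
        ]
        pairs2 = enumerate_candidate_pairs(aln, CFG)
        surviving_b = [
            c for c in pairs2
            if strand_consistency_filter(c, None, small_genome) and identity_difference_filter(c, aln, CFG)
        ]
        key = lambda cs: sorted((c.left.read_start, c.right.read_start) for c in cs)
        assert key(surviving_a) == key(surviving_b)
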