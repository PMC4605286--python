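"""Splice calling, linkage encoding/deduplication, end pooling, and isoform
enumeration against a brute-force subset oracle."""
from __future__ import annotations

from itertools import combinations

import pytest

from longfuse.annotation import AnnotationIndex
from longfuse.isoforms import (
    EndPool,
    Locus,
    build_boundaries,
    build_end_pool,
    call_splices,
    deduplicate_linkages,
    encode_linkage,
    enumerate_isoforms,
    is_polya_tail,
    validate_splices,
)
from longfuse.model import GeneModel, GenomeInterval, Splice

from conftest import make_fragment, make_read


def splice(donor, acceptor, chrom="chr1", strand="+"):
    return Splice(chrom=chrom, donor=donor, acceptor=acceptor, strand=strand)


class TestCallSplices:
    @pytest.mark.parametrize("gap,expected", [(68, 0), (69, 1), (200, 1)])
    def test_gap_threshold_is_strict(self, gap, expected):
        frag = make_fragment(gaps=[(10_099, 10_099 + gap + 1)])
        aln = make_read([frag])
        assert len(call_splices(aln)) == expected

    def test_cigar_style_gap(self):
        # 100M 200N 100M: one gap of 200
        frag = make_fragment(g_start=1_000, g_end=1_400, gaps=[(1_099, 1_300)])
        (sp,) = call_splices(make_read([frag]))
        assert sp.gap == 200


class TestValidateSplices:
    def setup_method(self):
        g = GeneModel(
            gene_name="G", isoform_name="G.t1",
            interval=GenomeInterval("chr1", 0, 1_000, "+"),
            exons=[(0, 100), (200, 1_000)], source="ref",
        )
        self.ann = AnnotationIndex([g])

    def test_annotated_intron_kept_without_short_reads(self):
        kept = validate_splices([splice(99, 200)], set(), self.ann)
        assert len(kept) == 1

    def test_novel_splice_with_short_read_support_kept(self):
        kept = validate_splices([splice(400, 600)], {("chr1", 400, 600)}, self.ann)
        assert len(kept) == 1

    def test_unsupported_novel_splice_dropped(self):
        assert validate_splices([splice(400, 600)], set(), self.ann) == []

    def test_exempt_fusion_splice_passes(self):
        kept = validate_splices([splice(400, 600)], set(), self.ann, exempt={("chr1", 400, 600)})
        assert len(kept) == 1


class TestBuildBoundaries:
    def test_two_splices_plus_annotated_isoform_gives_six(self):
        loc = Locus("chr1", 0, 2_000, "+")
        g = GeneModel(
            gene_name="G", isoform_name="G.t1",
            interval=GenomeInterval("chr1", 10, 1_990, "+"),
            exons=[(10, 1_990)], source="ref",
        )
        bs = build_boundaries(loc, [splice(99, 300), splice(499, 700)], AnnotationIndex([g]))
        assert bs == [10, 100, 300, 500, 700, 1_990]

    def test_duplicates_removed(self):
        loc = Locus("chr1", 0, 2_000, "+")
        bs = build_boundaries(loc, [splice(99, 300), splice(99, 300)], None)
        assert bs == [100, 300]

    def test_empty_locus(self):
        assert build_boundaries(Locus("chr1", 0, 100, "+"), [], None) == []


class TestEncodeLinkage:
    BOUNDS = {"chr1": [100, 300]}

    def test_read_through_both_boundaries_covers_all_markers(self):
        lk = encode_linkage([("chr1", 0, 400)], self.BOUNDS)
        assert lk.markers == frozenset(
            {("chr1", 100, "-"), ("chr1", 100, "+"), ("chr1", 300, "-"), ("chr1", 300, "+")}
        )

    def test_read_starting_exactly_at_boundary_covers_inner_marker_only(self):
        lk = encode_linkage([("chr1", 100, 200)], self.BOUNDS)
        assert ("chr1", 100, "+") in lk.markers
        assert ("chr1", 100, "-") not in lk.markers

    def test_read_splicing_at_boundary(self):
        # exon ends at 100 (splice donor 99), resumes at 300
        lk = encode_linkage([("chr1", 0, 100), ("chr1", 300, 400)], self.BOUNDS)
        assert lk.markers == frozenset({("chr1", 100, "-"), ("chr1", 300, "+")})

    def test_fusion_linkage_spans_two_loci(self):
        bounds = {"chr1": [100], "chr2": [500]}
        lk = encode_linkage(
            [("chr1", 0, 100), ("chr2", 500, 600)], bounds,
            is_fusion=True, fusion_splice=("chr1", 99, "chr2", 500),
        )
        assert lk.is_fusion
        assert {m[0] for m in lk.markers} == {"chr1", "chr2"}


class TestDeduplicateLinkages:
    B = {"chr1": [100, 300, 500]}

    def lk(self, blocks, read_id):
        return encode_linkage([("chr1", s, e) for s, e in blocks], self.B, read_id=read_id)

    def test_subset_removed(self):
        small = self.lk([(0, 100), (300, 400)], "r1")     # subset
        big = self.lk([(0, 100), (300, 400), (450, 550)], "r2")
        kept = deduplicate_linkages([small, big])
        assert len(kept) == 1
        assert kept[0].read_ids == {"r1", "r2"}

    def test_identical_merged(self):
        kept = deduplicate_linkages([self.lk([(0, 200)], "r1"), self.lk([(0, 200)], "r2")])
        assert len(kept) == 1 and kept[0].read_ids == {"r1", "r2"}

    def test_exon_skip_linkage_not_redundant_to_full_chain(self):
        """A read skipping an exon has a marker subset of the full-chain
        read but a different splice: both must survive."""
        bounds = {"chr1": [100, 200, 300, 400]}
        full = encode_linkage(
            [("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)], bounds,
            splices=[("chr1", 99, 200), ("chr1", 299, 400)], read_id="full",
        )
        skip = encode_linkage(
            [("chr1", 0, 100), ("chr1", 400, 500)], bounds,
            splices=[("chr1", 99, 400)], read_id="skip",
        )
        assert skip.markers < full.markers  # markers alone would collapse them
        kept = deduplicate_linkages([full, skip])
        assert len(kept) == 2

    def test_incomparable_both_survive(self):
        a = self.lk([(0, 150)], "r1")        # markers at 100 only
        b = self.lk([(250, 350)], "r2")      # markers at 300 only
        assert len(deduplicate_linkages([a, b])) == 2

    def test_idempotent_and_covering(self):
        lks = [
            self.lk([(0, 150)], "r1"),
            self.lk([(0, 150), (250, 350)], "r2"),
            self.lk([(250, 350)], "r3"),
            self.lk([(450, 550)], "r4"),
        ]
        once = deduplicate_linkages(lks)
        twice = deduplicate_linkages(once)
        assert {l.markers for l in once} == {l.markers for l in twice}
        assert len(once) <= len(lks)
        for orig in lks:
            assert any(orig.markers <= k.markers for k in once)


class TestEndPool:
    def test_polya_tail_detected(self):
        frag = make_fragment(read_start=0, read_end=500, g_start=1_000, g_end=1_500)
        aln = make_read([frag], read_length=510)
        pool = build_end_pool([aln], {"r1": "C" * 500 + "A" * 10}, None)
        assert ("chr1", 1_500) in pool.three_ends
        assert pool.three_ends[("chr1", 1_500)] == {"polyA"}

    def test_short_tail_not_called(self):
        frag = make_fragment(read_start=0, read_end=500)
        aln = make_read([frag], read_length=504)
        pool = build_end_pool([aln], {"r1": "C" * 500 + "AAAA"}, None)
        assert pool.three_ends == {}

    def test_annotated_ends_always_included(self):
        g_plus = GeneModel("G", "G.t1", GenomeInterval("chr1", 10, 900, "+"), [(10, 900)], "ref")
        g_minus = GeneModel("H", "H.t1", GenomeInterval("chr2", 50, 700, "-"), [(50, 700)], "ref")
        pool = build_end_pool([], None, AnnotationIndex([g_plus, g_minus]))
        assert ("chr1", 10) in pool.five_ends and ("chr1", 900) in pool.three_ends
        assert ("chr2", 700) in pool.five_ends and ("chr2", 50) in pool.three_ends

    @pytest.mark.parametrize("tail,ok", [("A" * 8, True), ("A" * 7, False), ("AACAAAAA", True), ("ACGTACGT", False)])
    def test_polya_rule(self, tail, ok):
        assert is_polya_tail(tail) == ok


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def brute_force_enumerate(seed_introns, forbidden_free_pool, tss_list, tes_list):
    """All subsets of pool introns + end pairs giving a valid exon chain
    containing the seed introns."""
    results = set()
    for lo in tss_list:
        for hi in tes_list:
            for k in range(len(forbidden_free_pool) + 1):
                for combo in combinations(forbidden_free_pool, k):
                    introns = sorted(seed_introns + list(combo))
                    if any(b[0] < a[1] for a, b in zip(introns, introns[1:])):
                        continue
                    if any(not (lo < s and e < hi) for s, e in introns):
                        continue
                    results.add((lo, hi, tuple(introns)))
    return results


class TestEnumerateIsoforms:
    def make_seed(self, blocks, splices, bounds):
        return encode_linkage(
            [("chr1", s, e) for s, e in blocks], bounds,
            splices=[("chr1", d, a) for d, a in splices], read_id="seed",
        )

    def test_optional_downstream_splice_doubles_candidates(self):
        # seed covers s1, s2; pool adds optional s3 between s2 and the 3' end
        loc = Locus("chr1", 0, 1_000, "+", label="G")
        bounds = {"chr1": [100, 200, 300, 400, 600, 700]}
        seed = self.make_seed(
            [(0, 100), (200, 300), (400, 450)], [(99, 200), (299, 400)], bounds
        )
        pool = [splice(99, 200), splice(299, 400), splice(599, 700)]
        ends = EndPool()
        ends.add5("chr1", 0, "ann")
        ends.add3("chr1", 1_000, "ann")
        cands = enumerate_isoforms(seed, pool, ends, loc)
        chains = {tuple(c.segments[0][2]) for c in cands}
        assert len(cands) == 2
        assert tuple([(0, 100), (200, 300), (400, 1_000)]) in chains
        assert tuple([(0, 100), (200, 300), (400, 600), (700, 1_000)]) in chains
        # matches brute force over subsets
        oracle = brute_force_enumerate([(100, 200), (300, 400)], [(600, 700)], [0], [1_000])
        assert len(oracle) == len(cands)

    def test_seed_covering_everything_gives_single_candidate(self):
        loc = Locus("chr1", 0, 500, "+", label="G")
        bounds = {"chr1": [100, 200]}
        seed = self.make_seed([(0, 100), (200, 500)], [(99, 200)], bounds)
        ends = EndPool()
        ends.add5("chr1", 0, "ann")
        ends.add3("chr1", 500, "ann")
        cands = enumerate_isoforms(seed, [splice(99, 200)], ends, loc)
        assert len(cands) == 1
        assert cands[0].segments[0][2] == [(0, 100), (200, 500)]

    def test_pool_splice_contradicting_seed_exon_excluded(self):
        # seed reads through [250, 350): a pool intron [260, 340) would
        # remove bases the seed shows exonic
        loc = Locus("chr1", 0, 500, "+", label="G")
        bounds = {"chr1": [260, 340]}
        seed = self.make_seed([(200, 400)], [], bounds)
        ends = EndPool()
        ends.add5("chr1", 0, "ann")
        ends.add3("chr1", 500, "ann")
        cands = enumerate_isoforms(seed, [splice(259, 340)], ends, loc)
        assert len(cands) == 1
        assert cands[0].segments[0][2] == [(0, 500)]

    def test_fusion_seed_two_tss_gives_two_candidates(self):
        loc5 = Locus("chr1", 0, 1_000, "+", label="G5")
        loc3 = Locus("chr2", 0, 1_000, "+", label="G3")
        bounds = {"chr1": [500], "chr2": [400]}
        seed = encode_linkage(
            [("chr1", 300, 500), ("chr2", 400, 700)], bounds,
            is_fusion=True, fusion_splice=("chr1", 499, "chr2", 400), read_id="seed",
        )
        ends = EndPool()
        ends.add5("chr1", 0, "ann")
        ends.add5("chr1", 100, "ann")
        ends.add3("chr2", 900, "ann")
        cands = enumerate_isoforms(seed, [], ends, loc5, locus3=loc3)
        assert len(cands) == 2
        assert all(c.is_fusion for c in cands)
        five_starts = sorted(c.segments[0][2][0][0] for c in cands)
        assert five_starts == [0, 100]
        for c in cands:
            assert c.segments[0][2][-1][1] == 500  # pinned at the junction
            assert c.segments[1][2][0][0] == 400
            assert c.segments[1][2][-1][1] == 900

    def test_enumeration_matches_brute_force_oracle_random(self, rng):
        for _ in range(200):
            n_pool = int(rng.integers(0, 5))
            # random non-overlapping candidate introns on [0, 2000)
            cuts = sorted(rng.choice(range(50, 1_950), size=2 * (n_pool + 1), replace=False).tolist())
            introns = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_pool + 1)]
            seed_introns = introns[:1]
            pool_introns = introns[1:]
            loc = Locus("chr1", 0, 2_000, "+", label="G")
            bounds = {"chr1": sorted({x for i in introns for x in i})}
            d, a = seed_introns[0]
            seed = self.make_seed([(max(0, d - 40), d), (a, min(2_000, a + 40))], [(d - 1, a)], bounds)
            pool = [splice(s - 1, e) for s, e in introns]
            ends = EndPool()
            tss = sorted(set(int(x) for x in rng.integers(0, 30, size=2)))
            tes = sorted(set(int(x) for x in rng.integers(1_960, 2_000, size=2)))
            for t in tss:
                ends.add5("chr1", t, "ann")
            for t in tes:
                ends.add3("chr1", t, "ann")
            cands = enumerate_isoforms(seed, pool, ends, loc)
            # oracle: the seed's exonic evidence is every boundary-flank base
            # its blocks cover; pool introns touching one are contradictions
            blocks = [(max(0, d - 40), d), (a, min(2_000, a + 40))]
            exonic = {
                b
                for c in bounds["chr1"]
                for b in (c - 1, c)
                if any(s <= b < e for s, e in blocks)
            }
            free = [
                (s, e) for s, e in pool_introns
                if not any(s <= b < e for b in exonic)
            ]
            oracle = brute_force_enumerate([seed_introns[0]], free, tss, tes)
            got = {
                (c.segments[0][2][0][0], c.segments[0][2][-1][1],
                 tuple((e1, s2) for (_, e1), (s2, _) in zip(c.segments[0][2], c.segments[0][2][1:])))
                for c in cands
            }
            want = {(lo, hi, tuple(ii)) for lo, hi, ii in oracle}
            assert got == want
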