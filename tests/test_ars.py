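"""ARS construction, merging (vs union-find oracle), coordinate bijections,
and FASTA round-trip."""
from __future__ import annotations

import numpy as np
import pytest

from longfuse.ars import (
    ARS,
    ars_to_genome,
    build_ars,
    genome_to_ars,
    merge_ars,
    mergeable,
    read_ars_fasta,
    write_ars_fasta,
)
from longfuse.model import FusionCandidate, GenomeInterval
from longfuse.seq import revcomp

from conftest import make_fragment


def make_candidate(
    chrom5="chr1", g5=(10_000, 11_000), s5="+",
    chrom3="chr2", g3=(5_000, 6_000), s3="+",
):
    cand = FusionCandidate(
        read_id="r1",
        left=make_fragment(read_start=0, read_end=150, chrom=chrom5, g_start=g5[0], g_end=g5[1]),
        right=make_fragment(read_start=160, read_end=320, chrom=chrom3, g_start=g3[0], g_end=g3[1]),
    )
    cand.strand5, cand.strand3 = s5, s3
    return cand


class TestBuildArs:
    def test_extension_arithmetic(self, small_genome):
        ars = build_ars(make_candidate(), small_genome, flank=2000)
        assert (ars.left_region.start, ars.left_region.end) == (10_000, 13_000)
        assert (ars.right_region.start, ars.right_region.end) == (3_000, 6_000)
        assert ars.boundary == 3_000
        assert len(ars) == 6_000

    def test_extension_clipped_at_chromosome_end(self, small_genome):
        # fragment ends 500 bp from the chromosome end (20 kb chroms)
        cand = make_candidate(g5=(18_500, 19_500))
        ars = build_ars(cand, small_genome, flank=2000)
        assert ars.left_region.end == 20_000
        assert len(ars.left_region) == 1_500

    def test_minus_strand_region_reverse_complemented(self, small_genome):
        cand = make_candidate(s3="-")
        ars = build_ars(cand, small_genome, flank=2000)
        # '-' right fragment: junction-proximal end is its genomic end
        assert (ars.right_region.start, ars.right_region.end) == (5_000, 8_000)
        right_seq = ars.sequence[ars.boundary:]
        assert right_seq == revcomp(small_genome["chr2"][5_000:8_000])
        # mapping an ARS substring back to the genome agrees with revcomp
        chrom, g, strand = ars_to_genome(ars, ars.boundary)
        assert (chrom, g, strand) == ("chr2", 7_999, "-")


class TestCoordinateMaps:
    def test_position_zero_and_boundary(self, small_genome):
        ars = build_ars(make_candidate(), small_genome)
        assert ars_to_genome(ars, 0) == ("chr1", 10_000, "+")
        assert ars_to_genome(ars, ars.boundary) == ("chr2", 3_000, "+")

    def test_out_of_range_errors(self, small_genome):
        ars = build_ars(make_candidate(), small_genome)
        with pytest.raises(ValueError):
            ars_to_genome(ars, len(ars))
        with pytest.raises(ValueError):
            ars_to_genome(ars, -1)

    @pytest.mark.parametrize("s3", ["+", "-"])
    def test_round_trip_bijection_everywhere(self, small_genome, s3):
        ars = build_ars(make_candidate(s3=s3), small_genome)
        for pos in range(0, len(ars), 97):
            chrom, g, _ = ars_to_genome(ars, pos)
            side = "left" if pos < ars.boundary else "right"
            assert genome_to_ars(ars, chrom, g, side) == pos


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def random_arss(r, genome, n=None):
    n = n or int(r.integers(1, 9))
    out = []
    for i in range(n):
        c5 = f"chr{int(r.integers(1, 3))}"
        c3 = f"chr{int(r.integers(1, 3))}"
        s5 = int(r.integers(0, 15_000))
        s3 = int(r.integers(0, 15_000))
        l5 = int(r.integers(500, 4_000))
        l3 = int(r.integers(500, 4_000))
        left = GenomeInterval(c5, s5, min(s5 + l5, 20_000), "+")
        right = GenomeInterval(c3, s3, min(s3 + l3, 20_000), "+")
        seq = genome[c5][left.start:left.end] + genome[c3][right.start:right.end]
        out.append(ARS(ars_id=f"A{i}", left_region=left, right_region=right, sequence=seq))
    return out


def union_find_components(arss):
    """Connected components of the pairwise mergeability graph via BFS."""
    n = len(arss)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp, queue = [], [i]
        seen[i] = True
        while queue:
            k = queue.pop()
            comp.append(k)
            for j in range(n):
                if not seen[j] and mergeable(arss[k], arss[j]):
                    seen[j] = True
                    queue.append(j)
        comps.append(frozenset(comp))
    return comps


def brute_force_merge_spans(arss, genome):
    """Independent fixpoint oracle: repeatedly find any mergeable pair and
    replace it by the span union, until none remains."""
    from longfuse.ars import ARS as _ARS

    items = [
        [a.left_region.chrom, a.left_region.start, a.left_region.end,
         a.right_region.chrom, a.right_region.start, a.right_region.end]
        for a in arss
    ]

    def overlaps(x, y):
        return (
            x[0] == y[0] and x[1] < y[2] and y[1] < x[2]
            and x[3] == y[3] and x[4] < y[5] and y[4] < x[5]
        )

    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if overlaps(items[i], items[j]):
                    a, b = items[i], items[j]
                    merged = [a[0], min(a[1], b[1]), max(a[2], b[2]),
                              a[3], min(a[4], b[4]), max(a[5], b[5])]
                    items = [items[k] for k in range(len(items)) if k not in (i, j)] + [merged]
                    changed = True
                    break
            if changed:
                break
    return sorted((t[1], t[2], t[4], t[5]) for t in items)


class TestMergeArs:
    def test_same_fusion_nearby_junctions_merge(self, small_genome):
        a = build_ars(make_candidate(g5=(10_000, 11_000), g3=(5_000, 6_000)), small_genome)
        b = build_ars(make_candidate(g5=(10_050, 11_050), g3=(5_050, 6_050)), small_genome)
        merged = merge_ars([a, b], small_genome)
        assert len(merged) == 1
        assert (merged[0].left_region.start, merged[0].left_region.end) == (10_000, 13_050)

    def test_unrelated_fusions_unchanged(self, small_genome):
        a = build_ars(make_candidate(chrom5="chr1", chrom3="chr2"), small_genome)
        b = build_ars(make_candidate(chrom5="chr2", chrom3="chr1"), small_genome)
        assert len(merge_ars([a, b], small_genome)) == 2

    def test_transitive_chain_merges_fully(self, small_genome):
        # A~B and B~C overlap pairwise, A and C do not
        mk = lambda off: build_ars(
            make_candidate(g5=(10_000 + off, 10_600 + off), g3=(5_000 + off, 5_600 + off)),
            small_genome, flank=200,
        )
        a, b, c = mk(0), mk(700), mk(1_400)
        assert mergeable(a, b) and mergeable(b, c) and not mergeable(a, c)
        merged = merge_ars([a, b, c], small_genome)
        assert len(merged) == 1

    def test_matches_union_find_oracle_randomized(self, rng, small_genome):
        for _ in range(1000):
            arss = random_arss(rng, small_genome)
            merged = merge_ars(arss, small_genome)
            got = sorted(
                (m.left_region.start, m.left_region.end, m.right_region.start, m.right_region.end)
                for m in merged
            )
            assert got == brute_force_merge_spans(arss, small_genome)
            # merging is at least as coarse as the original overlap graph
            assert len(merged) <= len(union_find_components(arss))
            # no mergeable pair remains
            for i in range(len(merged)):
                for j in range(i + 1, len(merged)):
                    assert not mergeable(merged[i], merged[j])

    def test_idempotent_and_order_independent(self, rng, small_genome):
        for _ in range(50):
            arss = random_arss(rng, small_genome)
            merged = merge_ars(arss, small_genome)
            again = merge_ars(merged, small_genome)
            sig = lambda ms: sorted(
                (m.left_region.start, m.left_region.end, m.right_region.start, m.right_region.end)
                for m in ms
            )
            assert sig(again) == sig(merged)
            perm = [arss[i] for i in rng.permutation(len(arss))]
            assert sig(merge_ars(perm, small_genome)) == sig(merged)


class TestPersistence:
    def test_fasta_round_trip_restores_maps(self, small_genome, tmp_path):
        arss = [
            build_ars(make_candidate(), small_genome, ars_id="ARS_1"),
            build_ars(make_candidate(chrom5="chr2", chrom3="chr1", s3="-"), small_genome, ars_id="ARS_2"),
        ]
        path = tmp_path / "ars.fa"
        write_ars_fasta(arss, path)
        back = read_ars_fasta(path)
        assert len(back) == 2
        for orig, re in zip(arss, back):
            assert re.sequence == orig.sequence
            assert len(re.sequence) == len(re.left_region) + len(re.right_region)
            for pos in (0, re.boundary, len(re) - 1):
                assert ars_to_genome(re, pos) == ars_to_genome(orig, pos)
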