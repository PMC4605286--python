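"""Isoform candidate construction from long-read splice linkages.

Long-read alignment gaps longer than 68 bp are called as splices (shorter
gaps are treated as deletions), validated against short-read junctions or
annotation, and the splices of one read are encoded as a splice linkage over
exon-boundary markers: each boundary P has an inner/outer marker pair
(P-, P+) for the two flanking bases, so a read splicing or ending at P is
distinguishable from a read reading straight through it.  Redundant linkages
(marker subsets) are removed.  Each surviving linkage seeds isoform
enumeration: compatible pool splices are added in all combinations between a
pooled 5' end and 3' end.  Fusion linkages seed fusion isoforms joined at
exactly one fusion splice, taking 5' ends from the 5' gene and 3' ends from
the 3' gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

from .annotation import AnnotationIndex
from .model import STRAND_FWD, STRAND_REV, LongReadAlignmentSet, Splice

MIN_SPLICE_GAP = 68

Marker = tuple[str, int, str]  # (chrom, between-base coord, "-" | "+")
SpliceKey = tuple[str, int, int]  # (chrom, donor, acceptor)


# ---------------------------------------------------------------------------
# splice calling and validation
# ---------------------------------------------------------------------------

def call_splices(aln: LongReadAlignmentSet, min_splice_gap: int = MIN_SPLICE_GAP) -> list[Splice]:
    """Call every alignment gap strictly longer than ``min_splice_gap`` as a
    splice; shorter gaps are deletions and ignored."""
    out = []
    for frag in aln.fragments:
        for donor, acceptor in frag.gaps:
            if acceptor - donor - 1 > min_splice_gap:
                out.append(Splice(chrom=frag.chrom, donor=donor, acceptor=acceptor,
                                  strand=frag.genome_span.strand))
    return out


def validate_splices(
    splices: Iterable[Splice],
    short_read_junctions: set[SpliceKey],
    annotation: AnnotationIndex | None = None,
    exempt: set[SpliceKey] | None = None,
) -> list[Splice]:
    """Keep splices confirmed by short reads or annotation.

    ``exempt`` keys (fusion splices, which are validated by the fusion-site
    caller instead) pass unconditionally.
    """
    exempt = exempt or set()
    kept = []
    for sp in splices:
        if sp.key in exempt:
            kept.append(sp)
        elif sp.key in short_read_junctions:
            kept.append(sp)
        elif annotation is not None and annotation.is_annotated_intron(*sp.key):
            kept.append(sp)
    return kept


# ---------------------------------------------------------------------------
# boundaries and linkages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A gene locus: the genomic span over which boundaries are collected."""

    chrom: str
    start: int
    end: int
    strand: str
    label: str = ""


def build_boundaries(
    locus: Locus,
    splices: Iterable[Splice],
    annotation: AnnotationIndex | None = None,
) -> list[int]:
    """Sorted unique exon-boundary coordinates (between-base convention) of a
    locus: splice donors/acceptors plus annotated isoform 5'/3' ends.

    A splice donor at base d contributes boundary d+1 (the exon ends there);
    an acceptor at base a contributes boundary a.
    """
    coords: set[int] = set()
    for sp in splices:
        if sp.chrom == locus.chrom and locus.start <= sp.donor and sp.acceptor <= locus.end:
            coords.add(sp.donor + 1)
            coords.add(sp.acceptor)
    if annotation is not None:
        for m in annotation.genes_overlapping(locus.chrom, locus.start, locus.end):
            coords.add(m.interval.start)
            coords.add(m.interval.end)
    return sorted(coords)


@dataclass
class SpliceLinkage:
    """The boundary markers covered by one long read, plus the actual splices
    the read took.  Marker subsets of another linkage are redundant."""

    markers: frozenset[Marker]
    splices: frozenset[SpliceKey]
    is_fusion: bool = False
    fusion_splice: Optional[tuple[str, int, str, int]] = None  # (chrom5, pos5, chrom3, pos3)
    read_ids: set[str] = field(default_factory=set)

    def ordered_markers(self) -> list[Marker]:
        return sorted(self.markers, key=lambda m: (m[0], m[1], m[2] == "+"))


def encode_linkage(
    exon_blocks: list[tuple[str, int, int]],
    boundaries: dict[str, list[int]],
    splices: Iterable[SpliceKey] = (),
    read_id: str = "",
    is_fusion: bool = False,
    fusion_splice: Optional[tuple[str, int, str, int]] = None,
) -> SpliceLinkage:
    """Encode a read's aligned exon blocks as a linkage over boundary markers.

    For a boundary at coord c, marker (c, "-") is covered when a block covers
    base c-1 and (c, "+") when a block covers base c; a read reading straight
    through contributes both, a read splicing or terminating at c only the
    inner one.
    """
    markers: set[Marker] = set()
    for chrom, s, e in exon_blocks:
        for c in boundaries.get(chrom, ()):
            if s <= c - 1 < e:
                markers.add((chrom, c, "-"))
            if s <= c < e:
                markers.add((chrom, c, "+"))
    return SpliceLinkage(
        markers=frozenset(markers),
        splices=frozenset(splices),
        is_fusion=is_fusion,
        fusion_splice=fusion_splice,
        read_ids={read_id} if read_id else set(),
    )


def deduplicate_linkages(linkages: list[SpliceLinkage]) -> list[SpliceLinkage]:
    """Remove redundant linkages, merging read-id provenance into the
    surviving superset.  Idempotent.

    A linkage is redundant to another when both its marker set and its
    splice set are subsets: a partial read of the same structure adds
    nothing, but a read taking a different splice (e.g. skipping an exon the
    other read covers) is distinct evidence even though its markers alone
    are a subset.
    """
    order = sorted(range(len(linkages)), key=lambda i: -len(linkages[i].markers))
    kept: list[SpliceLinkage] = []
    for i in order:
        lk = linkages[i]
        host = None
        for k in kept:
            if lk.markers <= k.markers and lk.splices <= k.splices:
                host = k
                break
        if host is None:
            kept.append(
                SpliceLinkage(
                    markers=lk.markers,
                    splices=lk.splices,
                    is_fusion=lk.is_fusion,
                    fusion_splice=lk.fusion_splice,
                    read_ids=set(lk.read_ids),
                )
            )
        else:
            host.read_ids |= lk.read_ids
    return kept


# ---------------------------------------------------------------------------
# 5'/3' end pool
# ---------------------------------------------------------------------------

@dataclass
class EndPool:
    """Candidate transcript ends, as between-base genomic coordinates,
    tagged by evidence source (polyA detection or an annotation library)."""

    five_ends: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    three_ends: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    def add5(self, chrom: str, coord: int, source: str) -> None:
        self.five_ends.setdefault((chrom, coord), set()).add(source)

    def add3(self, chrom: str, coord: int, source: str) -> None:
        self.three_ends.setdefault((chrom, coord), set()).add(source)

    def five_in(self, chrom: str, lo: int, hi: int) -> list[int]:
        return sorted(c for (ch, c) in self.five_ends if ch == chrom and lo <= c <= hi)

    def three_in(self, chrom: str, lo: int, hi: int) -> list[int]:
        return sorted(c for (ch, c) in self.three_ends if ch == chrom and lo <= c <= hi)


def is_polya_tail(tail: str, min_run: int = 8, min_frac: float = 0.8) -> bool:
    """A terminal tail counts as polyA evidence when it is at least
    ``min_run`` long and at least ``min_frac`` A (or T, for the reverse
    orientation)."""
    if len(tail) < min_run:
        return False
    tail = tail.upper()
    frac_a = tail.count("A") / len(tail)
    frac_t = tail.count("T") / len(tail)
    return max(frac_a, frac_t) >= min_frac


def build_end_pool(
    alns: Iterable[LongReadAlignmentSet],
    read_seqs: dict[str, str] | None,
    annotation: AnnotationIndex | None = None,
    polya_min_run: int = 8,
) -> EndPool:
    """Pool transcript 5'/3' ends from annotation plus polyA/polyT tails of
    long reads.

    A trailing A-rich tail past the last aligned read base marks a 3' end at
    the alignment terminus; a leading T-rich head marks a 3' end at the first
    fragment's upstream terminus (the read is then the reverse complement of
    a polyadenylated transcript).
    """
    pool = EndPool()
    if annotation is not None:
        for m in annotation.models:
            if m.strand == STRAND_REV:
                pool.add5(m.interval.chrom, m.interval.end, m.source)
                pool.add3(m.interval.chrom, m.interval.start, m.source)
            else:
                pool.add5(m.interval.chrom, m.interval.start, m.source)
                pool.add3(m.interval.chrom, m.interval.end, m.source)
    if read_seqs:
        for aln in alns:
            seq = read_seqs.get(aln.read_id)
            if not seq or not aln.fragments:
                continue
            last = max(aln.fragments, key=lambda f: f.read_end)
            tail = seq[last.read_end:]
            if tail and is_polya_tail(tail, polya_min_run) and tail.upper().count("A") >= tail.upper().count("T"):
                coord = last.genome_span.start if last.genome_span.strand == STRAND_REV else last.genome_span.end
                pool.add3(last.chrom, coord, "polyA")
            first = min(aln.fragments, key=lambda f: f.read_start)
            head = seq[: first.read_start]
            if head and is_polya_tail(head, polya_min_run) and head.upper().count("T") >= head.upper().count("A"):
                coord = first.genome_span.end if first.genome_span.strand == STRAND_REV else first.genome_span.start
                pool.add3(first.chrom, coord, "polyA")
    return pool


# ---------------------------------------------------------------------------
# isoform candidates
# ---------------------------------------------------------------------------

@dataclass
class IsoformCandidate:
    """An exon chain — one genomic block for a regular isoform, two (the 5'
    then the 3' locus) for a fusion isoform joined at one fusion splice."""

    isoform_id: str
    locus_label: str
    segments: list[tuple[str, str, list[tuple[int, int]]]]  # (chrom, strand, exons genomic order)
    is_fusion: bool = False
    splice_chain: frozenset[SpliceKey] = frozenset()
    fusion_splice: Optional[tuple[str, int, str, int]] = None
    seed_id: str = ""
    overflowed: bool = False
    rpkm: Optional[float] = None
    theta: Optional[float] = None

    def blocks(self):
        return list(self.segments)

    @property
    def length(self) -> int:
        return sum(e - s for _, _, exons in self.segments for s, e in exons)

    def exon_set(self) -> list[tuple[str, int, int]]:
        return [(chrom, s, e) for chrom, _, exons in self.segments for s, e in exons]

    def chain_markers(self) -> frozenset[Marker]:
        """Boundary markers implied by the splice chain (for TP labeling)."""
        markers: set[Marker] = set()
        for chrom, d, a in self.splice_chain:
            markers.add((chrom, d + 1, "-"))
            markers.add((chrom, a, "+"))
        return frozenset(markers)

    def consecutive_intron_pairs(self) -> list[tuple[SpliceKey, SpliceKey]]:
        """Adjacent intron pairs sharing an exon, per genomic block, excluding
        pairs that would involve the fusion splice."""
        pairs = []
        for chrom, _, exons in self.segments:
            introns = [
                (chrom, e1 - 1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])
            ]
            introns = [i for i in introns if i in self.splice_chain]
            pairs.extend(zip(introns, introns[1:]))
        return pairs


class EnumerationOverflow(Exception):
    pass


def _compatible_subsets(optional: list[tuple[int, int]], chosen: list[tuple[int, int]], limit: list[int]):
    """Yield all subsets of ``optional`` introns that are pairwise
    non-overlapping (and non-overlapping with each other); ``optional`` must
    be sorted and already filtered against fixed introns."""
    yield list(chosen)
    for i, intr in enumerate(optional):
        if chosen and intr[0] < chosen[-1][1]:
            continue
        chosen.append(intr)
        limit[0] -= 1
        if limit[0] < 0:
            raise EnumerationOverflow
        yield from _compatible_subsets(optional[i + 1 :], chosen, limit)
        chosen.pop()


def _exon_chain(span: tuple[int, int], introns: list[tuple[int, int]]) -> list[tuple[int, int]] | None:
    """Exon chain of a transcript span minus sorted introns; None when an
    intron touches the span edge (empty flanking exon)."""
    s, e = span
    exons = []
    cur = s
    for i_s, i_e in introns:
        if i_s <= cur or i_e >= e:
            return None
        exons.append((cur, i_s))
        cur = i_e
    exons.append((cur, e))
    return exons


def _side_variants(
    seed: SpliceLinkage,
    splice_pool: list[Splice],
    end_pool: EndPool,
    loc: Locus,
    limit: list[int],
    minimal: bool,
    pinned: tuple[str, int] | None = None,
) -> list[tuple[tuple[int, int], list[tuple[int, int]]]]:
    """All (span, introns) variants of one locus side.

    ``pinned`` fixes one transcript terminus at the fusion junction:
    ("3p", j) pins the transcript 3' side (the 5'-gene segment of a fusion)
    and ("5p", j) the transcript 5' side, at between-base coordinate j.
    Introns are returned as genomic [start, end) intervals.
    """
    seed_keys = sorted(k for k in seed.splices if k[0] == loc.chrom and _within(k, loc))
    fixed = [(d + 1, a) for (_, d, a) in seed_keys]
    exonic = [b for b in _seed_exonic_bases(seed, loc.chrom) if loc.start <= b < loc.end]
    anchor_pts = [p for i in fixed for p in i] + exonic
    if pinned is not None:
        anchor_pts.append(pinned[1])
    if not anchor_pts:
        anchor_pts = [loc.start, loc.end]
    anchor_lo, anchor_hi = min(anchor_pts), max(anchor_pts)

    pool = [
        (sp.donor, sp.acceptor)
        for sp in splice_pool
        if sp.chrom == loc.chrom
        and loc.start <= sp.donor
        and sp.acceptor <= loc.end
        and (sp.strand in (loc.strand, ".") or loc.strand == ".")
        and (sp.chrom, sp.donor, sp.acceptor) not in set(seed_keys)
    ]
    pool = _forbidden_filter(pool, exonic, fixed)
    if minimal:
        pool = []

    fives = end_pool.five_in(loc.chrom, loc.start, loc.end)
    threes = end_pool.three_in(loc.chrom, loc.start, loc.end)
    fwd = loc.strand != STRAND_REV
    # genomic-left / genomic-right terminus options
    if pinned is None:
        lefts = [c for c in (fives if fwd else threes) if c <= anchor_lo]
        rights = [c for c in (threes if fwd else fives) if c >= anchor_hi]
    elif pinned[0] == "3p":  # 5'-gene segment: junction at transcript 3' side
        if fwd:
            lefts = [c for c in fives if c <= anchor_lo]
            rights = [pinned[1]]
        else:
            lefts = [pinned[1]]
            rights = [c for c in fives if c >= anchor_hi]
    else:  # "5p": 3'-gene segment, junction at transcript 5' side
        if fwd:
            lefts = [pinned[1]]
            rights = [c for c in threes if c >= anchor_hi]
        else:
            lefts = [c for c in threes if c <= anchor_lo]
            rights = [pinned[1]]
    if minimal:
        lefts = [max(lefts)] if lefts else []
        rights = [min(rights)] if rights else []

    variants = []
    for lo in sorted(set(lefts)):
        for hi in sorted(set(rights)):
            if lo >= hi:
                continue
            usable = sorted((d + 1, a) for d, a in pool if lo < d + 1 and a < hi)
            for extra in _compatible_subsets(usable, [], limit):
                introns = sorted(fixed + extra)
                if any(b[0] < a[1] for a, b in zip(introns, introns[1:])):
                    continue
                if _exon_chain((lo, hi), introns) is not None:
                    variants.append(((lo, hi), introns))
    return variants


def _seed_exonic_bases(seed: SpliceLinkage, chrom: str) -> list[int]:
    """Bases the seed linkage proves exonic (marker flanking bases)."""
    return [
        (c - 1 if side == "-" else c)
        for (ch, c, side) in seed.markers
        if ch == chrom
    ]


def _forbidden_filter(pool, exonic, fixed):
    """Drop pool introns covering a seed-exonic base or overlapping a seed intron."""
    out = []
    for d, a in pool:
        lo, hi = d + 1, a
        if any(lo <= b < hi for b in exonic):
            continue
        if any(lo < f_hi and f_lo < hi for f_lo, f_hi in fixed):
            continue
        out.append((d, a))
    return out


def _chain_keys(chrom: str, introns: list[tuple[int, int]]) -> set[SpliceKey]:
    return {(chrom, lo - 1, hi) for lo, hi in introns}


def enumerate_isoforms(
    seed: SpliceLinkage,
    splice_pool: list[Splice],
    end_pool: EndPool,
    locus: Locus,
    locus3: Locus | None = None,
    max_candidates: int = 4096,
    id_prefix: str = "iso",
) -> list[IsoformCandidate]:
    """Enumerate all isoform candidates containing the seed linkage's splices.

    Pool splices of consistent strand are added in every combination that
    does not contradict the seed (no added intron may cover a base the seed
    marks exonic, nor overlap a seed intron), between every pooled 5' end
    upstream and 3' end downstream.  For a fusion seed (``locus3`` given),
    the 5' gene contributes the 5' ends and the 3' gene the 3' ends, the two
    segments joined at the seed's single fusion splice.  On combinatorial
    overflow the result is flagged and only the seed-faithful minimal isoform
    is kept.
    """
    try:
        return _enumerate(seed, splice_pool, end_pool, locus, locus3, [max_candidates], id_prefix)
    except EnumerationOverflow:
        out = _enumerate(seed, splice_pool, end_pool, locus, locus3, [max_candidates], id_prefix, minimal=True)
        for iso in out:
            iso.overflowed = True
        return out


def _enumerate(seed, splice_pool, end_pool, locus, locus3, limit, id_prefix, minimal=False):
    out: list[IsoformCandidate] = []
    if locus3 is None:
        for n, (span, introns) in enumerate(
            _side_variants(seed, splice_pool, end_pool, locus, limit, minimal)
        ):
            chain = _exon_chain(span, introns)
            out.append(
                IsoformCandidate(
                    isoform_id=f"{id_prefix}.{n + 1}",
                    locus_label=locus.label or f"{locus.chrom}:{locus.start + 1}",
                    segments=[(locus.chrom, locus.strand, chain)],
                    splice_chain=frozenset(_chain_keys(locus.chrom, introns)),
                    seed_id=id_prefix,
                )
            )
        return out

    if seed.fusion_splice is None:
        raise ValueError("fusion enumeration requires a seed with a fusion splice")
    chrom5, pos5, chrom3, pos3 = seed.fusion_splice
    j5 = pos5 + 1 if locus.strand != STRAND_REV else pos5
    j3 = pos3 if locus3.strand != STRAND_REV else pos3 + 1
    v5 = _side_variants(seed, splice_pool, end_pool, locus, limit, minimal, pinned=("3p", j5))
    v3 = _side_variants(seed, splice_pool, end_pool, locus3, limit, minimal, pinned=("5p", j3))
    n = 0
    for (span5, introns5), (span3, introns3) in product(v5, v3):
        limit[0] -= 1
        if limit[0] < 0:
            raise EnumerationOverflow
        n += 1
        keys = _chain_keys(locus.chrom, introns5) | _chain_keys(locus3.chrom, introns3)
        out.append(
            IsoformCandidate(
                isoform_id=f"{id_prefix}.f{n}",
                locus_label=f"{locus.label}--{locus3.label}",
                segments=[
                    (locus.chrom, locus.strand, _exon_chain(span5, introns5)),
                    (locus3.chrom, locus3.strand, _exon_chain(span3, introns3)),
                ],
                is_fusion=True,
                splice_chain=frozenset(keys),
                fusion_splice=seed.fusion_splice,
                seed_id=id_prefix,
            )
        )
    return out


def _within(key: SpliceKey, loc: Locus) -> bool:
    return loc.start <= key[1] and key[2] <= loc.end
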