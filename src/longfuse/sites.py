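"""Fusion-site determination from short-read splice alignments on ARSs.

Short reads spanning the true fusion junction align on an ARS with an N-gap
(the artificial intron) crossing the concatenation boundary.  Each such gap,
observed with sufficient overhang on both sides, is a single-nucleotide
fusion-site observation; mapping its two flanks back through the ARS
coordinate maps yields the genomic junction (pos5, pos3).  Sites are then
annotated with long-read support (and the MSFL uniqueness statistic), the
canonical GT-AG flag, and filtered on minimum long- and short-read support.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .ars import ARS, ars_to_genome
from .model import STRAND_REV, FusionSite, SiteConfig
from .seq import fetch, revcomp


@dataclass
class JunctionObservations:
    """Aggregated N-gap observations on ARSs, keyed by exact coordinates."""

    fusion: dict[tuple[str, int, int], int] = field(default_factory=dict)
    regular: dict[tuple[str, int, int], int] = field(default_factory=dict)


def _cigar_segments(cigartuples, ref_start: int):
    """Split an alignment at its N-gaps; yield (ref_span_len, gap_after) where
    gap_after is the N length following the segment (None for the last)."""
    segments = []
    span = 0
    pos = ref_start
    seg_start = ref_start
    for op, n in cigartuples:
        if op == 3:  # N
            segments.append((seg_start, pos, n))
            pos += n
            seg_start = pos
        elif op in (0, 2, 7, 8):  # M D = X consume reference
            pos += n
    segments.append((seg_start, pos, None))
    return segments


def extract_junctions(
    short_aln_path: str | Path,
    arss: dict[str, ARS],
    cfg: SiteConfig | None = None,
) -> JunctionObservations:
    """Collect junction observations from a SAM/BAM of short reads aligned to
    the ARS reference.

    An N-gap is counted when its length lies within [min_intron, max_intron]
    and the read has at least ``min_overhang`` aligned reference bases on each
    side of the gap.  Gaps whose flanks straddle the ARS boundary are fusion
    junctions; gaps inside one region are regular-splice observations.
    """
    cfg = cfg or SiteConfig()
    obs = JunctionObservations()
    mode = "rb" if str(short_aln_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(short_aln_path), mode) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            ars_id = rec.reference_name
            if ars_id not in arss:
                raise ValueError(f"alignment references unknown ARS {ars_id!r}")
            ars = arss[ars_id]
            segs = _cigar_segments(rec.cigartuples or [], rec.reference_start)
            for i, (seg_start, seg_end, gap) in enumerate(segs):
                if gap is None:
                    continue
                if not (cfg.min_intron <= gap <= cfg.max_intron):
                    continue
                left_overhang = seg_end - seg_start
                nxt_start, nxt_end, _ = segs[i + 1]
                right_overhang = nxt_end - nxt_start
                if left_overhang < cfg.min_overhang or right_overhang < cfg.min_overhang:
                    continue
                donor = seg_end - 1  # last aligned base before the gap
                acceptor = seg_end + gap  # first aligned base after
                key = (ars_id, donor, acceptor)
                target = obs.fusion if donor < ars.boundary <= acceptor else obs.regular
                target[key] = target.get(key, 0) + 1
    return obs


def _proximal_ends(cand) -> tuple[int, int]:
    """Genomic positions of the junction-proximal base of each fragment:
    the last base of the 5' fragment and the first base of the 3' fragment,
    in transcript orientation."""
    f5, f3 = cand.frag5, cand.frag3
    g5 = f5.genome_span.start if cand.strand5 == STRAND_REV else f5.genome_span.end - 1
    g3 = f3.genome_span.end - 1 if cand.strand3 == STRAND_REV else f3.genome_span.start
    return g5, g3


def call_fusion_sites(
    junctions: JunctionObservations,
    arss: dict[str, ARS],
    cfg: SiteConfig | None = None,
    genome=None,
) -> list[FusionSite]:
    """Map boundary-straddling junction observations to genomic fusion sites
    and attach read support.

    A source candidate (long read) supports a site when each of its fragment
    ends lies within ``cfg.long_read_window`` bp of the site position on its
    side.  SFL of a supporting read is the length of its shorter fragment;
    MSFL the maximum SFL.  Sites under the support minima are dropped.
    Distinct coordinates are distinct sites — no clustering.
    """
    cfg = cfg or SiteConfig()
    sites: list[FusionSite] = []
    for (ars_id, donor, acceptor), n_short in sorted(junctions.fusion.items()):
        ars = arss[ars_id]
        chrom5, pos5, strand5 = ars_to_genome(ars, donor)
        chrom3, pos3, strand3 = ars_to_genome(ars, acceptor)

        supporting = {}
        labels5: Counter = Counter()
        labels3: Counter = Counter()
        for cand in ars.source_candidates:
            g5, g3 = _proximal_ends(cand)
            if abs(g5 - pos5) <= cfg.long_read_window and abs(g3 - pos3) <= cfg.long_read_window:
                sfl = min(cand.frag5.read_span_len, cand.frag3.read_span_len)
                prev = supporting.get(cand.read_id, -1)
                supporting[cand.read_id] = max(prev, sfl)
            if cand.gene5_label:
                labels5[cand.gene5_label] += 1
            if cand.gene3_label:
                labels3[cand.gene3_label] += 1

        site = FusionSite(
            chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
            strand5=strand5, strand3=strand3,
            n_long_reads=len(supporting),
            n_short_reads=n_short,
            msfl=max(supporting.values(), default=0),
            gene5_label=labels5.most_common(1)[0][0] if labels5 else "",
            gene3_label=labels3.most_common(1)[0][0] if labels3 else "",
        )
        if genome is not None:
            site.canonical = flag_canonical(site, genome)
        if site.n_long_reads >= cfg.min_long_reads and site.n_short_reads >= cfg.min_short_reads:
            sites.append(site)
    return sites


def flag_canonical(site: FusionSite, genome) -> bool:
    """True iff the junction carries the canonical GT-AG splice signal in
    transcript orientation: GT immediately downstream of the 5' break and AG
    immediately upstream of the 3' break."""
    try:
        if site.strand5 == STRAND_REV:
            donor2 = revcomp(fetch(genome, site.chrom5, site.pos5 - 2, site.pos5))
        else:
            donor2 = fetch(genome, site.chrom5, site.pos5 + 1, site.pos5 + 3)
        if site.strand3 == STRAND_REV:
            acceptor2 = revcomp(fetch(genome, site.chrom3, site.pos3 + 1, site.pos3 + 3))
        else:
            acceptor2 = fetch(genome, site.chrom3, site.pos3 - 2, site.pos3)
    except (KeyError, IndexError):
        return False
    if len(donor2) < 2 or len(acceptor2) < 2:
        return False
    return donor2 == "GT" and acceptor2 == "AG"


def canonical_fraction(sites: list[FusionSite]) -> float:
    """Fraction of sites flagged canonical; undefined (error) on empty input."""
    if not sites:
        raise ValueError("canonical fraction undefined for an empty site list")
    return sum(1 for s in sites if s.canonical) / len(sites)
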