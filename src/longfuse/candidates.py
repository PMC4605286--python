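"""Fusion gene candidate detection from long-read fragment alignments.

A long read spanning a fusion junction splits into two fragment alignments on
distinct loci.  Every ordered pair of fragments of one read is tested against
four structural conditions (fragment length, locus separation, read-span
overlap, unaligned gap), then an alignment-ambiguity filter (identity
difference between best and second-best alignment of each fragment) and a
transcription-strand consistency filter.  Surviving pairs are labeled with
gene names (or genomic-locus labels for unannotated partners) and grouped
into fusion genes.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .annotation import AnnotationIndex
from .model import (
    STRAND_FWD,
    STRAND_REV,
    STRAND_UNKNOWN,
    DetectionConfig,
    FilterFlags,
    FragmentAlignment,
    FusionCandidate,
    LongReadAlignmentSet,
)
from .seq import fetch

MIN_SPLICE_GAP = 68  # alignment gaps longer than this are treated as splices


def splice_gaps(frag: FragmentAlignment, min_splice_gap: int = MIN_SPLICE_GAP) -> list[tuple[int, int]]:
    """(donor, acceptor) pairs of the fragment's gaps long enough to be splices."""
    return [(d, a) for d, a in frag.gaps if a - d - 1 > min_splice_gap]


# ---------------------------------------------------------------------------
# structural conditions (i)-(iv)
# ---------------------------------------------------------------------------

def _locus_separation_ok(
    a: FragmentAlignment,
    b: FragmentAlignment,
    cfg: DetectionConfig,
    annotation: AnnotationIndex | None,
) -> bool:
    if a.chrom != b.chrom:
        return True
    gap = max(a.genome_span.start, b.genome_span.start) - min(a.genome_span.end, b.genome_span.end)
    if gap >= cfg.min_intrachrom_distance:
        return True
    if annotation is not None:
        genes_a = set(annotation.gene_names_overlapping(a.chrom, a.genome_span.start, a.genome_span.end))
        genes_b = set(annotation.gene_names_overlapping(b.chrom, b.genome_span.start, b.genome_span.end))
        # two different annotated genes override the distance threshold
        if genes_a and genes_b and not (genes_a & genes_b):
            return True
    return False


def enumerate_candidate_pairs(
    aln: LongReadAlignmentSet,
    cfg: DetectionConfig | None = None,
    annotation: AnnotationIndex | None = None,
) -> list[FusionCandidate]:
    """All fragment pairs of one read passing structural conditions (i)-(iv).

    Pairs are ordered by position on the read (left precedes right).  Each
    returned candidate's ``flags`` records the outcome of every condition;
    only candidates with all four structural flags set are returned.
    """
    cfg = cfg or DetectionConfig()
    out: list[FusionCandidate] = []
    frags = sorted(aln.fragments, key=lambda f: f.read_start)
    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            left, right = frags[i], frags[j]
            flags = FilterFlags()
            flags.length_ok = (
                left.read_span_len > cfg.min_fragment_len
                and right.read_span_len > cfg.min_fragment_len
            )
            flags.locus_separation_ok = _locus_separation_ok(left, right, cfg, annotation)
            overlap = min(left.read_end, right.read_end) - max(left.read_start, right.read_start)
            flags.overlap_ok = overlap <= cfg.max_fragment_overlap
            unaligned = right.read_start - left.read_end
            flags.unaligned_gap_ok = unaligned <= cfg.max_unaligned_gap
            if flags.length_ok and flags.locus_separation_ok and flags.overlap_ok and flags.unaligned_gap_ok:
                out.append(FusionCandidate(read_id=aln.read_id, left=left, right=right, flags=flags))
    return out


# ---------------------------------------------------------------------------
# identity-difference filter
# ---------------------------------------------------------------------------

def identity_difference_filter(
    cand: FusionCandidate,
    alternatives: dict[int, list[FragmentAlignment]] | LongReadAlignmentSet,
    cfg: DetectionConfig | None = None,
) -> bool:
    """Reject candidates whose fragments align ambiguously.

    A fragment is ambiguous when the identity gap between its best and
    second-best alignment is below the threshold.  Fragments without an
    alternative alignment pass.  Returns True (pass) / False (filtered out)
    and records the outcome in ``cand.flags``.
    """
    cfg = cfg or DetectionConfig()
    if isinstance(alternatives, LongReadAlignmentSet):
        alt_map = {
            id(alternatives.fragments[i]): alts
            for i, alts in alternatives.alternatives.items()
            if i < len(alternatives.fragments)
        }
        lookup = lambda frag: alt_map.get(id(frag), [])
    else:
        lookup = lambda frag: alternatives.get(id(frag), [])

    ok = True
    for frag in (cand.left, cand.right):
        alts = lookup(frag)
        if not alts:
            continue
        second = max(a.identity for a in alts)
        if frag.identity - second < cfg.identity_diff_threshold:
            ok = False
            break
    cand.flags.identity_diff_ok = ok
    return ok


# ---------------------------------------------------------------------------
# strand determination and consistency
# ---------------------------------------------------------------------------

def determine_transcript_strand(
    frag: FragmentAlignment,
    genome,
    annotation: AnnotationIndex | None,
    min_splice_gap: int = MIN_SPLICE_GAP,
) -> str:
    """Genomic strand of the transcript a fragment comes from.

    Priority: canonical GT-AG / CT-AC motifs at the fragment's splice gaps;
    else the strand of an overlapping annotated gene; else unknown.
    """
    votes = {STRAND_FWD: 0, STRAND_REV: 0}
    if genome is not None:
        for donor, acceptor in splice_gaps(frag, min_splice_gap):
            left2 = fetch(genome, frag.chrom, donor + 1, donor + 3)
            right2 = fetch(genome, frag.chrom, acceptor - 2, acceptor)
            if left2 == "GT" and right2 == "AG":
                votes[STRAND_FWD] += 1
            elif left2 == "CT" and right2 == "AC":
                votes[STRAND_REV] += 1
    if votes[STRAND_FWD] != votes[STRAND_REV]:
        return STRAND_FWD if votes[STRAND_FWD] > votes[STRAND_REV] else STRAND_REV
    if annotation is not None:
        strands = {
            m.strand
            for m in annotation.genes_overlapping(frag.chrom, frag.genome_span.start, frag.genome_span.end)
        }
        if len(strands) == 1:
            return strands.pop()
    return STRAND_UNKNOWN


def strand_consistency_filter(
    cand: FusionCandidate,
    annotation: AnnotationIndex | None = None,
    genome=None,
) -> bool:
    """Require both fragments to traverse their source transcripts in the same
    direction along the read.

    A fragment reads its transcript forward when its alignment orientation
    matches the transcript strand.  Fragments with unknown strand inherit the
    partner's direction.  When both fragments read in reverse, the read is the
    reverse complement of the fusion transcript: the pair passes and the
    5'/3' roles of the fragments are swapped.
    """
    t_left = determine_transcript_strand(cand.left, genome, annotation)
    t_right = determine_transcript_strand(cand.right, genome, annotation)

    def direction(frag: FragmentAlignment, tstrand: str) -> str:
        if tstrand == STRAND_UNKNOWN:
            return STRAND_UNKNOWN
        return STRAND_FWD if frag.genome_span.strand == tstrand else STRAND_REV

    d_left = direction(cand.left, t_left)
    d_right = direction(cand.right, t_right)
    known = [d for d in (d_left, d_right) if d != STRAND_UNKNOWN]
    ok = len(set(known)) <= 1
    cand.flags.strand_ok = ok
    if ok:
        agreed = known[0] if known else STRAND_FWD
        cand.swapped = agreed == STRAND_REV
        if cand.swapped:
            cand.strand5, cand.strand3 = t_right, t_left
        else:
            cand.strand5, cand.strand3 = t_left, t_right
        # an unknown fragment inherits a strand consistent with the partner's
        # direction and its own alignment orientation
        for which, tstrand, frag in (("5", cand.strand5, cand.frag5), ("3", cand.strand3, cand.frag3)):
            if tstrand == STRAND_UNKNOWN:
                inherited = (
                    frag.genome_span.strand
                    if agreed == STRAND_FWD
                    else (STRAND_REV if frag.genome_span.strand == STRAND_FWD else STRAND_FWD)
                )
                if which == "5":
                    cand.strand5 = inherited
                else:
                    cand.strand3 = inherited
    return ok


# ---------------------------------------------------------------------------
# gene labels and grouping
# ---------------------------------------------------------------------------

def locus_label(chrom: str, start0: int) -> str:
    """Genomic-locus label for an unannotated fragment, 1-based."""
    return f"{chrom}:{start0 + 1}"


def _label_fragment(frag: FragmentAlignment, annotation: AnnotationIndex | None) -> str:
    if annotation is not None:
        for donor, acceptor in splice_gaps(frag):
            genes = annotation.genes_at_intron(frag.chrom, donor, acceptor)
            if genes:
                return genes[0].gene_name
        names = annotation.gene_names_overlapping(frag.chrom, frag.genome_span.start, frag.genome_span.end)
        if names:
            return names[0]
    return locus_label(frag.chrom, frag.genome_span.start)


def assign_gene_labels(cand: FusionCandidate, annotation: AnnotationIndex | None = None) -> FusionCandidate:
    """Label the 5' and 3' fragments with gene names, falling back to
    genomic-locus labels for unannotated loci."""
    cand.gene5_label = _label_fragment(cand.frag5, annotation)
    cand.gene3_label = _label_fragment(cand.frag3, annotation)
    return cand


@dataclass
class FusionGeneGroup:
    """Candidates sharing one unordered (gene5, gene3) label pair."""

    gene5_label: str
    gene3_label: str
    candidates: list[FusionCandidate] = field(default_factory=list)

    @property
    def n_long_reads(self) -> int:
        return len({c.read_id for c in self.candidates})

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene5_label, self.gene3_label))


def _cluster_locus_labels(labels: list[str], window: int) -> dict[str, str]:
    """Single-linkage clustering of genomic-locus labels within ``window`` bp
    on the same chromosome; maps each label to its cluster representative."""
    per_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for lab in labels:
        chrom, _, pos = lab.rpartition(":")
        per_chrom[chrom].append((int(pos), lab))
    mapping: dict[str, str] = {}
    for chrom, items in per_chrom.items():
        items.sort()
        rep_pos, rep = items[0]
        prev_pos = items[0][0]
        for pos, lab in items:
            if pos - prev_pos > window:
                rep_pos, rep = pos, lab
            mapping[lab] = rep
            prev_pos = pos
    return mapping


def group_candidates_to_fusion_genes(
    cands: list[FusionCandidate],
    locus_window: int = 100_000,
) -> list[FusionGeneGroup]:
    """Group labeled candidates into fusion genes by unordered label pair.

    Genomic-locus labels within ``locus_window`` bp on one chromosome are
    treated as the same locus.
    """
    locus_labels = [
        lab
        for c in cands
        for lab in (c.gene5_label, c.gene3_label)
        if lab and ":" in lab
    ]
    mapping = _cluster_locus_labels(locus_labels, locus_window)

    groups: dict[frozenset, FusionGeneGroup] = {}
    for c in cands:
        g5 = mapping.get(c.gene5_label, c.gene5_label)
        g3 = mapping.get(c.gene3_label, c.gene3_label)
        key = frozenset((g5, g3))
        if key not in groups:
            groups[key] = FusionGeneGroup(gene5_label=g5, gene3_label=g3)
        groups[key].candidates.append(c)
    return list(groups.values())


def detect_candidates(
    alns,
    cfg: DetectionConfig | None = None,
    annotation: AnnotationIndex | None = None,
    genome=None,
) -> list[FusionCandidate]:
    """Full candidate detection over a stream of long-read alignment sets:
    structural conditions, identity-difference filter, strand consistency,
    gene labeling."""
    cfg = cfg or DetectionConfig()
    out: list[FusionCandidate] = []
    for aln in alns:
        for cand in enumerate_candidate_pairs(aln, cfg, annotation):
            if not identity_difference_filter(cand, aln, cfg):
                continue
            if not strand_consistency_filter(cand, annotation, genome):
                continue
            assign_gene_labels(cand, annotation)
            out.append(cand)
    return out
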