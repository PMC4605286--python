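"""Artificial Reference Sequences (ARSs).

An ARS concatenates the two genomic windows flanking a candidate fusion
junction — each fragment's aligned span extended by a flank (default 2000 bp)
past its junction-proximal end — into one sequence that a splice-aware
short-read aligner can treat as a reference.  The true fusion site then
appears as an artificial intron spanning the concatenation boundary.  ARSs
from the same fusion locus are merged by span union so short reads are not
scattered over redundant references.

Each region is emitted in transcript orientation (reverse-complemented when
the determined transcript strand is '-'), so the fusion junction is always a
forward splice in ARS space.  Exact bidirectional coordinate maps between ARS
and genome space are provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model import STRAND_FWD, STRAND_REV, STRAND_UNKNOWN, FusionCandidate, GenomeInterval
from .seq import chrom_length, fetch, revcomp

DEFAULT_FLANK = 2000


@dataclass
class ARS:
    """Two extended genomic windows concatenated into one reference sequence.

    ``left_region``/``right_region`` carry the *transcript* strand of each
    side; the stored sequence is already oriented so position 0 is the 5'-most
    transcript base of the left region and the boundary starts the right
    region.
    """

    ars_id: str
    left_region: GenomeInterval
    right_region: GenomeInterval
    sequence: str
    source_candidates: list[FusionCandidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.left_region) + len(self.right_region):
            raise ValueError("ARS sequence length must equal the sum of region lengths")

    @property
    def boundary(self) -> int:
        """ARS offset of the first base of the right region."""
        return len(self.left_region)

    def __len__(self) -> int:
        return len(self.sequence)


def _extend_region(
    span: GenomeInterval,
    tstrand: str,
    proximal: str,
    flank: int,
    genome,
) -> GenomeInterval:
    """Extend a fragment's genomic span by ``flank`` bp past its
    junction-proximal end, clipped at chromosome edges.

    ``proximal`` is "3p" for the left (5'-gene) fragment — the junction sits at
    the transcript 3' end of the fragment — and "5p" for the right fragment.
    """
    clen = chrom_length(genome, span.chrom)
    extend_right = (tstrand != STRAND_REV) == (proximal == "3p")
    if extend_right:
        return GenomeInterval(span.chrom, span.start, min(span.end + flank, clen), tstrand)
    return GenomeInterval(span.chrom, max(span.start - flank, 0), span.end, tstrand)


def _region_seq(region: GenomeInterval, genome) -> str:
    s = fetch(genome, region.chrom, region.start, region.end)
    return revcomp(s) if region.strand == STRAND_REV else s


def build_ars(
    cand: FusionCandidate,
    genome,
    flank: int = DEFAULT_FLANK,
    ars_id: str = "ARS",
) -> ARS:
    """Build the ARS of one fusion candidate.

    The 5'-gene fragment becomes the left region, extended toward the
    junction; the 3'-gene fragment becomes the right region, extended
    likewise.  Fragments with unknown transcript strand are taken as '+'.
    """
    s5 = cand.strand5 if cand.strand5 != STRAND_UNKNOWN else STRAND_FWD
    s3 = cand.strand3 if cand.strand3 != STRAND_UNKNOWN else STRAND_FWD
    left = _extend_region(cand.frag5.genome_span, s5, "3p", flank, genome)
    right = _extend_region(cand.frag3.genome_span, s3, "5p", flank, genome)
    seq = _region_seq(left, genome) + _region_seq(right, genome)
    return ARS(ars_id=ars_id, left_region=left, right_region=right, sequence=seq,
               source_candidates=[cand])


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _regions_compatible(a: GenomeInterval, b: GenomeInterval) -> bool:
    return a.chrom == b.chrom and a.strand == b.strand and a.start < b.end and b.start < a.end


def mergeable(a: ARS, b: ARS) -> bool:
    """Two ARSs come from the same fusion locus when both their left and their
    right regions overlap on matching chromosome and strand."""
    return _regions_compatible(a.left_region, b.left_region) and _regions_compatible(
        a.right_region, b.right_region
    )


def merge_ars(arss: list[ARS], genome) -> list[ARS]:
    """Merge redundant ARSs from the same fusion locus.

    One pass unions the spans of all ARSs connected in the mergeability
    graph; because a widened span can overlap ARSs it previously missed,
    passes repeat until no mergeable pair remains.  Idempotent and
    order-independent.
    """
    merged = list(arss)
    while True:
        nxt = _merge_pass(merged, genome)
        if len(nxt) == len(merged):
            return nxt
        merged = nxt


def _merge_pass(arss: list[ARS], genome) -> list[ARS]:
    n = len(arss)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = find(i), find(j)
            if ri != rj and mergeable(arss[i], arss[j]):
                parent[rj] = ri

    groups: dict[int, list[ARS]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(arss[i])

    merged: list[ARS] = []
    for k, members in enumerate(sorted(groups.values(), key=lambda g: g[0].ars_id)):
        if len(members) == 1:
            merged.append(members[0])
            continue
        left = GenomeInterval(
            members[0].left_region.chrom,
            min(m.left_region.start for m in members),
            max(m.left_region.end for m in members),
            members[0].left_region.strand,
        )
        right = GenomeInterval(
            members[0].right_region.chrom,
            min(m.right_region.start for m in members),
            max(m.right_region.end for m in members),
            members[0].right_region.strand,
        )
        seq = _region_seq(left, genome) + _region_seq(right, genome)
        cands = [c for m in members for c in m.source_candidates]
        merged.append(
            ARS(
                ars_id=members[0].ars_id,
                left_region=left,
                right_region=right,
                sequence=seq,
                source_candidates=cands,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# coordinate maps
# ---------------------------------------------------------------------------

def ars_to_genome(ars: ARS, pos: int) -> tuple[str, int, str]:
    """Map an ARS position to (chrom, genome position, transcript strand)."""
    if not 0 <= pos < len(ars):
        raise ValueError(f"ARS position {pos} out of range [0, {len(ars)})")
    if pos < ars.boundary:
        region, off = ars.left_region, pos
    else:
        region, off = ars.right_region, pos - ars.boundary
    if region.strand == STRAND_REV:
        g = region.end - 1 - off
    else:
        g = region.start + off
    return region.chrom, g, region.strand


def genome_to_ars(ars: ARS, chrom: str, gpos: int, side: str | None = None) -> int:
    """Inverse of :func:`ars_to_genome`.  ``side`` ("left"/"right")
    disambiguates same-chromosome fusions whose regions overlap."""
    candidates = []
    if side in (None, "left"):
        candidates.append((ars.left_region, 0))
    if side in (None, "right"):
        candidates.append((ars.right_region, ars.boundary))
    for region, base in candidates:
        if region.chrom == chrom and region.start <= gpos < region.end:
            off = (region.end - 1 - gpos) if region.strand == STRAND_REV else (gpos - region.start)
            return base + off
    raise ValueError(f"{chrom}:{gpos} not covered by ARS {ars.ars_id} (side={side})")


def project_blocks_to_ars(
    ars: ARS,
    blocks: list[tuple[str, int, int]],
    side: str,
) -> list[tuple[int, int]]:
    """Project genomic exon blocks [(chrom, start, end), ...] of one region
    into ARS coordinates.  Returns sorted [start, end) ARS intervals."""
    out = []
    for chrom, s, e in blocks:
        a1 = genome_to_ars(ars, chrom, s, side)
        a2 = genome_to_ars(ars, chrom, e - 1, side)
        out.append((min(a1, a2), max(a1, a2) + 1))
    return sorted(out)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

REGIONS_SUFFIX = ".regions.tsv"


def write_ars_fasta(arss: list[ARS], path: str | Path) -> None:
    """Write ARS sequences as FASTA plus a sidecar region table
    (``<path>.regions.tsv``) from which coordinate maps can be rebuilt."""
    from .io import write_fasta

    write_fasta(((a.ars_id, a.sequence) for a in arss), path)
    with open(str(path) + REGIONS_SUFFIX, "w") as fh:
        fh.write(
            "ars_id\tchrom5\tstart5\tend5\tstrand5\tchrom3\tstart3\tend3\tstrand3\tboundary\n"
        )
        for a in arss:
            l, r = a.left_region, a.right_region
            fh.write(
                f"{a.ars_id}\t{l.chrom}\t{l.start}\t{l.end}\t{l.strand}"
                f"\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{a.boundary}\n"
            )


def read_ars_fasta(path: str | Path) -> list[ARS]:
    """Reload ARSs written by :func:`write_ars_fasta`."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
        if name is not None:
            seqs[name] = "".join(parts)

    arss = []
    with open(str(path) + REGIONS_SUFFIX) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            arss.append(
                ARS(
                    ars_id=f[0],
                    left_region=GenomeInterval(f[1], int(f[2]), int(f[3]), f[4]),
                    right_region=GenomeInterval(f[5], int(f[6]), int(f[7]), f[8]),
                    sequence=seqs[f[0]],
                )
            )
    return arss
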