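"""Synthetic transcriptome generator with ground truth.

Emulates the data regime the pipeline targets: a multi-chromosome genome
carrying multi-isoform gene models with GT-AG introns, inter- and
intra-chromosomal fusion events joining a 5' prefix of one gene to a 3'
suffix of another at one or more fusion splices, long reads sampled from
isoforms with configurable substitution/indel noise and polyA tails, and
spliced short reads at configurable depth.  Truth alignments are emitted
directly (SAM with N-gaps at introns and split primary + supplementary
records at fusion junctions), so every pipeline stage is testable without
external aligners.  All outputs are byte-reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .io import write_fasta
from .model import STRAND_REV, GeneModel, GenomeInterval
from .seq import revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulation run."""

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (200, 2000)  # min must exceed 68
    isoforms_per_gene: tuple[int, int] = (1, 3)
    n_fusions: int = 5
    fusion_splices_per_fusion: tuple[int, int] = (1, 3)
    long_read_depth: int = 5  # long reads per isoform
    long_read_sub_rate: float = 0.01
    long_read_ins_rate: float = 0.01
    long_read_del_rate: float = 0.01
    short_read_length: int = 101
    short_read_depth: int = 30  # mean short-read coverage per expressed base
    polya_tail_len: int = 12
    intergenic_gap: tuple[int, int] = (5_000, 20_000)
    min_intrachrom_fusion_distance: int = 100_000

    def __post_init__(self) -> None:
        if self.intron_length[0] <= 68:
            raise ValueError("minimum intron length must exceed 68 bp")
        for r in (self.long_read_sub_rate, self.long_read_ins_rate, self.long_read_del_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must be in [0, 1)")


@dataclass
class TrueIsoform:
    """One expressed transcript with its genomic structure and abundance."""

    isoform_id: str
    gene_labels: tuple[str, ...]
    # one (chrom, strand, exons) block for regular isoforms, two for fusion
    segments: list[tuple[str, str, list[tuple[int, int]]]]
    theta: float  # expected short reads per transcript base
    is_fusion: bool = False
    fusion_splice: Optional[tuple[str, int, str, int]] = None  # chrom5, pos5, chrom3, pos3

    @property
    def length(self) -> int:
        return sum(e - s for _, _, exons in self.segments for s, e in exons)

    def sequence(self, genome: dict[str, str]) -> str:
        parts = []
        for chrom, strand, exons in self.segments:
            seq = "".join(genome[chrom][s:e] for s, e in exons)
            parts.append(revcomp(seq) if strand == STRAND_REV else seq)
        return "".join(parts)

    def transcript_map(self) -> list[tuple[str, str, int, int]]:
        """Exons in transcript order as (chrom, strand, genome_start, length);
        for '-' segments exons run right-to-left."""
        out = []
        for chrom, strand, exons in self.segments:
            ordered = exons if strand != STRAND_REV else list(reversed(exons))
            for s, e in ordered:
                out.append((chrom, strand, s, e - s))
        return out


@dataclass
class FusionEvent:
    gene5: str
    gene3: str
    splices: list[tuple[str, int, str, int]] = field(default_factory=list)


@dataclass
class TruthSet:
    genome: dict[str, str]
    genes: list[GeneModel]
    isoforms: list[TrueIsoform] = field(default_factory=list)
    fusions: list[FusionEvent] = field(default_factory=list)
    read_provenance: dict[str, str] = field(default_factory=dict)  # read_id -> isoform_id


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(cfg: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Random chromosomes with non-overlapping multi-isoform genes whose
    introns all carry GT-AG signals on the gene strand."""
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = {
        f"chr{i + 1}": rng.choice(BASES, size=cfg.chrom_length)
        for i in range(cfg.n_chroms)
    }

    genes: list[GeneModel] = []
    cursors = {c: 0 for c in chroms}
    chrom_names = sorted(chroms)
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
        intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1)
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        start = cursors[chrom] + gap
        span = int(exon_lens.sum() + intron_lens.sum())
        if start + span > cfg.chrom_length:
            raise ValueError(f"gene g{g + 1} does not fit on {chrom}")
        cursors[chrom] = start + span
        strand = "+" if rng.random() < 0.5 else "-"

        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                il = int(intron_lens[i])
                arr = chroms[chrom]
                if strand == "+":
                    arr[pos], arr[pos + 1] = "G", "T"
                    arr[pos + il - 2], arr[pos + il - 1] = "A", "G"
                else:
                    arr[pos], arr[pos + 1] = "C", "T"
                    arr[pos + il - 2], arr[pos + il - 1] = "A", "C"
                pos += il
        name = f"g{g + 1}"
        genes.append(
            GeneModel(
                gene_name=name,
                isoform_name=f"{name}.t1",
                interval=GenomeInterval(chrom, start, pos, strand),
                exons=exons,
                source="sim",
            )
        )

    genome = {c: "".join(arr) for c, arr in chroms.items()}
    truth = TruthSet(genome=genome, genes=genes)

    # expressed regular isoforms: the full chain plus exon-skipping variants
    for gm in genes:
        n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
        chains = [gm.exons]
        internal = list(range(1, len(gm.exons) - 1))
        rng.shuffle(internal)
        for k in range(min(n_iso - 1, len(internal))):
            skip = internal[k]
            chains.append([e for i, e in enumerate(gm.exons) if i != skip])
        for t, chain in enumerate(chains):
            theta = cfg.short_read_depth / cfg.short_read_length * float(rng.lognormal(0.0, 1.0))
            truth.isoforms.append(
                TrueIsoform(
                    isoform_id=f"{gm.gene_name}.i{t + 1}",
                    gene_labels=(gm.gene_name,),
                    segments=[(gm.interval.chrom, gm.strand, list(chain))],
                    theta=theta,
                )
            )
    return truth


def simulate_fusions(truth: TruthSet, cfg: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Add fusion events joining a 5' exon prefix of one gene to a 3' exon
    suffix of another, at 1-6 distinct fusion splices per event.

    Fusion junctions sit at existing exon boundaries, so the genomic flanks
    carry the genes' own GT / AG intron signals in transcript orientation
    (canonical fusion splices).  Intra-chromosomal partners are at least
    ``min_intrachrom_fusion_distance`` apart.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    eligible = [g for g in truth.genes if len(g.exons) >= 3]
    order = list(range(len(eligible)))
    rng.shuffle(order)
    used: set[str] = set()
    pairs: list[tuple[GeneModel, GeneModel]] = []
    for i in order:
        if len(pairs) >= cfg.n_fusions:
            break
        a = eligible[i]
        if a.gene_name in used:
            continue
        for j in order:
            b = eligible[j]
            if b.gene_name in used or b.gene_name == a.gene_name:
                continue
            if a.interval.chrom == b.interval.chrom:
                gap = max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end)
                if gap < cfg.min_intrachrom_fusion_distance:
                    continue
            pairs.append((a, b))
            used.add(a.gene_name)
            used.add(b.gene_name)
            break
    if len(pairs) < cfg.n_fusions:
        raise ValueError("not enough eligible gene pairs for the requested fusions")

    for a, b in pairs:
        k = int(rng.integers(cfg.fusion_splices_per_fusion[0], cfg.fusion_splices_per_fusion[1] + 1))
        # donor after exon i of the 5' gene (an intron must follow),
        # acceptor at exon j of the 3' gene (an intron must precede)
        donors = list(range(len(a.exons) - 1))
        acceptors = list(range(1, len(b.exons)))
        combos = [(i, j) for i in donors for j in acceptors]
        rng.shuffle(combos)
        event = FusionEvent(gene5=a.gene_name, gene3=b.gene_name)
        for i, j in combos[:k]:
            # transcript-order prefix of a, suffix of b
            if a.strand == "-":
                exons5 = a.exons[-(i + 1):]
                pos5 = exons5[0][0]
            else:
                exons5 = a.exons[: i + 1]
                pos5 = exons5[-1][1] - 1
            if b.strand == "-":
                exons3 = b.exons[: len(b.exons) - j]
                pos3 = exons3[-1][1] - 1
            else:
                exons3 = b.exons[j:]
                pos3 = exons3[0][0]
            key = (a.interval.chrom, pos5, b.interval.chrom, pos3)
            event.splices.append(key)
            theta = cfg.short_read_depth / cfg.short_read_length * float(rng.lognormal(0.0, 1.0))
            truth.isoforms.append(
                TrueIsoform(
                    isoform_id=f"{a.gene_name}-{b.gene_name}.fs{len(event.splices)}",
                    gene_labels=(a.gene_name, b.gene_name),
                    segments=[
                        (a.interval.chrom, a.strand, list(exons5)),
                        (b.interval.chrom, b.strand, list(exons3)),
                    ],
                    theta=theta,
                    is_fusion=True,
                    fusion_splice=key,
                )
            )
        truth.fusions.append(event)
    return truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _mutate_exon(seq: str, rng, sub: float, ins: float, dele: float):
    """Apply errors to one exon's transcript-orientation sequence; returns
    (read piece, cigar ops [(op_char, length)], nm)."""
    if sub == ins == dele == 0:
        return seq, [("M", len(seq))], 0
    out = []
    ops: list[list] = []
    nm = 0

    def push(op, n=1):
        if ops and ops[-1][0] == op:
            ops[-1][1] += n
        else:
            ops.append([op, n])

    for ch in seq:
        r = rng.random()
        if r < dele:
            push("D")
            nm += 1
            continue
        if r < dele + ins:
            out.append(str(rng.choice(BASES)))
            push("I")
            nm += 1
            out.append(ch)
            push("M")
            continue
        if r < dele + ins + sub:
            alt = str(rng.choice(BASES))
            while alt == ch:
                alt = str(rng.choice(BASES))
            out.append(alt)
            nm += 1
        else:
            out.append(ch)
        push("M")
    return "".join(out), [(op, n) for op, n in ops], nm


_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}


def _segment_alignment(chrom, strand, exons, genome, rng, sub, ins, dele):
    """Simulate one fragment: transcript-orientation read piece plus the
    reference-order CIGAR and reference start for a SAM record."""
    ordered = exons if strand != STRAND_REV else list(reversed(exons))
    t_ops: list[tuple[str, int]] = []
    piece_parts = []
    nm = 0
    for idx, (s, e) in enumerate(ordered):
        exon_seq = genome[chrom][s:e]
        if strand == STRAND_REV:
            exon_seq = revcomp(exon_seq)
        p, ops, n = _mutate_exon(exon_seq, rng, sub, ins, dele)
        piece_parts.append(p)
        t_ops.extend(ops)
        nm += n
        if idx < len(ordered) - 1:
            ns, ne = ordered[idx + 1]
            gap = (ns - e) if strand != STRAND_REV else (s - ne)
            t_ops.append(("N", gap))
    piece = "".join(piece_parts)
    ref_ops = list(reversed(t_ops)) if strand == STRAND_REV else t_ops
    ref_start = min(s for s, _ in exons)
    return piece, ref_ops, ref_start, nm


def _write_sam_records(out, read_id, read_seq, parts):
    """Emit one SAM record per fragment; the first is primary, the rest
    supplementary.  ``parts`` items: (chrom, strand, ref_ops, ref_start,
    read_start, read_end, nm)."""
    for k, (chrom, strand, ref_ops, ref_start, r_start, r_end, nm) in enumerate(parts):
        a = pysam.AlignedSegment(out.header)
        a.query_name = read_id
        rev = strand == STRAND_REV
        flag = 0
        if rev:
            flag |= 16
        if k > 0:
            flag |= 2048
        a.flag = flag
        a.reference_id = out.header.references.index(chrom)
        a.reference_start = ref_start
        a.mapping_quality = 60
        total = len(read_seq)
        if rev:
            pre, post = total - r_end, r_start
            seq = revcomp(read_seq)
        else:
            pre, post = r_start, total - r_end
            seq = read_seq
        cig = []
        if pre:
            cig.append((4, pre))
        cig.extend((_OP_CODE[op], n) for op, n in ref_ops)
        if post:
            cig.append((4, post))
        a.cigartuples = cig
        a.query_sequence = seq
        a.set_tag("NM", nm)
        out.write(a)


def simulate_long_reads(truth: TruthSet, cfg: SimConfig, rng, fasta_path, sam_path) -> None:
    """Sample ``long_read_depth`` full-length reads per isoform with noise and
    a polyA tail; truth SAM has N-gaps at introns and split primary +
    supplementary records at fusion junctions."""
    header = pysam.AlignmentHeader.from_references(
        sorted(truth.genome), [len(truth.genome[c]) for c in sorted(truth.genome)]
    )
    reads: list[tuple[str, str]] = []
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for iso in truth.isoforms:
            for r in range(cfg.long_read_depth):
                read_id = f"LR_{iso.isoform_id}_{r + 1}"
                parts = []
                pieces = []
                offset = 0
                for chrom, strand, exons in iso.segments:
                    piece, ref_ops, ref_start, nm = _segment_alignment(
                        chrom, strand, exons, truth.genome, rng,
                        cfg.long_read_sub_rate, cfg.long_read_ins_rate, cfg.long_read_del_rate,
                    )
                    parts.append([chrom, strand, ref_ops, ref_start, offset, offset + len(piece), nm])
                    pieces.append(piece)
                    offset += len(piece)
                read_seq = "".join(pieces) + "A" * cfg.polya_tail_len
                _write_sam_records(out, read_id, read_seq, [tuple(p) for p in parts])
                reads.append((read_id, read_seq))
                truth.read_provenance[read_id] = iso.isoform_id
    write_fasta(reads, fasta_path)


def _transcript_to_blocks(iso: TrueIsoform, t_start: int, t_end: int) -> list[tuple[str, int, int, str]]:
    """Genome blocks (chrom, start, end, strand) in transcript order of
    transcript interval [t_start, t_end)."""
    blocks = []
    pos = 0
    for chrom, strand, g_start, length in iso.transcript_map():
        lo, hi = max(t_start, pos), min(t_end, pos + length)
        if lo < hi:
            if strand == STRAND_REV:
                s = g_start + (pos + length - hi)
                e = g_start + (pos + length - lo)
            else:
                s = g_start + (lo - pos)
                e = g_start + (hi - pos)
            blocks.append((chrom, s, e, strand))
        pos += length
    return blocks


def simulate_short_reads(truth: TruthSet, cfg: SimConfig, rng, table_path, sam_path=None):
    """Error-free spliced short reads sampled per isoform at rate
    theta * (L - read_length + 1); the truth table records each read's exact
    genome blocks in transcript order."""
    rl = cfg.short_read_length
    rows = []
    for iso in truth.isoforms:
        L = iso.length
        if L < rl:
            continue
        n = int(rng.poisson(iso.theta * (L - rl + 1)))
        if n == 0:
            continue
        starts = rng.integers(0, L - rl + 1, size=n)
        for k, t0 in enumerate(sorted(starts.tolist())):
            read_id = f"SR_{iso.isoform_id}_{k + 1}"
            blocks = _transcript_to_blocks(iso, t0, t0 + rl)
            rows.append((read_id, iso.isoform_id, blocks))
            truth.read_provenance[read_id] = iso.isoform_id
    with open(table_path, "w") as fh:
        fh.write("read_id\tisoform_id\tblocks\n")
        for read_id, iso_id, blocks in rows:
            bstr = ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in blocks)
            fh.write(f"{read_id}\t{iso_id}\t{bstr}\n")
    if sam_path is not None:
        _write_short_sam(truth, rows, sam_path)
    return rows


def _write_short_sam(truth: TruthSet, rows, sam_path) -> None:
    """Genome-space truth SAM for short reads; reads spanning a fusion
    junction yield one record per chromosome side."""
    header = pysam.AlignmentHeader.from_references(
        sorted(truth.genome), [len(truth.genome[c]) for c in sorted(truth.genome)]
    )
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for read_id, _, blocks in rows:
            sides: list[list[tuple[str, int, int, str]]] = []
            for b in blocks:
                if sides:
                    p = sides[-1][-1]
                    same = p[0] == b[0] and p[3] == b[3]
                    if same and b[3] != STRAND_REV and 0 <= b[1] - p[2] <= 400_000:
                        sides[-1].append(b)
                        continue
                    if same and b[3] == STRAND_REV and 0 <= p[1] - b[2] <= 400_000:
                        sides[-1].append(b)
                        continue
                sides.append([b])
            for k, side in enumerate(sides):
                rev = side[0][3] == STRAND_REV
                genomic = list(reversed(side)) if rev else side
                a = pysam.AlignedSegment(header)
                a.query_name = read_id
                a.flag = (16 if rev else 0) | (2048 if k > 0 else 0)
                a.reference_id = out.header.references.index(genomic[0][0])
                a.reference_start = genomic[0][1]
                a.mapping_quality = 60
                cig = []
                for i, (c, s, e, _) in enumerate(genomic):
                    if i > 0:
                        cig.append((3, s - genomic[i - 1][2]))
                    cig.append((0, e - s))
                a.cigartuples = cig
                a.set_tag("NM", 0)
                out.write(a)


def read_short_read_table(path) -> list[tuple[str, str, list[tuple[str, int, int, str]]]]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            read_id, iso_id, bstr = line.rstrip("\n").split("\t")
            blocks = []
            for item in bstr.split(";"):
                parts = item.split(":")
                if len(parts) == 3:
                    chrom, span, strand = parts
                else:  # legacy strand-less form
                    chrom, span, strand = ":".join(parts[:-1]), parts[-1], "+"
                s, e = span.split("-")
                blocks.append((chrom, int(s), int(e), strand))
            rows.append((read_id, iso_id, blocks))
    return rows


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def write_genepred(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    (
                        g.isoform_name, g.interval.chrom, g.strand,
                        str(g.interval.start), str(g.interval.end),
                        str(g.interval.start), str(g.interval.end),
                        str(len(g.exons)), starts, ends, "0", g.gene_name,
                    )
                )
                + "\n"
            )


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> TruthSet:
    """Run the full generator and write all standard-format outputs:

    genome.fa, annotation.genePred, long_reads.fa, long_reads.sam,
    short_reads.tsv (exact genome blocks per read), short_reads_genome.sam,
    truth_fusions.tsv, truth_isoforms.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_genome_and_genes(cfg, rng)
    if cfg.n_fusions > 0:
        simulate_fusions(truth, cfg, rng)
    write_fasta(sorted(truth.genome.items()), outdir / "genome.fa")
    write_genepred(truth.genes, outdir / "annotation.genePred")
    simulate_long_reads(truth, cfg, rng, outdir / "long_reads.fa", outdir / "long_reads.sam")
    simulate_short_reads(truth, cfg, rng, outdir / "short_reads.tsv", outdir / "short_reads_genome.sam")
    with open(outdir / "truth_fusions.tsv", "w") as fh:
        fh.write("gene5\tgene3\tchrom5\tpos5\tchrom3\tpos3\n")
        for ev in truth.fusions:
            for c5, p5, c3, p3 in ev.splices:
                fh.write(f"{ev.gene5}\t{ev.gene3}\t{c5}\t{p5 + 1}\t{c3}\t{p3 + 1}\n")
    with open(outdir / "truth_isoforms.tsv", "w") as fh:
        fh.write("isoform_id\tgenes\tis_fusion\ttheta\tlength\n")
        for iso in truth.isoforms:
            fh.write(
                f"{iso.isoform_id}\t{','.join(iso.gene_labels)}\t"
                f"{int(iso.is_fusion)}\t{iso.theta:.6f}\t{iso.length}\n"
            )
    return truth
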