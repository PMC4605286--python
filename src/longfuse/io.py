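"""Readers and writers for the standard formats the pipeline touches.

Long-read alignments come in as SAM/BAM (split reads as primary +
supplementary records, alternatives as secondary records) or as PSL-like
tabular output of a spliced long-read aligner.  Annotation comes in as
genePred or GTF.  All conversion between 1-based (file) and 0-based
(in-memory) coordinates happens here and nowhere else.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .model import (
    STRAND_UNKNOWN,
    FragmentAlignment,
    FusionSite,
    GeneModel,
    GenomeInterval,
    LongReadAlignmentSet,
    Splice,
)

logger = logging.getLogger(__name__)

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M I S = X
_TARGET_CONSUMING = {0, 2, 3, 7, 8}  # M D N = X


class FormatError(ValueError):
    """Raised on malformed records; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"line {line}: {message}" if line is not None else message)
        self.line = line


# ---------------------------------------------------------------------------
# long-read alignments
# ---------------------------------------------------------------------------

def _fragment_from_sam(rec: pysam.AlignedSegment) -> FragmentAlignment:
    cig = rec.cigartuples or []
    clip_left = clip_right = 0
    i = 0
    while i < len(cig) and cig[i][0] in (4, 5):  # S H
        clip_left += cig[i][1]
        i += 1
    j = len(cig) - 1
    while j >= 0 and cig[j][0] in (4, 5):
        clip_right += cig[j][1]
        j -= 1
    aligned_query = sum(n for op, n in cig if op in (0, 1, 7, 8))
    read_len = clip_left + clip_right + aligned_query
    if rec.is_reverse:
        read_start, read_end = clip_right, clip_right + aligned_query
    else:
        read_start, read_end = clip_left, clip_left + aligned_query

    target_len = sum(n for op, n in cig if op in _TARGET_CONSUMING)
    try:
        nm = rec.get_tag("NM")
    except KeyError:
        nm = 0
    n_matches = max(target_len - int(nm), 0)
    identity = n_matches / target_len if target_len else 0.0

    # every alignment gap (N, or D of any length) is a candidate splice
    gaps: list[tuple[int, int]] = []
    pos = rec.reference_start
    for op, n in cig:
        if op in (2, 3) and n >= 1:  # D N
            gaps.append((pos - 1, pos + n))
        if op in _TARGET_CONSUMING:
            pos += n

    strand = "-" if rec.is_reverse else "+"
    span = GenomeInterval(rec.reference_name, rec.reference_start, rec.reference_end, strand)
    return FragmentAlignment(
        read_id=rec.query_name,
        read_start=read_start,
        read_end=read_end,
        genome_span=span,
        n_matches=n_matches,
        identity=min(identity, 1.0),
        rank=1 if rec.is_secondary else 0,
        gaps=gaps,
    ), read_len


def _assemble_set(read_id: str, parsed: list[tuple[FragmentAlignment, int]]) -> LongReadAlignmentSet:
    fragments = [f for f, _ in parsed if f.rank == 0]
    secondaries = [f for f, _ in parsed if f.rank > 0]
    read_length = max(length for _, length in parsed)
    aln = LongReadAlignmentSet(read_id=read_id, read_length=read_length, fragments=fragments)
    aln.sort()
    # a secondary record is an alternative of the fragment its read span overlaps most
    for sec in secondaries:
        best_i, best_ov = None, 0
        for i, frag in enumerate(aln.fragments):
            ov = min(frag.read_end, sec.read_end) - max(frag.read_start, sec.read_start)
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i is not None:
            aln.alternatives.setdefault(best_i, []).append(sec)
    for alts in aln.alternatives.values():
        alts.sort(key=lambda f: -f.identity)
        for r, f in enumerate(alts, start=1):
            f.rank = r
    return aln


def _read_sam_long(path: str | Path) -> Iterator[LongReadAlignmentSet]:
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise FormatError("SAM header lacks a sequence dictionary (@SQ lines)")
        groups: dict[str, list] = {}
        order: list[str] = []
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.query_name not in groups:
                groups[rec.query_name] = []
                order.append(rec.query_name)
            groups[rec.query_name].append(_fragment_from_sam(rec))
    for read_id in order:
        yield _assemble_set(read_id, groups[read_id])


def _read_psl_long(path: str | Path) -> Iterator[LongReadAlignmentSet]:
    """GMAP-style PSL: 21 columns, query coords always on the plus strand of
    the read, target block starts always forward-genome."""
    groups: dict[str, list[FragmentAlignment]] = {}
    sizes: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) < 21:
                raise FormatError(f"expected >= 21 PSL columns, got {len(f)}", lineno)
            try:
                matches = int(f[0])
                strand = f[8][-1]
                qname, qsize, qstart, qend = f[9], int(f[10]), int(f[11]), int(f[12])
                tname, tstart, tend = f[13], int(f[15]), int(f[16])
                block_sizes = [int(x) for x in f[18].rstrip(",").split(",")]
                tstarts = [int(x) for x in f[20].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed PSL record: {exc}", lineno)
            target_len = tend - tstart
            gaps = [
                (ts + bs - 1, nts)
                for ts, bs, nts in zip(tstarts, block_sizes, tstarts[1:])
                if nts > ts + bs
            ]
            frag = FragmentAlignment(
                read_id=qname,
                read_start=qstart,
                read_end=qend,
                genome_span=GenomeInterval(tname, tstart, tend, strand),
                n_matches=matches,
                identity=min(matches / target_len, 1.0) if target_len else 0.0,
                gaps=gaps,
            )
            if qname not in groups:
                groups[qname] = []
                order.append(qname)
            groups[qname].append(frag)
            sizes[qname] = max(sizes.get(qname, 0), qsize)
    for read_id in order:
        # cluster alignments by read-span overlap: the best of a cluster is
        # the fragment, the rest are its alternatives
        frags = sorted(groups[read_id], key=lambda f: -f.identity)
        aln = LongReadAlignmentSet(read_id=read_id, read_length=sizes[read_id])
        placed: list[FragmentAlignment] = []
        alts: dict[int, list[FragmentAlignment]] = {}
        for f in frags:
            host = None
            for i, p in enumerate(placed):
                ov = min(p.read_end, f.read_end) - max(p.read_start, f.read_start)
                if ov > 0.5 * min(p.read_span_len, f.read_span_len):
                    host = i
                    break
            if host is None:
                placed.append(f)
            else:
                alts.setdefault(host, []).append(f)
        aln.fragments = placed
        aln.alternatives = alts
        aln.sort()
        for alist in aln.alternatives.values():
            for r, f in enumerate(alist, start=1):
                f.rank = r
        yield aln


def read_long_alignments(path: str | Path, dialect: str = "sam") -> Iterator[LongReadAlignmentSet]:
    """Stream long-read alignment sets from a SAM/BAM or PSL-like file.

    Parameters
    ----------
    dialect : {"sam", "psl"}
        ``sam`` groups primary/supplementary/secondary records by read id;
        ``psl`` clusters overlapping alignments of one read into fragments
        plus alternatives.
    """
    if dialect == "sam":
        yield from _read_sam_long(path)
    elif dialect == "psl":
        yield from _read_psl_long(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _parse_genepred_line(line: str, lineno: int, source: str) -> GeneModel | None:
    f = line.rstrip("\n").split("\t")
    # optionally bin-prefixed (UCSC table dumps)
    if len(f) >= 11 and f[0].lstrip("-").isdigit() and not f[1].lstrip("-").isdigit():
        f = f[1:]
    if len(f) < 10:
        raise FormatError(f"expected >= 10 genePred columns, got {len(f)}", lineno)
    name, chrom, strand = f[0], f[1], f[2]
    tx_start, tx_end = int(f[3]), int(f[4])
    starts = [int(x) for x in f[8].rstrip(",").split(",")]
    ends = [int(x) for x in f[9].rstrip(",").split(",")]
    gene = f[11] if len(f) >= 12 and f[11] else name
    exons = sorted(zip(starts, ends))
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 > s2:
            logger.warning("line %d: overlapping exons in %s, record rejected", lineno, name)
            return None
    return GeneModel(
        gene_name=gene,
        isoform_name=name,
        interval=GenomeInterval(chrom, tx_start, tx_end, strand),
        exons=[(s, e) for s, e in exons],
        source=source,
    )


def _read_gtf(path: str | Path, source: str) -> list[GeneModel]:
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"expected 9 GTF columns, got {len(f)}", lineno)
            if f[2] != "exon":
                continue
            attrs = {}
            for item in f[8].strip().rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError("exon feature lacks transcript_id", lineno)
            rec = tx.setdefault(
                tid,
                {
                    "chrom": f[0],
                    "strand": f[6],
                    "gene": attrs.get("gene_name") or attrs.get("gene_id") or tid,
                    "exons": [],
                },
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))  # GTF is 1-based closed
    models = []
    for tid, rec in tx.items():
        exons = sorted(rec["exons"])
        ok = all(e1 <= s2 for (_, e1), (s2, _) in zip(exons, exons[1:]))
        if not ok:
            logger.warning("overlapping exons in transcript %s, record rejected", tid)
            continue
        models.append(
            GeneModel(
                gene_name=rec["gene"],
                isoform_name=tid,
                interval=GenomeInterval(rec["chrom"], exons[0][0], exons[-1][1], rec["strand"]),
                exons=exons,
                source=source,
            )
        )
    return models


def read_annotation(path: str | Path, fmt: str | None = None, source: str | None = None) -> list[GeneModel]:
    """Load gene models from a genePred or GTF file.

    ``fmt`` is inferred from the extension when omitted.  ``source`` tags each
    model with the library name (defaults to the file stem) so several
    libraries can be pooled.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "genepred"
    src = source or path.stem
    if fmt == "gtf":
        return _read_gtf(path, src)
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            m = _parse_genepred_line(line, lineno, src)
            if m is not None:
                models.append(m)
    return models


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

FUSION_REPORT_COLUMNS = [
    "gene5", "gene3", "chrom5", "pos5", "chrom3", "pos3",
    "strand5", "strand3", "n_long_reads", "n_short_reads", "MSFL", "canonical",
]


def write_fusion_report(sites: Iterable[FusionSite], path: str | Path) -> None:
    """Write fusion sites as TSV with 1-based positions."""
    with open(path, "w") as fh:
        fh.write("\t".join(FUSION_REPORT_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.gene5_label, s.gene3_label,
                        s.chrom5, s.pos5 + 1, s.chrom3, s.pos3 + 1,
                        s.strand5, s.strand3,
                        s.n_long_reads, s.n_short_reads, s.msfl,
                        "yes" if s.canonical else "no",
                    )
                )
                + "\n"
            )


def read_fusion_report(path: str | Path) -> list[FusionSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FUSION_REPORT_COLUMNS:
            raise FormatError("unexpected fusion report header", 1)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                FusionSite(
                    gene5_label=f[0], gene3_label=f[1],
                    chrom5=f[2], pos5=int(f[3]) - 1,
                    chrom3=f[4], pos3=int(f[5]) - 1,
                    strand5=f[6], strand3=f[7],
                    n_long_reads=int(f[8]), n_short_reads=int(f[9]),
                    msfl=int(f[10]), canonical=f[11] == "yes",
                )
            )
    return sites


def write_isoforms_gtf(isoforms, path: str | Path) -> None:
    """Write isoform candidates (with abundance, if estimated) as GTF.

    A fusion isoform is emitted as two transcript blocks (one per locus)
    sharing a transcript id, marked with a ``fusion "true"`` attribute and a
    ``fusion_splice`` attribute carrying the junction coordinates.
    """
    with open(path, "w") as fh:
        for iso in isoforms:
            rpkm = getattr(iso, "rpkm", None)
            rpkm_attr = f' RPKM "{rpkm:.4f}";' if rpkm is not None else ""
            fusion_attr = ' fusion "true";' if iso.is_fusion else ""
            fs = getattr(iso, "fusion_splice", None)
            if fs is not None:
                fusion_attr += f' fusion_splice "{fs[0]}:{fs[1]}:{fs[2]}:{fs[3]}";'
            for block_i, (chrom, strand, exons) in enumerate(iso.blocks()):
                base = (
                    f'gene_id "{iso.locus_label}"; transcript_id "{iso.isoform_id}";'
                    + fusion_attr + rpkm_attr + f' block "{block_i}";'
                )
                fh.write(
                    "\t".join(
                        (
                            chrom, "longfuse", "transcript",
                            str(exons[0][0] + 1), str(exons[-1][1]), ".", strand, ".",
                            base,
                        )
                    )
                    + "\n"
                )
                for s, e in exons:
                    fh.write(
                        "\t".join(
                            (chrom, "longfuse", "exon", str(s + 1), str(e), ".", strand, ".", base)
                        )
                        + "\n"
                    )


def read_isoforms_gtf(path: str | Path):
    """Reload isoform candidates written by :func:`write_isoforms_gtf`."""
    from .isoforms import IsoformCandidate

    tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for item in f[8].strip().rstrip(";").split(";"):
                item = item.strip()
                if item:
                    key, _, val = item.partition(" ")
                    attrs[key] = val.strip().strip('"')
            tid = attrs["transcript_id"]
            if tid not in tx:
                tx[tid] = {
                    "locus": attrs.get("gene_id", tid),
                    "fusion": attrs.get("fusion") == "true",
                    "fusion_splice": attrs.get("fusion_splice"),
                    "rpkm": float(attrs["RPKM"]) if "RPKM" in attrs else None,
                    "blocks": {},
                }
                order.append(tid)
            if f[2] == "exon":
                key = (int(attrs.get("block", 0)), f[0], f[6])
                tx[tid]["blocks"].setdefault(key, []).append((int(f[3]) - 1, int(f[4])))
    out = []
    for tid in order:
        rec = tx[tid]
        segments = [
            (chrom, strand, sorted(exons))
            for (_, chrom, strand), exons in sorted(rec["blocks"].items())
        ]
        chain = {
            (chrom, e1 - 1, s2)
            for chrom, _, exons in segments
            for (_, e1), (s2, _) in zip(exons, exons[1:])
        }
        fs = None
        if rec["fusion_splice"]:
            c5, p5, c3, p3 = rec["fusion_splice"].split(":")
            fs = (c5, int(p5), c3, int(p3))
        iso = IsoformCandidate(
            isoform_id=tid,
            locus_label=rec["locus"],
            segments=segments,
            is_fusion=rec["fusion"],
            splice_chain=frozenset(chain),
            fusion_splice=fs,
            rpkm=rec["rpkm"],
        )
        out.append(iso)
    return out


# ---------------------------------------------------------------------------
# FASTA / misc helpers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def to_1_based(pos: int) -> int:
    """Convert a 0-based position to the 1-based convention used in reports."""
    return pos + 1


def to_0_based(pos: int) -> int:
    return pos - 1
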