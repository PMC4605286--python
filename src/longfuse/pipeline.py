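"""End-to-end orchestration of the fusion detection pipeline.

Stages communicate through files in standard formats, so any stage can be
fed externally produced data (real aligner output instead of simulated truth
alignments).  The chain is: detect fusion candidates from long-read fragment
alignments -> build and merge ARSs -> project/align short reads on ARSs and
call fusion sites -> build isoform candidates from splice linkages ->
quantify by Poisson MLE -> select significantly expressed isoforms.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam
import pyfaidx

from . import ars as ars_mod
from . import candidates as cand_mod
from . import isoforms as iso_mod
from . import quantify as quant_mod
from . import selection as sel_mod
from . import sites as sites_mod
from .annotation import AnnotationIndex
from .io import read_annotation, read_long_alignments, write_fusion_report, write_isoforms_gtf
from .model import DetectionConfig, SiteConfig
from .simulate import read_short_read_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Union of all stage parameters, at the method's default values."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    site: SiteConfig = field(default_factory=SiteConfig)
    ars_flank: int = 2000
    min_splice_gap: int = 68
    polya_min_run: int = 8
    rpkm_threshold: float = 10.0
    target_fpr: float | None = None
    max_candidates: int = 4096
    long_read_dialect: str = "sam"


def load_genome(path: str | Path):
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def load_read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name:
                    seqs[name] = "".join(parts)
                name, parts = line[1:].split()[0], []
            else:
                parts.append(line)
        if name:
            seqs[name] = "".join(parts)
    return seqs


# ---------------------------------------------------------------------------
# stage: detect
# ---------------------------------------------------------------------------

def stage_detect(long_aln_path, annotation: AnnotationIndex, genome, cfg: PipelineConfig):
    """Fusion candidate detection over all long reads; returns the surviving
    candidates and the fusion-gene groups."""
    alns = read_long_alignments(long_aln_path, cfg.long_read_dialect)
    cands = cand_mod.detect_candidates(alns, cfg.detection, annotation, genome)
    groups = cand_mod.group_candidates_to_fusion_genes(cands, cfg.detection.min_intrachrom_distance)
    logger.info("detect: %d candidates in %d fusion gene groups", len(cands), len(groups))
    return cands, groups


CANDIDATE_COLUMNS = [
    "read_id", "gene5", "gene3", "swapped",
    "chrom5", "gstart5", "gend5", "astrand5", "tstrand5", "rstart5", "rend5",
    "chrom3", "gstart3", "gend3", "astrand3", "tstrand3", "rstart3", "rend3",
]


def write_candidates_tsv(cands, path) -> None:
    """Candidate debug/interchange TSV: one row per surviving pair with
    enough structure to rebuild ARSs and long-read site support."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        _write_candidate_rows(cands, fh)


def read_candidates_tsv(path):
    from .model import FragmentAlignment, FusionCandidate, GenomeInterval

    cands = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_COLUMNS:
            raise ValueError("unexpected candidate TSV header")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            swapped = bool(int(f[3]))

            def frag(off):
                span = GenomeInterval(f[off], int(f[off + 1]), int(f[off + 2]), f[off + 3])
                return FragmentAlignment(
                    read_id=f[0], read_start=int(f[off + 5]), read_end=int(f[off + 6]),
                    genome_span=span, n_matches=len(span), identity=1.0,
                )

            f5, f3 = frag(4), frag(11)
            left, right = (f3, f5) if swapped else (f5, f3)
            c = FusionCandidate(read_id=f[0], left=left, right=right, swapped=swapped)
            c.gene5_label, c.gene3_label = f[1], f[2]
            c.strand5, c.strand3 = f[8], f[15]
            cands.append(c)
    return cands


# ---------------------------------------------------------------------------
# stage: ars
# ---------------------------------------------------------------------------

def stage_ars(cands, genome, cfg: PipelineConfig):
    arss = [
        ars_mod.build_ars(c, genome, cfg.ars_flank, ars_id=f"ARS_{i + 1:05d}")
        for i, c in enumerate(cands)
    ]
    merged = ars_mod.merge_ars(arss, genome)
    logger.info("ars: %d built, %d after merging", len(arss), len(merged))
    return merged


def write_ars_candidates(arss, path) -> None:
    """Sidecar mapping each ARS to its source candidates, so a later stage
    can reload long-read support without re-running detection."""
    import io as _io

    with open(path, "w") as fh:
        fh.write("ars_id\t" + "\t".join(CANDIDATE_COLUMNS) + "\n")
        for a in arss:
            buf = _io.StringIO()
            _write_candidate_rows(a.source_candidates, buf)
            for row in buf.getvalue().splitlines():
                fh.write(f"{a.ars_id}\t{row}\n")


def _write_candidate_rows(cands, fh) -> None:
    for c in cands:
        f5, f3 = c.frag5, c.frag3
        fh.write(
            "\t".join(
                str(x)
                for x in (
                    c.read_id, c.gene5_label, c.gene3_label, int(c.swapped),
                    f5.chrom, f5.genome_span.start, f5.genome_span.end,
                    f5.genome_span.strand, c.strand5, f5.read_start, f5.read_end,
                    f3.chrom, f3.genome_span.start, f3.genome_span.end,
                    f3.genome_span.strand, c.strand3, f3.read_start, f3.read_end,
                )
            )
            + "\n"
        )


def attach_ars_candidates(arss, path) -> None:
    """Reload the sidecar written by :func:`write_ars_candidates`."""
    from .model import FragmentAlignment, FusionCandidate, GenomeInterval

    by_id = {a.ars_id: a for a in arss}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            ars = by_id.get(f[0])
            if ars is None:
                continue
            f = f[1:]
            swapped = bool(int(f[3]))

            def frag(off):
                span = GenomeInterval(f[off], int(f[off + 1]), int(f[off + 2]), f[off + 3])
                return FragmentAlignment(
                    read_id=f[0], read_start=int(f[off + 5]), read_end=int(f[off + 6]),
                    genome_span=span, n_matches=len(span), identity=1.0,
                )

            f5, f3 = frag(4), frag(11)
            left, right = (f3, f5) if swapped else (f5, f3)
            c = FusionCandidate(read_id=f[0], left=left, right=right, swapped=swapped)
            c.gene5_label, c.gene3_label = f[1], f[2]
            c.strand5, c.strand3 = f[8], f[15]
            ars.source_candidates.append(c)


def write_linkages_tsv(linkages, path) -> None:
    with open(path, "w") as fh:
        fh.write("linkage_id\tis_fusion\tn_reads\tmarkers\tsplices\tfusion_splice\n")
        for i, lk in enumerate(linkages):
            markers = ",".join(f"{c}:{p}:{s}" for c, p, s in lk.ordered_markers())
            splices = ",".join(f"{c}:{d}:{a}" for c, d, a in sorted(lk.splices))
            fs = (
                f"{lk.fusion_splice[0]}:{lk.fusion_splice[1]}:{lk.fusion_splice[2]}:{lk.fusion_splice[3]}"
                if lk.fusion_splice else ""
            )
            fh.write(f"L{i + 1}\t{int(lk.is_fusion)}\t{len(lk.read_ids)}\t{markers}\t{splices}\t{fs}\n")


def read_linkages_tsv(path):
    from .isoforms import SpliceLinkage

    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            lid, is_fusion, n_reads, markers, splices, fs = line.rstrip("\n").split("\t")
            marker_set = set()
            if markers:
                for item in markers.split(","):
                    c, p, s = item.rsplit(":", 2)
                    marker_set.add((c, int(p), s))
            splice_set = set()
            if splices:
                for item in splices.split(","):
                    c, d, a = item.rsplit(":", 2)
                    splice_set.add((c, int(d), int(a)))
            fusion_splice = None
            if fs:
                c5, p5, c3, p3 = fs.split(":")
                fusion_splice = (c5, int(p5), c3, int(p3))
            out.append(
                SpliceLinkage(
                    markers=frozenset(marker_set),
                    splices=frozenset(splice_set),
                    is_fusion=bool(int(is_fusion)),
                    fusion_splice=fusion_splice,
                    read_ids={f"{lid}.r{k}" for k in range(int(n_reads))},
                )
            )
    return out


# ---------------------------------------------------------------------------
# short-read projection onto ARSs (truth-alignment adapter)
# ---------------------------------------------------------------------------

def _norm_blocks(blocks):
    """Accept (chrom, start, end[, strand]) blocks; default strand '+'."""
    return [(b[0], b[1], b[2], b[3] if len(b) > 3 else "+") for b in blocks]


def _genomic_gap(prev, cur):
    """Intron length between transcript-consecutive blocks on one strand, or
    None when they cannot be joined by an ordinary splice."""
    if prev[0] != cur[0] or prev[3] != cur[3]:
        return None
    gap = (cur[1] - prev[2]) if prev[3] != "-" else (prev[1] - cur[2])
    return gap if gap >= 0 else None


def _split_sides(blocks, max_intron=400_000, min_fusion_gap=100_000):
    """Split a read's transcript-ordered genome blocks at junctions that
    cannot be ordinary introns: chromosome or strand switch, reversal,
    implausibly long gap, or a gap at the intra-chromosomal fusion scale."""
    blocks = _norm_blocks(blocks)
    sides = [[blocks[0]]]
    for prev, cur in zip(blocks, blocks[1:]):
        gap = _genomic_gap(prev, cur)
        if gap is not None and gap <= max_intron and gap < min_fusion_gap:
            sides[-1].append(cur)
        else:
            sides.append([cur])
    return sides


def _covered(region, blocks):
    return all(
        b[0] == region.chrom and region.start <= b[1] and b[2] <= region.end for b in blocks
    )


def project_short_reads_to_ars(rows, arss, out_sam_path):
    """Project genome-space short-read truth alignments onto the ARS
    reference, writing a SAM that a splice aligner would have produced.

    Only reads whose blocks split across two sides (fusion-spanning reads)
    are projected; each is emitted once per ARS covering both sides, with an
    N-gap crossing the ARS boundary.
    """
    header = pysam.AlignmentHeader.from_references(
        [a.ars_id for a in arss], [len(a) for a in arss]
    )
    n_out = 0
    with pysam.AlignmentFile(str(out_sam_path), "wh", header=header) as out:
        for read_id, _, blocks in rows:
            sides = _split_sides(blocks)
            if len(sides) != 2:
                continue
            left_b = [(c, s, e) for c, s, e, _ in sides[0]]
            right_b = [(c, s, e) for c, s, e, _ in sides[1]]
            for ref_i, a in enumerate(arss):
                if not (_covered(a.left_region, left_b) and _covered(a.right_region, right_b)):
                    continue
                ars_blocks = ars_mod.project_blocks_to_ars(a, left_b, "left") + ars_mod.project_blocks_to_ars(a, right_b, "right")
                ars_blocks.sort()
                if any(b[0] < prev[1] for prev, b in zip(ars_blocks, ars_blocks[1:])):
                    continue
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.flag = 0
                rec.reference_id = ref_i
                rec.reference_start = ars_blocks[0][0]
                rec.mapping_quality = 60
                cig = []
                for i, (s, e) in enumerate(ars_blocks):
                    if i > 0:
                        cig.append((3, s - ars_blocks[i - 1][1]))
                    cig.append((0, e - s))
                rec.cigartuples = cig
                out.write(rec)
                n_out += 1
    logger.info("project: %d fusion-spanning short reads projected onto ARSs", n_out)
    return n_out


# ---------------------------------------------------------------------------
# stage: sites
# ---------------------------------------------------------------------------

def stage_sites(ars_sam_path, arss, genome, cfg: PipelineConfig, report_path=None):
    ars_map = {a.ars_id: a for a in arss}
    junctions = sites_mod.extract_junctions(ars_sam_path, ars_map, cfg.site)
    called = sites_mod.call_fusion_sites(junctions, ars_map, cfg.site, genome)
    logger.info(
        "sites: %d fusion junction coordinates observed, %d sites pass support filters",
        len(junctions.fusion), len(called),
    )
    if report_path is not None:
        write_fusion_report(called, report_path)
    return called


# ---------------------------------------------------------------------------
# stage: isoforms
# ---------------------------------------------------------------------------

def _gene_loci(annotation: AnnotationIndex) -> dict[str, iso_mod.Locus]:
    spans: dict[str, list] = {}
    for m in annotation.models:
        rec = spans.setdefault(m.gene_name, [m.interval.chrom, m.interval.start, m.interval.end, m.strand])
        rec[1] = min(rec[1], m.interval.start)
        rec[2] = max(rec[2], m.interval.end)
    return {
        name: iso_mod.Locus(chrom=c, start=s, end=e, strand=st, label=name)
        for name, (c, s, e, st) in spans.items()
    }


def _read_exon_blocks(aln) -> list[tuple[str, int, int]]:
    """Aligned exonic blocks of one long read across all its fragments,
    splitting each fragment at its splice-scale gaps."""
    blocks = []
    for frag in aln.fragments:
        cur = frag.genome_span.start
        for d, a in sorted(frag.gaps):
            if a - d - 1 > iso_mod.MIN_SPLICE_GAP:
                blocks.append((frag.chrom, cur, d + 1))
                cur = a
        blocks.append((frag.chrom, cur, frag.genome_span.end))
    return blocks


def _junctions_from_short_reads(rows, min_gap: int, max_gap: int) -> dict[tuple, int]:
    """Genome-space (chrom, donor, acceptor) junction counts from spliced
    short reads, strand-normalized so donor < acceptor."""
    counts: dict[tuple, int] = defaultdict(int)
    for _, _, blocks in rows:
        blocks = _norm_blocks(blocks)
        for prev, cur in zip(blocks, blocks[1:]):
            gap = _genomic_gap(prev, cur)
            if gap is None or not (min_gap < gap <= max_gap):
                continue
            if prev[3] != "-":
                donor, acceptor = prev[2] - 1, cur[1]
            else:
                donor, acceptor = cur[2] - 1, prev[1]
            counts[(prev[0], donor, acceptor)] += 1
    return dict(counts)


def stage_isoforms(
    long_aln_path,
    short_rows,
    annotation: AnnotationIndex,
    sites,
    cfg: PipelineConfig,
    read_seqs: dict[str, str] | None = None,
    genome=None,
):
    """Build isoform candidates: call and validate splices, encode and
    deduplicate splice linkages (fusion linkages bound to their called fusion
    site), pool ends, and enumerate candidates per seed."""
    alns = list(read_long_alignments(long_aln_path, cfg.long_read_dialect))
    loci = _gene_loci(annotation)
    short_junctions = _junctions_from_short_reads(rows=short_rows, min_gap=cfg.min_splice_gap, max_gap=cfg.site.max_intron)
    junction_keys = set(short_junctions)

    # splice pool: annotated introns plus novel short-read junctions
    pool: dict[tuple, iso_mod.Splice] = {}
    for m in annotation.models:
        for d, a in m.introns:
            key = (m.interval.chrom, d, a)
            pool[key] = iso_mod.Splice(chrom=key[0], donor=d, acceptor=a, strand=m.strand, annotated=True)
    for (c, d, a), n in short_junctions.items():
        if (c, d, a) not in pool:
            pool[(c, d, a)] = iso_mod.Splice(chrom=c, donor=d, acceptor=a, support_short_reads=n)

    site_lookup = list(sites)
    boundaries: dict[str, list[int]] = defaultdict(set)  # chrom -> coords

    def add_locus_boundaries(loc: iso_mod.Locus):
        for c in iso_mod.build_boundaries(loc, pool.values(), annotation):
            boundaries[loc.chrom].add(c)

    for loc in loci.values():
        add_locus_boundaries(loc)
    for s in sites:
        boundaries[s.chrom5].add(s.pos5 + 1)
        boundaries[s.chrom3].add(s.pos3)
    bdict = {c: sorted(v) for c, v in boundaries.items()}

    end_pool = iso_mod.build_end_pool(alns, read_seqs, annotation, cfg.polya_min_run)
    # a called fusion site contributes transcript termini at the junction for
    # the two locus segments; those are pinned during enumeration instead.

    # encode linkages
    regular_linkages: dict[str, list[iso_mod.SpliceLinkage]] = defaultdict(list)
    fusion_linkages: dict[tuple, list[iso_mod.SpliceLinkage]] = defaultdict(list)
    det_cfg = cfg.detection
    for aln in alns:
        splices = iso_mod.call_splices(aln, cfg.min_splice_gap)
        valid = iso_mod.validate_splices(splices, junction_keys, annotation)
        keys = [sp.key for sp in valid]
        blocks = _read_exon_blocks(aln)
        pairs = cand_mod.enumerate_candidate_pairs(aln, det_cfg, annotation)
        fusion_site = None
        gene_pair = None
        for cand in pairs:
            if not cand_mod.strand_consistency_filter(cand, annotation, genome):
                continue
            cand_mod.assign_gene_labels(cand, annotation)
            g5, g3 = sites_mod._proximal_ends(cand)
            w = cfg.site.long_read_window
            for s in site_lookup:
                if (
                    s.chrom5 == cand.frag5.chrom
                    and s.chrom3 == cand.frag3.chrom
                    and abs(g5 - s.pos5) <= w
                    and abs(g3 - s.pos3) <= w
                ):
                    fusion_site = s
                    gene_pair = (cand.gene5_label, cand.gene3_label)
                    break
            if fusion_site is not None:
                break

        if fusion_site is not None:
            lk = iso_mod.encode_linkage(
                blocks, bdict, keys, read_id=aln.read_id, is_fusion=True,
                fusion_splice=(fusion_site.chrom5, fusion_site.pos5, fusion_site.chrom3, fusion_site.pos3),
            )
            fusion_linkages[(gene_pair, lk.fusion_splice)].append(lk)
        else:
            genes = set()
            for frag in aln.fragments:
                genes.update(
                    annotation.gene_names_overlapping(frag.chrom, frag.genome_span.start, frag.genome_span.end)
                )
            if len(genes) == 1:
                lk = iso_mod.encode_linkage(blocks, bdict, keys, read_id=aln.read_id)
                if lk.markers:
                    regular_linkages[genes.pop()].append(lk)

    pool_splices = list(pool.values())
    all_candidates: list[iso_mod.IsoformCandidate] = []
    all_linkages: list[iso_mod.SpliceLinkage] = []
    seen_chains = set()

    def admit(cands_list):
        for c in cands_list:
            sig = (tuple(tuple((ch, st, tuple(ex))) for ch, st, ex in c.segments))
            if sig not in seen_chains:
                seen_chains.add(sig)
                all_candidates.append(c)

    for gene, lks in regular_linkages.items():
        loc = loci.get(gene)
        if loc is None:
            continue
        nr = iso_mod.deduplicate_linkages(lks)
        all_linkages.extend(nr)
        for i, seed in enumerate(nr):
            admit(
                iso_mod.enumerate_isoforms(
                    seed, pool_splices, end_pool, loc,
                    max_candidates=cfg.max_candidates, id_prefix=f"{gene}.s{i + 1}",
                )
            )

    for (gene_pair, fs), lks in fusion_linkages.items():
        g5, g3 = gene_pair
        loc5, loc3 = loci.get(g5), loci.get(g3)
        if loc5 is None or loc3 is None:
            continue
        nr = iso_mod.deduplicate_linkages(lks)
        all_linkages.extend(nr)
        for i, seed in enumerate(nr):
            admit(
                iso_mod.enumerate_isoforms(
                    seed, pool_splices, end_pool, loc5, locus3=loc3,
                    max_candidates=cfg.max_candidates,
                    id_prefix=f"{g5}--{g3}.s{i + 1}",
                )
            )
    logger.info("isoforms: %d candidates from %d non-redundant linkages", len(all_candidates), len(all_linkages))
    return all_candidates, all_linkages


# ---------------------------------------------------------------------------
# stage: quantify / select
# ---------------------------------------------------------------------------

def stage_quantify(candidates, short_rows, cfg: PipelineConfig, read_length: int = 101):
    reads = [blocks for _, _, blocks in short_rows]
    model = quant_mod.build_segment_model(candidates, reads, total_reads=len(reads), read_length=read_length)
    est = quant_mod.mle_abundance(model)
    for iso, th, rp in zip(candidates, est.theta, est.rpkm_values):
        iso.theta = float(th)
        iso.rpkm = float(rp)
    return est


def stage_select(candidates, linkages, annotation_sets, est, cfg: PipelineConfig):
    tcsl = sel_mod.build_tcsl_library(annotation_sets)
    labels = sel_mod.label_candidates(candidates, linkages, tcsl)
    abundances = {c.isoform_id: (c.rpkm or 0.0) for c in candidates}
    non_fusion = {k: v for k, v in abundances.items() if not next(c for c in candidates if c.isoform_id == k).is_fusion}
    roc = None
    threshold = cfg.rpkm_threshold
    try:
        if cfg.target_fpr is not None:
            roc = sel_mod.roc_threshold(non_fusion, labels, target_fpr=cfg.target_fpr)
            threshold = roc.chosen_threshold
        else:
            roc = sel_mod.roc_threshold(non_fusion, labels, manual_threshold=cfg.rpkm_threshold)
    except ValueError as exc:
        logger.warning("select: ROC unavailable (%s); using manual threshold %.3g", exc, threshold)
    selected, fusion_counts = sel_mod.select_isoforms(candidates, abundances, threshold)
    return selected, fusion_counts, labels, roc


# ---------------------------------------------------------------------------
# all
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    candidates: list
    groups: list
    arss: list
    sites: list
    isoform_candidates: list
    linkages: list
    abundance: object
    selected: list
    fusion_counts: dict


def run_all(
    workdir: str | Path,
    genome_path,
    annotation_path,
    long_aln_path,
    short_table_path,
    cfg: PipelineConfig | None = None,
    long_read_fasta: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on standard-format inputs, writing stage outputs
    under ``workdir``."""
    cfg = cfg or PipelineConfig()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(genome_path)
    models = read_annotation(annotation_path)
    annotation = AnnotationIndex(models)
    short_rows = read_short_read_table(short_table_path)

    cands, groups = stage_detect(long_aln_path, annotation, genome, cfg)
    arss = stage_ars(cands, genome, cfg)
    if arss:
        ars_mod.write_ars_fasta(arss, workdir / "ars.fa")
        ars_sam = workdir / "short_reads_ars.sam"
        project_short_reads_to_ars(short_rows, arss, ars_sam)
        called = stage_sites(ars_sam, arss, genome, cfg, report_path=workdir / "fusion_sites.tsv")
    else:
        called = []
        write_fusion_report([], workdir / "fusion_sites.tsv")

    read_seqs = load_read_fasta(long_read_fasta) if long_read_fasta is not None else None

    iso_cands, linkages = stage_isoforms(
        long_aln_path, short_rows, annotation, called, cfg, read_seqs=read_seqs, genome=genome
    )
    est = stage_quantify(iso_cands, short_rows, cfg)
    selected, fusion_counts, labels, roc = stage_select(iso_cands, linkages, [models], est, cfg)
    write_isoforms_gtf(iso_cands, workdir / "isoforms.gtf")
    with open(workdir / "abundance.tsv", "w") as fh:
        fh.write("isoform_id\tlocus\tlength\ttheta\trpkm\tis_fusion\tlabel\tselected\n")
        sel_ids = {c.isoform_id for c in selected}
        for c in iso_cands:
            fh.write(
                f"{c.isoform_id}\t{c.locus_label}\t{c.length}\t{c.theta:.6g}\t{c.rpkm:.4f}"
                f"\t{int(c.is_fusion)}\t{labels.get(c.isoform_id, '')}\t{int(c.isoform_id in sel_ids)}\n"
            )
    return PipelineResult(
        candidates=cands, groups=groups, arss=arss, sites=called,
        isoform_candidates=iso_cands, linkages=linkages, abundance=est,
        selected=selected, fusion_counts=fusion_counts,
    )
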