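"""Core record types shared across the pipeline.

All genomic coordinates are 0-based half-open internally; 1-based closed
coordinates appear only at I/O boundaries (reports, genePred/GTF edges).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRAND_FWD = "+"
STRAND_REV = "-"
STRAND_UNKNOWN = "."


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Splice:
    """An intron call: `donor` is the last exonic base before the gap and
    `acceptor` the first exonic base after it (both 0-based)."""

    chrom: str
    donor: int
    acceptor: int
    strand: str = STRAND_UNKNOWN
    support_short_reads: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.acceptor - self.donor - 1 < 1:
            raise ValueError("splice gap must be >= 1 bp")

    @property
    def gap(self) -> int:
        """Intron length in bases."""
        return self.acceptor - self.donor - 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)


@dataclass
class FragmentAlignment:
    """One aligned piece of a long read.

    ``read_span`` is in original-read coordinates (0-based half-open), so two
    fragments of one read can be ordered along the read regardless of which
    genome strand each aligns to.  ``identity`` is matches over target length,
    where the target length spans the whole genomic footprint of the alignment
    (gaps included, GMAP-style).
    """

    read_id: str
    read_start: int
    read_end: int
    genome_span: GenomeInterval
    n_matches: int
    identity: float
    splices: list[Splice] = field(default_factory=list)
    rank: int = 0
    gaps: list[tuple[int, int]] = field(default_factory=list)  # (donor, acceptor) of every alignment gap

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError("read_start must precede read_end")
        if not 0.0 <= self.identity <= 1.0 + 1e-9:
            raise ValueError(f"identity out of [0,1]: {self.identity}")

    @property
    def read_span_len(self) -> int:
        return self.read_end - self.read_start

    @property
    def chrom(self) -> str:
        return self.genome_span.chrom


@dataclass
class LongReadAlignmentSet:
    """All fragment alignments of one long read, best (rank-0) fragments
    sorted by position on the read; rank>0 alternatives kept per fragment."""

    read_id: str
    read_length: int
    fragments: list[FragmentAlignment] = field(default_factory=list)
    # alternatives[i] lists rank>0 alignments of fragments[i]
    alternatives: dict[int, list[FragmentAlignment]] = field(default_factory=dict)

    def sort(self) -> None:
        order = sorted(range(len(self.fragments)), key=lambda i: self.fragments[i].read_start)
        self.fragments = [self.fragments[i] for i in order]
        self.alternatives = {
            new: self.alternatives[old] for new, old in enumerate(order) if old in self.alternatives
        }


@dataclass
class GeneModel:
    """One annotated isoform of a gene: sorted disjoint exons in genomic order."""

    gene_name: str
    isoform_name: str
    interval: GenomeInterval
    exons: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"exons of {self.isoform_name} not sorted/disjoint")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """(donor, acceptor) base pairs between consecutive exons."""
        return [
            (e1 - 1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class FilterFlags:
    """Per-filter outcome record for a candidate pair."""

    length_ok: bool = True
    locus_separation_ok: bool = True
    overlap_ok: bool = True
    unaligned_gap_ok: bool = True
    identity_diff_ok: bool = True
    strand_ok: bool = True

    def all_pass(self) -> bool:
        return all(
            (
                self.length_ok,
                self.locus_separation_ok,
                self.overlap_ok,
                self.unaligned_gap_ok,
                self.identity_diff_ok,
                self.strand_ok,
            )
        )


@dataclass
class FusionCandidate:
    """An ordered pair of fragment alignments of one long read.

    ``left`` precedes ``right`` on the read.  After strand determination,
    ``swapped`` is True when the read is the reverse complement of the fusion
    transcript, i.e. the right fragment is the transcript's 5' side.
    """

    read_id: str
    left: FragmentAlignment
    right: FragmentAlignment
    flags: FilterFlags = field(default_factory=FilterFlags)
    gene5_label: Optional[str] = None
    gene3_label: Optional[str] = None
    strand5: str = STRAND_UNKNOWN
    strand3: str = STRAND_UNKNOWN
    swapped: bool = False

    def __post_init__(self) -> None:
        if self.left.read_id != self.right.read_id:
            raise ValueError("fragments must come from the same read")
        if self.left.read_start > self.right.read_start:
            raise ValueError("left fragment must precede right fragment on the read")

    @property
    def frag5(self) -> FragmentAlignment:
        """Fragment covering the transcript's 5' gene."""
        return self.right if self.swapped else self.left

    @property
    def frag3(self) -> FragmentAlignment:
        return self.left if self.swapped else self.right


@dataclass
class DetectionConfig:
    """Structural-filter thresholds for candidate pair detection."""

    min_fragment_len: int = 100
    min_intrachrom_distance: int = 100_000
    max_fragment_overlap: int = 100
    max_unaligned_gap: int = 100
    identity_diff_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.identity_diff_threshold <= 1:
            raise ValueError("identity_diff_threshold must be in (0, 1]")
        for name in ("min_fragment_len", "min_intrachrom_distance", "max_fragment_overlap", "max_unaligned_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SiteConfig:
    """Support and junction-geometry thresholds for fusion-site calling."""

    min_long_reads: int = 2
    min_short_reads: int = 2
    min_overhang: int = 12
    min_intron: int = 68
    max_intron: int = 400_000
    long_read_window: int = 200  # fragment-end compatibility window around a site

    def __post_init__(self) -> None:
        for name in ("min_long_reads", "min_short_reads", "min_overhang", "min_intron", "max_intron"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FusionSite:
    """A fusion junction in genome coordinates at single-nucleotide resolution.

    ``pos5`` is the last base of the 5' gene segment and ``pos3`` the first
    base of the 3' gene segment, both 0-based.  SFL (short fragment length) of
    a supporting long read is the length of its shorter flanking fragment;
    MSFL is the maximum SFL over supporting long reads.
    """

    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    strand5: str = STRAND_UNKNOWN
    strand3: str = STRAND_UNKNOWN
    n_long_reads: int = 0
    n_short_reads: int = 0
    msfl: int = 0
    canonical: bool = False
    gene5_label: str = ""
    gene3_label: str = ""


@dataclass
class BenchmarkResult:
    """Sensitivity / precision / F-score of predictions against a gold set."""

    n_predicted: int
    n_gold: int
    n_matched: int
    sensitivity: float
    precision: float
    f_score: float
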