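"""Indexed access to annotation libraries: gene overlap and intron lookup."""
from __future__ import annotations

from collections import defaultdict

from intervaltree import IntervalTree

from .model import GeneModel


class AnnotationIndex:
    """Interval-tree index over one or more annotation libraries.

    Supports the three lookups the pipeline needs: which genes overlap a span,
    whether a (donor, acceptor) pair is an annotated intron, and the strand of
    the genes at a locus.
    """

    def __init__(self, models: list[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._introns: dict[tuple[str, int, int], list[GeneModel]] = defaultdict(list)
        for m in self.models:
            self._trees[m.interval.chrom].addi(m.interval.start, m.interval.end, m)
            for donor, acceptor in m.introns:
                self._introns[(m.interval.chrom, donor, acceptor)].append(m)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        if chrom not in self._trees:
            return []
        return sorted(
            (iv.data for iv in self._trees[chrom].overlap(start, end)),
            key=lambda m: (m.interval.start, m.isoform_name),
        )

    def genes_at_intron(self, chrom: str, donor: int, acceptor: int) -> list[GeneModel]:
        return self._introns.get((chrom, donor, acceptor), [])

    def is_annotated_intron(self, chrom: str, donor: int, acceptor: int) -> bool:
        return (chrom, donor, acceptor) in self._introns

    def gene_names_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        seen: list[str] = []
        for m in self.genes_overlapping(chrom, start, end):
            if m.gene_name not in seen:
                seen.append(m.gene_name)
        return seen
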