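"""Benchmarking predicted fusion gene pairs against a gold-standard list.

Sensitivity is the fraction of gold pairs detected, precision the fraction
of predictions matching a gold pair, and the F-score their harmonic mean.
All ratios are computed exactly from integer counts; rounding (percentages
to 2 decimals, F-score to 4, half-up) happens only at formatting.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .annotation import AnnotationIndex
from .model import BenchmarkResult

GenePair = tuple[str, str]


def _resolve_label(label: str, annotation: AnnotationIndex | None) -> set[str]:
    """Names a prediction label can stand for: itself, plus any annotated
    gene overlapping it when it is a genomic-locus label."""
    names = {label}
    if annotation is not None and ":" in label:
        chrom, _, pos = label.rpartition(":")
        try:
            p = int(pos) - 1
        except ValueError:
            return names
        names.update(annotation.gene_names_overlapping(chrom, p, p + 1))
    return names


def match_predictions(
    predicted: list[GenePair],
    gold: list[GenePair],
    annotation: AnnotationIndex | None = None,
) -> int:
    """Count gold pairs hit by at least one prediction.

    Pairs are unordered; genomic-locus labels (``chrom:pos``) match a gold
    gene when the position falls inside the gene's annotated span.  Each gold
    pair counts at most once however many predictions hit it.
    """
    matched: set[frozenset] = set()
    gold_sets = [frozenset(p) for p in gold]
    for a, b in predicted:
        names_a = _resolve_label(a, annotation)
        names_b = _resolve_label(b, annotation)
        for gset in gold_sets:
            if gset in matched:
                continue
            g1, g2 = tuple(gset) if len(gset) == 2 else (next(iter(gset)),) * 2
            if (g1 in names_a and g2 in names_b) or (g2 in names_a and g1 in names_b):
                matched.add(gset)
    return len(matched)


def score(n_matched: int, n_predicted: int, n_gold: int) -> BenchmarkResult:
    """Sensitivity, precision and F-score from integer counts."""
    if not (0 <= n_matched <= n_predicted):
        raise ValueError("require 0 <= n_matched <= n_predicted")
    if n_matched > n_gold:
        raise ValueError("n_matched cannot exceed n_gold")
    if n_predicted == 0:
        raise ValueError("precision undefined: no predictions")
    if n_gold == 0:
        raise ValueError("sensitivity undefined: empty gold set")
    precision = n_matched / n_predicted
    sensitivity = n_matched / n_gold
    f = 2 * precision * sensitivity / (precision + sensitivity) if precision + sensitivity else 0.0
    return BenchmarkResult(
        n_predicted=n_predicted,
        n_gold=n_gold,
        n_matched=n_matched,
        sensitivity=sensitivity,
        precision=precision,
        f_score=f,
    )


def format_percent(x: float) -> str:
    """Half-up percentage with 2 decimals, e.g. 0.685714 -> '68.57%'."""
    return str(Decimal(repr(x * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) + "%"


def format_f_score(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def read_gold_pairs(path: str | Path) -> list[GenePair]:
    """Gold-standard TSV: gene1, gene2[, source]; header line optional."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 2 or f[0].lower() in ("gene1", "gene_a"):
                continue
            pairs.append((f[0], f[1]))
    return pairs


def write_benchmark_report(result: BenchmarkResult, path: str | Path, tool: str = "longfuse") -> None:
    with open(path, "w") as fh:
        fh.write("tool\tn_matched\tsensitivity\tn_predicted\tprecision\tf_score\n")
        fh.write(
            f"{tool}\t{result.n_matched}\t{format_percent(result.sensitivity)}"
            f"\t{result.n_predicted}\t{format_percent(result.precision)}"
            f"\t{format_f_score(result.f_score)}\n"
        )
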