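"""Significance selection of isoform candidates by ROC-thresholded abundance.

True positives are candidates whose complete splice chain is directly
observed in one non-redundant splice linkage.  True negatives are candidates
containing a two-consecutive-splice-linkage (TCSL: an ordered pair of
adjacent introns sharing an exon) absent from a TCSL library pooled over
annotation libraries — near-exhaustive catalogs of intron pairs occurring in
nature.  The ROC over non-fusion candidates, with abundance as the
classifier score, yields the abundance threshold at a target FPR (or the
achieved FPR at a manual threshold); the threshold is then applied to fusion
candidates, selecting isoforms with abundance strictly above it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .isoforms import IsoformCandidate, SpliceKey, SpliceLinkage
from .model import GeneModel

TcslKey = tuple[SpliceKey, SpliceKey]


@dataclass
class TcslLibrary:
    """Union of consecutive-intron pairs over annotation libraries."""

    keys: set[TcslKey] = field(default_factory=set)
    sources: dict[TcslKey, set[str]] = field(default_factory=dict)

    def __contains__(self, key: TcslKey) -> bool:
        return key in self.keys

    def add(self, key: TcslKey, source: str) -> None:
        self.keys.add(key)
        self.sources.setdefault(key, set()).add(source)


def build_tcsl_library(annotations: list[list[GeneModel]]) -> TcslLibrary:
    """Every consecutive intron pair of every annotated isoform with at least
    two introns, unioned over libraries and deduplicated."""
    lib = TcslLibrary()
    for models in annotations:
        for m in models:
            introns = [(m.interval.chrom, d, a) for d, a in m.introns]
            for i1, i2 in zip(introns, introns[1:]):
                lib.add((i1, i2), m.source)
    return lib


def label_candidates(
    candidates: list[IsoformCandidate],
    linkages: list[SpliceLinkage],
    tcsl: TcslLibrary,
) -> dict[str, str]:
    """Label candidates TP / TN / unlabeled.

    TP: one non-redundant linkage covers every boundary marker of the
    candidate's splice chain (direct full-length observation; overrides TN).
    TN: at least one consecutive-intron pair of the candidate is missing from
    the TCSL library (pairs involving the fusion splice are not testable
    against annotation and are skipped).
    """
    labels: dict[str, str] = {}
    for cand in candidates:
        chain_markers = cand.chain_markers()
        tp = bool(chain_markers) and any(chain_markers <= lk.markers for lk in linkages)
        if not chain_markers:
            # single-exon candidate: directly observed iff any linkage exists
            # from its reads; treat as unlabeled-able TP only via linkages
            tp = False
        if tp:
            labels[cand.isoform_id] = "TP"
            continue
        tn = any(pair not in tcsl for pair in cand.consecutive_intron_pairs())
        labels[cand.isoform_id] = "TN" if tn else "unlabeled"
    return labels


@dataclass
class RocResult:
    """Step-function ROC over the observed-abundance grid.

    A candidate is called positive when its abundance is strictly greater
    than the threshold, matching the selection rule.
    """

    thresholds: list[float]
    sensitivity: list[float]
    fpr: list[float]
    chosen_threshold: float
    achieved_fpr: float
    achieved_sensitivity: float


def roc_threshold(
    abundances: dict[str, float],
    labels: dict[str, str],
    target_fpr: float | None = None,
    manual_threshold: float | None = None,
) -> RocResult:
    """Find the abundance threshold at a target FPR, or the FPR achieved by a
    manual threshold.

    The grid is the observed abundances plus 0 and +inf; FPR(t) and
    sensitivity(t) count labeled candidates with abundance > t.  The chosen
    threshold is the smallest grid value with FPR <= target (maximal
    sensitivity under the FPR control).
    """
    if (target_fpr is None) == (manual_threshold is None):
        raise ValueError("supply exactly one of target_fpr or manual_threshold")
    tp_vals = [v for k, v in abundances.items() if labels.get(k) == "TP"]
    tn_vals = [v for k, v in abundances.items() if labels.get(k) == "TN"]
    if not tn_vals:
        raise ValueError("FPR undefined: no true-negative labels")
    if not tp_vals:
        raise ValueError("sensitivity undefined: no true-positive labels")

    grid = sorted(set(abundances.values()) | {0.0, math.inf})
    sens = [sum(1 for v in tp_vals if v > t) / len(tp_vals) for t in grid]
    fpr = [sum(1 for v in tn_vals if v > t) / len(tn_vals) for t in grid]

    if manual_threshold is not None:
        chosen = manual_threshold
    else:
        chosen = next((t for t, f in zip(grid, fpr) if f <= target_fpr), math.inf)
    ach_fpr = sum(1 for v in tn_vals if v > chosen) / len(tn_vals)
    ach_sens = sum(1 for v in tp_vals if v > chosen) / len(tp_vals)
    return RocResult(
        thresholds=grid,
        sensitivity=sens,
        fpr=fpr,
        chosen_threshold=chosen,
        achieved_fpr=ach_fpr,
        achieved_sensitivity=ach_sens,
    )


def select_isoforms(
    candidates: list[IsoformCandidate],
    abundances: dict[str, float],
    threshold: float,
) -> tuple[list[IsoformCandidate], dict[str, int]]:
    """Select isoforms with abundance strictly greater than the threshold.

    Returns the selected candidates and, for the fusion ones, the count of
    selected fusion isoforms per fusion gene (locus-pair label).
    """
    selected = [
        c for c in candidates if abundances.get(c.isoform_id, 0.0) > threshold
    ]
    fusion_counts: dict[str, int] = {}
    for c in selected:
        if c.is_fusion:
            fusion_counts[c.locus_label] = fusion_counts.get(c.locus_label, 0) + 1
    return selected, fusion_counts
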