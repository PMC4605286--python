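"""Isoform abundance estimation under a Poisson coverage model.

The locus is partitioned into minimal segments by the exon boundaries of all
candidate isoforms (fusion loci are partitioned jointly across both sides).
Segment read counts n_s are modeled as independent Poisson variables with
rate lambda_s = l_s * sum_j a_sj theta_j, where l_s is the segment length,
a_sj the segment/isoform incidence and theta_j the expected reads per base
of isoform j.  The likelihood is maximized by EM with the latent variable
being the isoform of origin of each segment read; the likelihood is concave
in theta, so a fixed uniform initialization and deterministic iteration
suffice.  Junction-spanning reads are counted once on a virtual junction
segment whose length is the number of read start positions crossing the
junction (read length minus one).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isoforms import IsoformCandidate


@dataclass
class SegmentModel:
    """Minimal exonic partition of a locus with isoform incidence and counts."""

    isoform_ids: list[str]
    segment_keys: list[tuple]              # genomic segments (chrom, s, e) or junction keys
    lengths: np.ndarray                    # l_s, bp
    incidence: np.ndarray                  # a_sj in {0,1}, shape (S, J)
    counts: np.ndarray                     # n_s
    total_reads: int                       # N, dataset-wide mapped short reads
    # optional exact start-position lengths per (segment, isoform); when
    # absent the rate matrix is l_s * a_sj
    effective_lengths: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segment_keys)

    @property
    def rate_matrix(self) -> np.ndarray:
        """E[n_s] = (rate_matrix @ theta)_s."""
        if self.effective_lengths is not None:
            return self.effective_lengths
        return self.lengths[:, None] * self.incidence.astype(float)


def _norm_blocks(blocks):
    return [(b[0], b[1], b[2], b[3] if len(b) > 3 else "+") for b in blocks]


def _junction_of(blocks) -> tuple | None:
    """Key of the first junction a transcript-ordered read spans: a regular
    splice key with donor < acceptor in genome coordinates, or a fusion key
    in transcript (5' gene, 3' gene) order."""
    blocks = _norm_blocks(blocks)
    if len(blocks) < 2:
        return None
    b0, b1 = blocks[0], blocks[1]
    trailing = b0[2] - 1 if b0[3] != "-" else b0[1]
    leading = b1[1] if b1[3] != "-" else b1[2] - 1
    if b0[0] == b1[0] and b0[3] == b1[3]:
        gap = (b1[1] - b0[2]) if b0[3] != "-" else (b0[1] - b1[2])
        if 0 <= gap < 100_000:
            donor, acceptor = (trailing, leading) if trailing < leading else (leading, trailing)
            return ("J", b0[0], donor, b0[0], acceptor)
    return ("J", b0[0], trailing, b1[0], leading)


def build_segment_model(
    candidates: list[IsoformCandidate],
    reads: list[list[tuple]],
    total_reads: int | None = None,
    read_length: int = 101,
) -> SegmentModel:
    """Partition the candidates' exonic space and count reads per segment.

    ``reads`` are short-read alignments as transcript-ordered exon-block
    lists (chrom, start, end[, strand]) in genome space; fusion-spanning
    reads carry blocks on both loci.  A read spanning a junction is assigned
    once to the virtual segment of its first junction; a contiguous read to
    the segment containing its first transcript base.  Effective segment
    lengths are computed per isoform as the number of read start positions
    the assignment rule routes to each segment, so the Poisson rates are
    exact for uniformly sampled reads.
    """
    bounds: dict[str, set[int]] = {}
    for iso in candidates:
        for chrom, s, e in iso.exon_set():
            bounds.setdefault(chrom, set()).update((s, e))
    segments: list[tuple] = []
    for chrom in sorted(bounds):
        bs = sorted(bounds[chrom])
        for s, e in zip(bs, bs[1:]):
            if any(
                cs <= s and e <= ce
                for iso in candidates
                for c, cs, ce in iso.exon_set()
                if c == chrom
            ):
                segments.append((chrom, s, e))

    # virtual junction segments for every junction present in any candidate,
    # fusion junctions included
    junction_keys: list[tuple] = []
    seen = set()
    for iso in candidates:
        for k in _iso_junction_keys(iso):
            if k not in seen:
                seen.add(k)
                junction_keys.append(k)

    iso_ids = [iso.isoform_id for iso in candidates]
    S = len(segments) + len(junction_keys)
    J = len(candidates)
    lengths = np.zeros(S)
    for si, (chrom, s, e) in enumerate(segments):
        lengths[si] = e - s
    lengths[len(segments):] = max(read_length - 1, 1)

    seg_index = {k: i for i, k in enumerate(segments)}
    jct_index = {k: len(segments) + i for i, k in enumerate(junction_keys)}
    seg_starts = {}
    for chrom in sorted(bounds):
        seg_starts[chrom] = sorted((s, e, seg_index[(chrom, s, e)]) for (c, s, e) in segments if c == chrom)

    def locate_segment(chrom, g):
        import bisect

        arr = seg_starts.get(chrom)
        if not arr:
            return None
        i = bisect.bisect_right(arr, (g, float("inf"), -1)) - 1
        if i >= 0 and arr[i][0] <= g < arr[i][1]:
            return arr[i][2]
        return None

    eff = np.zeros((S, J))
    for ji, iso in enumerate(candidates):
        exons = [
            (chrom, strand, s, e)
            for chrom, strand, chain in iso.segments
            for s, e in (chain if strand != "-" else reversed(chain))
        ]
        # transcript offsets of exon starts and junction coordinates
        offsets = []
        pos = 0
        for chrom, strand, s, e in exons:
            offsets.append(pos)
            pos += e - s
        L = pos
        if L < read_length:
            continue
        jct_positions = []  # (transcript coord of junction, segment row)
        for k, (a, b) in enumerate(zip(exons, exons[1:])):
            key = _pair_junction_key(a, b)
            if key in jct_index:
                jct_positions.append((offsets[k + 1], jct_index[key]))
        jp = 0
        for t in range(0, L - read_length + 1):
            while jp < len(jct_positions) and jct_positions[jp][0] <= t:
                jp += 1
            if jp < len(jct_positions) and jct_positions[jp][0] < t + read_length:
                eff[jct_positions[jp][1], ji] += 1
                continue
            # genomic base of transcript position t
            import bisect

            k = bisect.bisect_right(offsets, t) - 1
            chrom, strand, s, e = exons[k]
            g = (s + (t - offsets[k])) if strand != "-" else (e - 1 - (t - offsets[k]))
            si = locate_segment(chrom, g)
            if si is not None:
                eff[si, ji] += 1

    counts = np.zeros(S)
    for blocks in reads:
        jkey = _junction_of(blocks)
        if jkey is not None:
            if jkey in jct_index:
                counts[jct_index[jkey]] += 1
            continue
        b0 = _norm_blocks(blocks)[0]
        g0 = b0[1] if b0[3] != "-" else b0[2] - 1
        si = locate_segment(b0[0], g0)
        if si is not None:
            counts[si] += 1

    return SegmentModel(
        isoform_ids=iso_ids,
        segment_keys=segments + junction_keys,
        lengths=lengths,
        incidence=(eff > 0).astype(np.int8),
        counts=counts,
        total_reads=total_reads if total_reads is not None else int(counts.sum()),
        effective_lengths=eff,
    )


def _iso_junction_keys(iso: IsoformCandidate) -> list[tuple]:
    exons = [
        (chrom, strand, s, e)
        for chrom, strand, chain in iso.segments
        for s, e in (chain if strand != "-" else reversed(chain))
    ]
    return [_pair_junction_key(a, b) for a, b in zip(exons, exons[1:])]


def _pair_junction_key(a, b) -> tuple:
    """Junction key between two transcript-consecutive exons: regular
    (donor < acceptor) on one chrom/strand, fusion key in transcript order
    otherwise."""
    trailing = a[3] - 1 if a[1] != "-" else a[2]
    leading = b[2] if b[1] != "-" else b[3] - 1
    if a[0] == b[0] and a[1] == b[1]:
        gap = (b[2] - a[3]) if a[1] != "-" else (a[2] - b[3])
        if 0 <= gap < 100_000:
            donor, acceptor = (trailing, leading) if trailing < leading else (leading, trailing)
            return ("J", a[0], donor, a[0], acceptor)
    return ("J", a[0], trailing, b[0], leading)


@dataclass
class AbundanceEstimate:
    """MLE result for one locus model: theta in reads/base per isoform,
    RPKM per isoform, and the final Poisson log-likelihood."""

    isoform_ids: list[str]
    theta: np.ndarray
    rpkm_values: np.ndarray
    log_likelihood: float
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)


def _loglik(theta: np.ndarray, model: SegmentModel) -> float:
    lam = model.rate_matrix @ theta
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(model.counts > 0, model.counts * np.log(lam), 0.0)
    if np.any((lam == 0) & (model.counts > 0)):
        return -np.inf
    return float(np.sum(term) - lam.sum())


def mle_abundance(
    model: SegmentModel,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> AbundanceEstimate:
    """Maximize the Poisson segment-count likelihood over theta >= 0 by EM.

    Deterministic: theta starts uniform at (sum n_s)/(J * sum l_s).  The
    log-likelihood is non-decreasing across iterations; iteration stops when
    its change falls below ``tol``.
    """
    J = len(model.isoform_ids)
    n = model.counts
    R = model.rate_matrix  # (S, J): E[n_s] = R @ theta
    denom = R.sum(axis=0)  # effective length of each isoform
    total = n.sum()
    if total == 0 or J == 0:
        theta = np.zeros(J)
        return AbundanceEstimate(
            isoform_ids=model.isoform_ids,
            theta=theta,
            rpkm_values=np.zeros(J),
            log_likelihood=_loglik(theta, model) if J else 0.0,
        )

    theta = np.full(J, total / max(denom.sum(), 1.0))
    trace = [_loglik(theta, model)]
    converged = False
    for _ in range(max_iter):
        lam_iso = R * theta  # (S, J) per-isoform contributions to the rate
        lam_tot = lam_iso.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(lam_tot[:, None] > 0, lam_iso / lam_tot[:, None], 0.0)
        expected = resp.T @ n  # reads attributed to each isoform
        new_theta = np.where(denom > 0, expected / np.where(denom > 0, denom, 1.0), 0.0)
        theta = new_theta
        trace.append(_loglik(theta, model))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    N = model.total_reads
    rpkm_values = np.array([rpkm(t, max(int(el), 1), N) if N > 0 else 0.0 for t, el in zip(theta, denom)])
    return AbundanceEstimate(
        isoform_ids=model.isoform_ids,
        theta=theta,
        rpkm_values=rpkm_values,
        log_likelihood=trace[-1],
        converged=converged,
        loglik_trace=trace,
    )


def rpkm(theta_j: float, length_j: int, N: int) -> float:
    """Reads per kilobase per million mapped reads.

    With theta in expected reads per base, reads attributed to the isoform
    are theta * length, so RPKM = 1e9 * theta / N independent of length.
    """
    if N <= 0:
        raise ValueError("total mapped reads N must be positive")
    if length_j <= 0:
        raise ValueError("isoform length must be positive")
    return 1e9 * theta_j / N
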