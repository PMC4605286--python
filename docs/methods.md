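# Methods

`longfuse` characterizes gene fusions from hybrid transcriptome sequencing:
long reads (error-corrected third-generation reads) locate fusion gene
candidates genome-wide, short second-generation reads pin the fusion sites
at single-nucleotide resolution, and the two together reconstruct and
quantify the transcript isoforms expressed across each fusion. This note
describes the model and procedure, the parameters that matter, what the
bundled simulator does and does not emulate, and the numerical choices made
where the design was open.

## Fusion gene detection from long-read fragment alignments

A long read that spans a fusion junction cannot align contiguously; a
spliced long-read aligner splits it into *fragment alignments* on two loci.
For each read, every pair of fragments (ordered by position on the read) is
tested against four structural conditions:

1. **length** — both fragments aligned over more than `min_fragment_len`
   (default 100 bp) of the read; shorter fragments align ambiguously;
2. **locus separation** — different chromosomes, or at least
   `min_intrachrom_distance` (default 100 kb) apart, or overlapping two
   different annotated genes (annotation overrides distance, so read-through
   fusions of adjacent genes are not discarded);
3. **read-span overlap** ≤ `max_fragment_overlap` (default 100 bp);
4. **unaligned gap** between the fragments ≤ `max_unaligned_gap`
   (default 100 bp).

Two further filters remove artifacts of repeats and residual read error.
The *identity-difference* filter discards a pair when either fragment has an
alternative alignment whose identity (matches over target length, the
target spanning the full genomic footprint including gaps) is within
`identity_diff_threshold` (default 0.2) of the best — evidence that the
fragment is not uniquely placeable. Alternative alignments are taken from
the aligner's secondary records rather than by re-aligning; a hook accepts
externally computed alternatives. The *strand-consistency* filter requires
the two fragments to traverse their source transcripts in the same
direction along the read. Each fragment's transcript strand is determined
from the canonical GT–AG (or CT–AC on the reverse strand) motifs of its
splice gaps, falling back to the strand of an overlapping annotated gene,
else unknown; unknown inherits the partner's direction. When both fragments
read their transcripts in reverse, the read is the reverse complement of
the fusion transcript and the 5′/3′ roles of the fragments are swapped
rather than rejected.

Fragments are labeled with a gene name when a detected splice matches an
annotated intron or the alignment overlaps an annotated gene; otherwise
they carry a genomic-locus label (`chrom:pos`, 1-based). Candidates are
grouped into fusion genes by unordered label pair, with locus labels within
`min_intrachrom_distance` on one chromosome clustered as one locus.

## Fusion sites on artificial reference sequences

Long-read fragment ends only bracket the true junction (their ends scatter
with the residual error rate), so the junction is refined with short reads.
For each candidate an *artificial reference sequence* (ARS) is built: each
fragment's genomic span is extended `ars_flank` (default 2000 bp) past its
junction-proximal end and the two windows are concatenated, each emitted in
transcript orientation, so the true junction appears inside the ARS as a
~4 kb forward "artificial intron". Extension is junction-proximal only —
the distal ends keep the fragments' aligned extent — which is what makes
the artificial intron ≈ 2 × flank. ARSs from the same fusion locus (both
left and right regions overlapping, on matching chromosome and strand) are
merged by span union; because a widened span can newly overlap other ARSs,
merging iterates to a fixpoint, leaving no mergeable pair. Exact bijective
coordinate maps between ARS and genome space are kept per region.

Short-read spliced alignments against the ARS reference are scanned for
N-gaps of length within `[min_intron, max_intron]` (defaults 68 bp and
400 kb — the same junction-geometry contract a spliced aligner would be run
with) having at least `min_overhang` (default 12 bp) aligned on each side.
A gap whose flanks straddle the ARS boundary is a fusion-site observation;
mapping its flanks back through the coordinate maps gives the genomic
junction (last base of the 5′ segment, first base of the 3′ segment).
Distinct coordinates are distinct sites — no clustering — which is what
single-nucleotide resolution means here. Per site we count supporting short
reads, supporting long reads (a candidate supports a site when each of its
fragment ends lies within `long_read_window`, default 200 bp, of the site
position on its side — wide enough to cover the observed scatter of
fragment ends), and the MSFL: each supporting read's SFL is the length of
its shorter flanking fragment, and the MSFL is the maximum SFL, a measure
of how uniquely the long-read evidence is mappable. Sites with fewer than
`min_long_reads` or `min_short_reads` (both default 2) are dropped. A site
is flagged *canonical* when the two genomic bases just downstream of the 5′
break are GT and the two just upstream of the 3′ break are AG, both in
transcript orientation; GC–AG and AT–AC variants are reported but flagged
non-canonical.

This package does not run an aligner. Alignments are consumed from files,
and for simulated data an exact coordinate projection transfers the
genome-space truth alignments of fusion-spanning short reads onto the ARSs,
playing the aligner's role. A read is considered fusion-spanning when
consecutive blocks switch chromosome or strand, reverse, or jump by at
least the intra-chromosomal fusion distance (100 kb) — the last clause
matters because an intra-chromosomal fusion junction gap can be shorter
than the 400 kb a spliced aligner would accept as an intron.

## Isoform reconstruction from splice linkages

Alignment gaps of a long read longer than 68 bp are called as splices
(shorter gaps are treated as deletions; in human annotation the intron
length distribution is almost entirely above this value). Called splices
are kept only when confirmed by a short-read junction or an annotated
intron; fusion splices are exempt, being validated by the fusion-site
caller instead.

Within each locus, exon boundaries are collected from all splice sites plus
annotated transcript ends. Each boundary `P` carries two markers for its
flanking bases, `P−` and `P+`; a read whose exon covers both flanking bases
shows the boundary is read through, while a read splicing or terminating at
`P` contributes only the inner marker. The markers covered by one read form
its *splice linkage* (a fusion linkage when the read spans two loci). A
linkage is redundant — and removed, with its read provenance merged — when
both its marker set and its splice set are subsets of another's: partial
reads of one structure collapse, but a read taking a different splice (an
exon skip has a marker subset yet a distinct splice) is separate evidence
and survives. Comparing markers alone would delete exactly the alternative
splicing the method is meant to recover.

Each non-redundant linkage seeds candidate enumeration. Pool splices
(annotated introns plus novel short-read junctions) of consistent strand
are added in every combination that does not contradict the seed — no added
intron may cover a base the seed marks exonic, nor overlap a seed intron —
between every pooled 5′ end upstream and 3′ end downstream. The end pool
contains annotated transcript ends plus 3′ ends from polyA evidence: a
terminal soft-clipped tail of at least `polya_min_run` (default 8) bases
that is ≥ 80 % A (or T for the opposite orientation) marks a 3′ end at the
alignment terminus. For a fusion seed the 5′ gene supplies the 5′ ends, the
3′ gene the 3′ ends, and the two segments join at the seed's single fusion
splice (multi-fusion chains are out of scope). Enumeration is capped at
`max_candidates` (default 4096) per seed; on overflow the locus is flagged
and only the seed-faithful minimal isoform is kept, since "all
combinations" is exponential in pool size.

## Abundance by Poisson MLE

Candidate exon boundaries partition each locus (fusion loci jointly across
both sides) into minimal segments; every junction of any candidate,
fusion junctions included, gets a virtual segment. A short read spanning a
junction is counted once on its first junction's virtual segment; a
contiguous read on the segment containing its first transcript base.
Segment counts `n_s` are modeled as independent Poissons with rate
`λ_s = Σ_j R_sj θ_j`, where `θ_j` is isoform `j`'s expected reads per base
and `R_sj` is the number of read start positions of isoform `j` that the
assignment rule routes to segment `s`, computed exactly per isoform by
walking its transcript (start positions within read-length−1 upstream of a
junction go to the junction's virtual segment; `Σ_s R_sj = L_j − rl + 1`).
Using plain segment lengths instead of these effective lengths biases `θ`
low by roughly the junction density times the read length, which is why the
rate matrix is computed exactly. The likelihood is concave in `θ`, so EM
with a fixed uniform initialization and a `1e-8` log-likelihood tolerance
is deterministic and sufficient; the log-likelihood is non-decreasing by
construction and the fit is checked against a grid-search maximizer in the
tests. RPKM is `10⁹ · θ / N` with `N` the dataset-wide mapped short-read
count (the conventional denominator). Fusion and regular candidates of a
fusion gene are quantified jointly, competing for shared segments.

## Selection by ROC-thresholded abundance

True positives for the ROC are candidates whose complete splice chain is
covered by a single non-redundant linkage (direct full-length observation).
True negatives contain a two-consecutive-splice-linkage — an ordered pair
of adjacent introns sharing an exon — absent from the TCSL library pooled
over the annotation libraries; such libraries are near-exhaustive catalogs
of intron pairs occurring in nature, so an unseen pair marks a likely
artifact. Direct observation overrides the TN test; candidates meeting
neither are unlabeled and take no part in thresholding but are subject to
selection. Pairs involving a fusion splice are skipped in the TN test (they
cannot occur in annotation), and the ROC itself is computed on non-fusion
candidates only, the resulting threshold then applied to fusion candidates.
A positive call is abundance strictly greater than the threshold — the same
strict inequality used for final selection — over a grid of the observed
abundances plus 0 and +∞; the chosen threshold is the smallest grid value
whose FPR meets the target. Alternatively a manual threshold (e.g.
RPKM > 10) is supplied and the achieved FPR reported.

## Benchmarking

Predicted fusion gene pairs are matched (unordered) against a gold-standard
pair list; locus labels match a gold gene when the position falls inside
the gene's annotated span, and each gold pair counts at most once.
Sensitivity is matched/gold, precision matched/predicted, F-score their
harmonic mean; ratios are exact and rounding (half-up; percentages to two
decimals, F to four) happens only at formatting.

## The simulator and what passing means

`longfuse.simulate` generates the study conditions end to end: random
chromosomes; non-overlapping genes (3–8 exons of 120–400 bp, introns of
200–2000 bp) whose introns all carry GT–AG on the gene strand (written into
the genome, so strand determination and canonical flagging are exercised
for real); 1–3 expressed isoforms per gene (full chain plus exon-skipping
variants); fusion events joining a 5′ exon prefix of one gene to a 3′ exon
suffix of another (inter-chromosomal or ≥ 100 kb apart), each with 1–6
fusion splices at exon boundaries — canonical by construction, since the
flanks inherit the genes' own intron signals. Expression levels θ\* are
drawn lognormal (σ = 1) around `short_read_depth / read_length`, matching
the heavy-tailed dynamic range of real transcriptomes. Long reads are
full-length transcript copies with independent per-base substitution,
insertion and deletion errors (defaults 1 % each, emulating error-corrected
long reads; raw 15 %-error reads are not modeled) and a polyA tail; their
truth SAM encodes introns as N-gaps and fusion junctions as primary +
supplementary split records, with CIGARs and NM tags reflecting the
injected errors exactly. Short reads (default 101 bp) are sampled
uniformly per isoform at rate θ\*(L − rl + 1), error-free, with exact
spliced truth alignments. One RNG stream per run makes every output
byte-reproducible under a fixed seed.

Because truth alignments are emitted directly, passing tests demonstrate
the correctness of the method's own logic — candidate filtering, ARS
geometry, junction mapping, reconstruction, estimation, selection — under
idealized alignment. They do not demonstrate robustness to aligner
artifacts, repeat-induced mis-splitting, uncorrected error regimes,
sequence-dependent coverage bias, or annotation errors; on real data those
enter through the upstream aligners. The default desk-scale conditions
(2 × 1 Mb, 40 genes, 5 fusions) make the end-to-end suite complete in
seconds; counts from the original application (dozens of fusion genes from
millions of reads) are properties of that dataset, not reproducible at this
scale.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; 1-based appears
  only in reports and at annotation-format edges.
- SAM D operations are treated like N for splice calling (aligners encode
  introns either way); the 68 bp threshold is strict (a 68 bp gap is a
  deletion, 69 bp a splice), as are the 100 bp fragment-length (a 100 bp
  fragment fails) and 12 bp overhang (11 rejects) thresholds.
- `canonical_fraction` of an empty site list, RPKM with `N = 0`, precision
  with zero predictions, and an FPR with no TN labels are errors, not
  silent zeros.
- ARS extensions are clipped at chromosome ends with a warning; a junction
  at a chromosome edge is non-canonical by definition.
- EM returns the best iterate with a warning flag if the tolerance is not
  met within `max_iter` (10 000); with all-zero counts θ is identically 0.
- Ties at the selection threshold are excluded (strict `>`), consistently
  between ROC counting and selection.

## Known limitations

- The identity-difference filter is only as good as the alternative
  alignments present in the input; with no secondary records it passes
  everything.
- Long-read support assignment among several nearby sites of one fusion
  uses the `long_read_window` proximity rule; reads between two sites
  closer than the window count for both.
- Isoform 5′ ends come only from annotation (no CAGE ingestion); novel
  TSSs of unannotated genes are approximated by fragment extents only
  insofar as annotated ends exist at the locus.
- Intra-chromosomal fusions closer than 100 kb in the same orientation are
  indistinguishable from long introns without annotation evidence and are
  excluded by design, as are fusions whose reads cannot satisfy the 2-long
  + 2-short support minimum.
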