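# longfuse

Fusion gene, fusion site and fusion isoform detection from **hybrid**
transcriptome sequencing — long reads plus short reads together.

Gene fusions are a recurrent driver and biomarker in cancer, yet the two
read types each see only half the picture: long reads span fusion junctions
and whole isoforms but carry residual error that blurs the exact breakpoint,
while accurate short reads rarely bridge a junction unambiguously on a
whole-genome scale. `longfuse` combines them:

1. **Fusion genes** — a long read spanning a fusion splits into two
   *fragment alignments*; pairs of fragments from one read passing length,
   locus-separation, overlap and unaligned-gap conditions, an
   alignment-ambiguity (identity-difference) filter and a
   transcription-strand consistency filter become fusion gene candidates.
2. **Fusion sites** — for each candidate an *artificial reference sequence*
   (ARS) concatenates the two genomic windows around the junction (each
   extended 2 kb). Short reads spliced across the ARS boundary determine
   the junction at single-nucleotide resolution; sites need ≥ 2 supporting
   long reads and ≥ 2 short reads, and are annotated with the MSFL
   uniqueness statistic and a canonical GT–AG flag.
3. **Fusion isoforms** — long-read alignment gaps > 68 bp are called as
   splices, encoded as *splice linkages* over exon-boundary markers,
   de-redundified, and used as seeds to enumerate isoform candidates
   (fusion candidates join a 5′-gene segment and a 3′-gene segment at one
   fusion splice). Abundances θ (reads per base) are estimated by the
   Poisson segment-count model maximized with EM, reported as
   RPKM = 10⁹·θ/N, and significantly expressed isoforms are selected by an
   abundance threshold chosen from a ROC over directly observed (TP) vs
   annotation-contradicting (TN) candidates at a target false-positive
   rate, or a manual threshold such as RPKM > 10.

A fully ground-truthed simulator (`longfuse.simulate`) generates genomes
with GT–AG gene models, fusion events, noisy long reads and spliced short
reads in standard formats, so the whole pipeline is testable end to end
without downloads. See `docs/methods.md` for the model details and
assumptions.

## Worked example

Simulate a dataset (2 × 1 Mb chromosomes, 40 genes, 5 fusion events,
error-free long reads) and run the full pipeline:

```bash
longfuse simulate --seed 7 --error-free --out sim
# simulated 40 genes, 5 fusions, 90 isoforms -> sim

longfuse all \
    --genome sim/genome.fa --annotation sim/annotation.genePred \
    --long-reads sim/long_reads.sam --short-reads sim/short_reads.tsv \
    --long-read-fasta sim/long_reads.fa --workdir work
# 5 fusion genes, 6 fusion sites, 90 isoform candidates, 90 selected (threshold RPKM > 10)
```

`work/fusion_sites.tsv` reports each fusion site in 1-based genome
coordinates with its support:

```
gene5  gene3  chrom5  pos5    chrom3  pos3    strand5 strand3 n_long_reads  n_short_reads  MSFL  canonical
g12    g1     chr2    128994  chr1    12150   -       -       5             29             314   yes
g11    g26    chr1    102724  chr2    279299  +       -       5             43             144   yes
g39    g4     chr1    370764  chr2    31891   +       -       5             26             387   yes
```

Each row is one junction: `pos5` is the last base of the 5′ gene segment
and `pos3` the first base of the 3′ gene segment; 5 long reads and tens of
short reads support each site; the MSFL (longest "shorter flanking
fragment" over supporting long reads) indicates how uniquely the long-read
evidence maps; all sites fall at exon boundaries and carry the canonical
GT–AG signal. `work/abundance.tsv` gives per-isoform estimates:

```
isoform_id      locus    length  theta     rpkm        is_fusion  label  selected
g1.s1.1         g1       913     0.166606  3665.2849   0          TP     1
g12--g1.s1.f1   g12--g1  715     0.328680  7230.8845   1          TP     1
```

`theta` is expected short reads per transcript base; with ~45k mapped
short reads in this small dataset the RPKM values are in the thousands, and
all 90 reconstructed isoforms (every simulated one, fusion isoforms
included) clear the RPKM > 10 threshold.

Per-stage subcommands (`detect`, `ars`, `sites`, `isoforms`, `quantify`,
`select`, `benchmark`) chain through files in standard formats — candidate
TSV, ARS FASTA with coordinate sidecars, fusion-site TSV, isoform GTF — so
any stage can be fed externally produced data (e.g. real GMAP/STAR
alignments) in place of the simulator's truth alignments.

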