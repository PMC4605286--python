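"""Shared fixtures: tiny deterministic genomes, fragment builders, and a
small simulated dataset used by integration tests."""
from __future__ import annotations

import numpy as np
import pytest

from longfuse.model import FragmentAlignment, FusionCandidate, GenomeInterval, LongReadAlignmentSet
from longfuse.simulate import SimConfig, simulate_dataset


def make_fragment(
    read_id="r1",
    read_start=0,
    read_end=150,
    chrom="chr1",
    g_start=10_000,
    g_end=11_000,
    strand="+",
    identity=1.0,
    gaps=(),
    rank=0,
):
    span = GenomeInterval(chrom, g_start, g_end, strand)
    return FragmentAlignment(
        read_id=read_id,
        read_start=read_start,
        read_end=read_end,
        genome_span=span,
        n_matches=int(identity * len(span)),
        identity=identity,
        rank=rank,
        gaps=list(gaps),
    )


def make_read(fragments, read_length=None, alternatives=None):
    rl = read_length or max(f.read_end for f in fragments)
    aln = LongReadAlignmentSet(read_id=fragments[0].read_id, read_length=rl, fragments=list(fragments))
    aln.sort()
    if alternatives:
        aln.alternatives = alternatives
    return aln


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)


@pytest.fixture(scope="session")
def small_genome():
    """Two 20 kb random chromosomes as plain strings."""
    r = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {c: "".join(r.choice(bases, size=20_000)) for c in ("chr1", "chr2")}


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Small error-free simulation shared across integration tests:
    2 x 300 kb chromosomes, 14 genes, 2 fusions."""
    outdir = tmp_path_factory.mktemp("sim_small")
    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=300_000,
        n_genes=14,
        n_fusions=2,
        long_read_sub_rate=0.0,
        long_read_ins_rate=0.0,
        long_read_del_rate=0.0,
        short_read_depth=25,
    )
    truth = simulate_dataset(cfg, outdir)
    return cfg, truth, outdir


__all__ = ["make_fragment", "make_read"]
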