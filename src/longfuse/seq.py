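"""Small sequence helpers shared across modules."""
from __future__ import annotations

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) (plus strand) from a pyfaidx.Fasta, a dict of
    strings, or anything mapping chrom -> sliceable sequence."""
    if start >= end:
        return ""
    piece = genome[chrom][start:end]
    return str(piece).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])
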