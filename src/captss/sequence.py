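"""Low-level nucleotide sequence helpers shared across the package.

Sequences are plain uppercase strings over {A, C, G, T, N}.  For numeric
work they are encoded as ``numpy.uint8`` arrays with A=0, C=1, G=2, T=3 and
N (or any other character) = 4, so that a dinucleotide starting at position
``i`` has the code ``4 * a[i] + a[i + 1]`` whenever both bases are < 4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0,C=1,G=2,T=3,other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return seq.translate(_COMPLEMENT)[::-1]


def oriented_slice(contig_seq: str, strand: str, five_pos: int, length: int) -> str | None:
    """Sequence of ``length`` nt read in transcript orientation from ``five_pos``.

    On '+' this is ``contig_seq[five_pos : five_pos + length]``; on '-' it is
    the reverse complement of the upstream-facing slice, so the returned
    string always starts with the base at ``five_pos``.  Returns None when
    the requested span leaves the contig.
    """
    if strand == "+":
        if five_pos < 0 or five_pos + length > len(contig_seq):
            return None
        return contig_seq[five_pos : five_pos + length]
    start = five_pos - length + 1
    if start < 0 or five_pos + 1 > len(contig_seq):
        return None
    return revcomp(contig_seq[start : five_pos + 1])


def offset_window(contig_seq: str, strand: str, anchor: int, upstream: int, downstream: int) -> str | None:
    """Strand-oriented window covering anchor-relative offsets [-upstream, downstream-1].

    The anchor base sits at index ``upstream`` of the returned string.
    Returns None when the window leaves the contig.
    """
    length = upstream + downstream
    if strand == "+":
        start = anchor - upstream
        if start < 0 or start + length > len(contig_seq):
            return None
        return contig_seq[start : start + length]
    # '-' strand: offset o maps to genomic position anchor - o
    start = anchor - downstream + 1
    if start < 0 or anchor + upstream + 1 > len(contig_seq):
        return None
    return revcomp(contig_seq[start : anchor + upstream + 1])
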