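"""Placement of oligo-cap tags on the genome.

The 5'-most template base of each uniquely mapped tag defines a TSS (for a
non-trans-spliced tag) or a first-exon 5' end (for a trans-spliced tag,
whose leader has been stripped).  Mapping policy:

* edit allowance: mismatches + indels <= floor(0.10 * tag length)
  (a 90% match criterion including insertions and deletions);
* the tag's first base must itself be aligned — never clipped or inserted;
* only a unique best hit counts: if two distinct loci attain the minimal
  edit count the tag is discarded as a multiple hit.

The built-in aligner targets desk-scale genomes (tens of Mb): a sorted
k-mer index proposes candidate 5'-anchored placements and edlib evaluates
each within the edit bound.  Placements within one tag length on the same
contig/strand are treated as the same locus, so small indel-induced jitter
does not masquerade as a multiple hit.  For larger genomes, alignments from
an external aligner can be ingested from SAM with the same rules applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np

from .read_processing import NON_TRANS_SPLICED, TRANS_SPLICED, CapTag
from .sequence import encode, revcomp

log = logging.getLogger(__name__)

NO_HIT = "no_hit"
MULTIPLE_HITS = "multiple_hits"
FIVE_PRIME_UNALIGNED = "five_prime_unaligned"


def edit_allowance(tag_length: int, identity: float = 0.90) -> int:
    """Maximum edits for a tag: floor((1 - identity) * length)."""
    return int((1.0 - identity) * tag_length)


def tss_coordinate(start: int, end: int, strand: str) -> int:
    """5'-most template base of an alignment span [start, end): start on '+', end-1 on '-'."""
    return start if strand == "+" else end - 1


@dataclass(slots=True)
class MappedTag:
    read_id: str
    contig: str
    strand: str
    tss_pos: int
    edits: int
    read_class: str
    dataset_id: str
    acceptor_ok: bool | None = None


@dataclass(slots=True)
class Unmapped:
    read_id: str
    reason: str


class GenomeIndex:
    """Sorted k-mer index over both strands of a genome.

    Contigs (and their reverse complements) are concatenated with N spacers;
    k-mers containing N are excluded.  Lookup is O(log n) by binary search
    on the sorted code array.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.names = list(genome)
        self.lengths = [len(genome[n]) for n in self.names]
        spacer = "N" * k
        segments: list[str] = []
        self.seg_meta: list[tuple[int, int, str, int, str]] = []  # (start, end, contig, length, strand)
        pos = 0
        for name in self.names:
            seq = genome[name].upper()
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                segments.append(s)
                self.seg_meta.append((pos, pos + len(s), name, len(s), strand))
                pos += len(s) + k
                segments.append(spacer)
        self.concat = "".join(segments)
        self.arr = encode(self.concat)
        self.seg_starts = np.array([m[0] for m in self.seg_meta], dtype=np.int64)
        self._build()

    def _build(self) -> None:
        arr = self.arr.astype(np.int64)
        k = self.k
        n = arr.size - k + 1
        if n <= 0:
            raise ValueError("genome shorter than k")
        codes = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for i in range(k):
            w = arr[i : i + n]
            codes = (codes << 2) | (w & 3)
            valid &= w < 4
        self.positions = np.flatnonzero(valid).astype(np.int64)
        codes = codes[self.positions]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_positions = self.positions[order]

    def kmer_code(self, kmer_arr: np.ndarray) -> int | None:
        if np.any(kmer_arr >= 4):
            return None
        code = 0
        for v in kmer_arr:
            code = (code << 2) | int(v)
        return code

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.sorted_positions[lo:hi]

    def segment_of(self, concat_pos: int) -> tuple[int, int, str, int, str]:
        i = int(np.searchsorted(self.seg_starts, concat_pos, side="right")) - 1
        return self.seg_meta[i]


def _seed_offsets(tag_len: int, k: int, n_errors: int) -> list[int]:
    """Seed offsets guaranteeing detection when errors permit an exact k-mer."""
    if tag_len <= k:
        return [0]
    n_seeds = min(n_errors + 2, (tag_len - 1) // k + 1)
    n_seeds = max(n_seeds, 2)
    return sorted({round(i * (tag_len - k) / (n_seeds - 1)) for i in range(n_seeds)})


def map_unique(
    tag: CapTag,
    index: GenomeIndex,
    identity: float = 0.90,
) -> MappedTag | Unmapped:
    """Map one tag to its unique best 5'-anchored placement, if any."""
    seq = tag.seq
    L = len(seq)
    k = index.k
    if L < k:
        log.warning("tag %s shorter than k=%d; unmapped", tag.read_id, k)
        return Unmapped(tag.read_id, NO_HIT)
    allow = edit_allowance(L, identity)
    arr = encode(seq)

    candidates: set[tuple[int, int]] = set()  # (concat_start, segment index)
    overhang_seen = False
    for off in _seed_offsets(L, k, allow):
        code = index.kmer_code(arr[off : off + k])
        if code is None:
            continue
        for p in index.lookup(code):
            seg_i = int(np.searchsorted(index.seg_starts, int(p), side="right")) - 1
            base = int(p) - off
            for shift in (-1, 0, 1) if allow else (0,):
                candidates.add((base + shift, seg_i))

    if not candidates:
        return Unmapped(tag.read_id, NO_HIT)

    # evaluate 5'-anchored edit distance at each candidate start
    placements: list[tuple[int, int]] = []  # (concat_start, edits)
    for s, seg_i in candidates:
        seg_start, seg_end, _, _, _ = index.seg_meta[seg_i]
        if s < seg_start:
            # the tag's 5' end would fall before the contig (or its reverse
            # complement) begins: its first base cannot be aligned here
            overhang_seen = True
            continue
        if s >= seg_end:
            continue
        target = index.concat[s : min(s + L + allow, seg_end)]
        if len(target) < L - allow:
            continue
        res = edlib.align(seq, target, mode="SHW", task="distance", k=allow)
        d = res["editDistance"]
        if d == -1:
            continue
        placements.append((s, d))

    if not placements:
        return Unmapped(tag.read_id, FIVE_PRIME_UNALIGNED if overhang_seen else NO_HIT)

    best = min(d for _, d in placements)
    best_placements = sorted(s for s, d in placements if d == best)
    # cluster placements within one tag length into loci
    loci: list[int] = [best_placements[0]]
    for s in best_placements[1:]:
        if s - loci[-1] > L:
            loci.append(s)
    if len(loci) > 1:
        return Unmapped(tag.read_id, MULTIPLE_HITS)

    s = loci[0]
    seg_start, _, contig, seg_len, strand = index.segment_of(s)
    within = s - seg_start
    if strand == "+":
        tss = within
    else:
        tss = seg_len - 1 - within
    return MappedTag(
        read_id=tag.read_id,
        contig=contig,
        strand=strand,
        tss_pos=tss,
        edits=best,
        read_class=tag.read_class,
        dataset_id=tag.dataset_id,
    )


def map_many(
    tags: Iterable[CapTag],
    index: GenomeIndex,
    identity: float = 0.90,
    tally: dict[str, int] | None = None,
) -> list[MappedTag]:
    """Map a tag stream, memoising by sequence (TSS-seq tags repeat heavily)."""
    cache: dict[str, MappedTag | Unmapped | None] = {}
    out: list[MappedTag] = []
    tally = tally if tally is not None else {}
    for tag in tags:
        hit = cache.get(tag.seq, False)
        if hit is False:
            hit = map_unique(tag, index, identity)
            cache[tag.seq] = hit
        if isinstance(hit, MappedTag):
            out.append(
                MappedTag(
                    read_id=tag.read_id,
                    contig=hit.contig,
                    strand=hit.strand,
                    tss_pos=hit.tss_pos,
                    edits=hit.edits,
                    read_class=tag.read_class,
                    dataset_id=tag.dataset_id,
                )
            )
            tally["mapped"] = tally.get("mapped", 0) + 1
        else:
            tally[hit.reason] = tally.get(hit.reason, 0) + 1
    return out


def check_acceptor(mapped: MappedTag, genome: Mapping[str, str]) -> bool:
    """True iff the 2 genomic bases immediately 5' of the tag are the AG acceptor.

    Trans-splicing joins the leader to the first exon at a splice acceptor,
    so on '+' the bases at [tss-2, tss) should read AG; on '-' the bases at
    [tss+1, tss+3) read CT on the plus strand.
    """
    seq = genome[mapped.contig]
    if mapped.strand == "+":
        if mapped.tss_pos < 2:
            return False
        return seq[mapped.tss_pos - 2 : mapped.tss_pos] == "AG"
    if mapped.tss_pos + 3 > len(seq):
        return False
    return seq[mapped.tss_pos + 1 : mapped.tss_pos + 3] == "CT"


def annotate_acceptors(
    mapped: Iterable[MappedTag],
    genome: Mapping[str, str],
    strict: bool = False,
) -> list[MappedTag]:
    """Fill ``acceptor_ok`` on trans-spliced tags; drop failures in strict mode."""
    out = []
    for m in mapped:
        if m.read_class == TRANS_SPLICED:
            m.acceptor_ok = check_acceptor(m, genome)
            if strict and not m.acceptor_ok:
                continue
        out.append(m)
    return out


def ingest_sam(
    sam_path: str,
    tags_by_id: Mapping[str, CapTag],
    identity: float = 0.90,
    tally: dict[str, int] | None = None,
) -> list[MappedTag]:
    """Apply the unique-best-hit / 90% / 5'-aligned rules to external alignments.

    Records are grouped by read id; the primary alignment is the candidate
    placement and any other alignment (secondary/supplementary) with an
    equal-or-better edit count makes the read a multiple hit.  5' soft or
    hard clipping (strand-aware) voids the placement.
    """
    import pysam

    tally = tally if tally is not None else {}
    by_read: dict[str, list] = {}
    skipped_unknown = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.query_name not in tags_by_id:
                skipped_unknown += 1
                continue
            by_read.setdefault(rec.query_name, []).append(rec)
    if skipped_unknown:
        log.warning("ingest_sam: %d records with unknown read ids skipped", skipped_unknown)
        tally["unknown_id"] = tally.get("unknown_id", 0) + skipped_unknown

    out: list[MappedTag] = []
    for read_id, recs in by_read.items():
        tag = tags_by_id[read_id]
        allow = edit_allowance(len(tag.seq), identity)
        primary = [r for r in recs if not r.is_unmapped and not r.is_secondary and not r.is_supplementary]
        others = [r for r in recs if not r.is_unmapped and (r.is_secondary or r.is_supplementary)]
        if not primary:
            tally[NO_HIT] = tally.get(NO_HIT, 0) + 1
            continue
        rec = primary[0]
        nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
        cig = rec.cigartuples or []
        # CIGAR ops 4 = soft clip, 5 = hard clip; the 5' end of the read is
        # the first op on '+' and the last op on '-'
        five_op = cig[-1] if rec.is_reverse else cig[0] if cig else None
        clipped5 = five_op is not None and five_op[0] in (4, 5)
        clip_total = sum(ln for op, ln in cig if op in (4, 5))
        edits = int(nm) + clip_total  # unaligned tag bases count against identity
        if clipped5:
            tally[FIVE_PRIME_UNALIGNED] = tally.get(FIVE_PRIME_UNALIGNED, 0) + 1
            continue
        if edits > allow:
            tally[NO_HIT] = tally.get(NO_HIT, 0) + 1
            continue
        tied = False
        for o in others:
            o_nm = o.get_tag("NM") if o.has_tag("NM") else 0
            o_clip = sum(ln for op, ln in (o.cigartuples or []) if op in (4, 5))
            if int(o_nm) + o_clip <= edits:
                tied = True
                break
        if tied:
            tally[MULTIPLE_HITS] = tally.get(MULTIPLE_HITS, 0) + 1
            continue
        strand = "-" if rec.is_reverse else "+"
        tss = tss_coordinate(rec.reference_start, rec.reference_end, strand)
        out.append(
            MappedTag(
                read_id=read_id,
                contig=rec.reference_name,
                strand=strand,
                tss_pos=tss,
                edits=int(nm),
                read_class=tag.read_class,
                dataset_id=tag.dataset_id,
            )
        )
        tally["mapped"] = tally.get("mapped", 0) + 1
    return out
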