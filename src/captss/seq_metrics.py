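"""Dinucleotide statistics over genomic windows.

The central quantity is the CpG *score*, the observed/expected ratio
``CpG * N / (C * G)`` computed in a window of fixed size N, where C, G and
CpG are observed counts.  A score near 1 means CpG occurs as often as the
mononucleotide composition predicts; scores well below 1 are the footprint
of methylation-driven deamination (methylated CpG mutates to TpG/CpA over
evolutionary time).  The CpG *content* is the plain density CpG / (N - 1),
whose expectation for i.i.d. uniform sequence is 1/16.  Both generalise to
any dinucleotide XY as XY * N / (X * Y); TpG and CpA scores above 1 are the
complementary footprint of the same mutational process.

Conventions: dinucleotide counting is overlapping; any pair containing an
ambiguous base contributes to no dinucleotide; mononucleotide counts and
the G+C denominator exclude ambiguous bases; a score whose mononucleotide
denominator is zero is MISSING (returned as None).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .sequence import BASES, N_CODE, encode

log = logging.getLogger(__name__)

#: the 16 dinucleotides in row-major (first base, second base) order
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: pyrimidine-purine (YR) initiator dinucleotides
YR_DINUCLEOTIDES = ("CA", "CG", "TA", "TG")


def _pair_codes(arr: np.ndarray) -> np.ndarray:
    """Codes 0..15 of valid overlapping pairs; pairs touching N are dropped."""
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    a, b = arr[:-1], arr[1:]
    valid = (a < N_CODE) & (b < N_CODE)
    return (a[valid].astype(np.int64) << 2) | b[valid]


def count_dinucleotides(seq: str | np.ndarray) -> dict[str, int]:
    """Overlapping counts of all 16 dinucleotides; N-containing pairs dropped."""
    arr = encode(seq) if isinstance(seq, str) else seq
    codes = _pair_codes(arr)
    counts = np.bincount(codes, minlength=16)
    return {d: int(counts[i]) for i, d in enumerate(DINUCLEOTIDES)}


def _base_counts(arr: np.ndarray) -> np.ndarray:
    return np.bincount(arr, minlength=5)[:4]


def dinuc_score(seq: str | np.ndarray, xy: str) -> float | None:
    """Observed/expected score XY * N / (X * Y); None when X or Y is absent.

    N is the window length (including ambiguous positions, which is the
    fixed window size of the scan that produced the sequence).
    """
    xy = xy.upper()
    if len(xy) != 2 or any(b not in BASES for b in xy):
        raise ValueError(f"not a dinucleotide: {xy!r}")
    arr = encode(seq) if isinstance(seq, str) else seq
    n = arr.size
    bc = _base_counts(arr)
    x = int(bc[BASES.index(xy[0])])
    y = int(bc[BASES.index(xy[1])])
    if x == 0 or y == 0:
        return None
    code = (BASES.index(xy[0]) << 2) | BASES.index(xy[1])
    pair = int(np.count_nonzero(_pair_codes(arr) == code))
    return pair * n / (x * y)


def cpg_score(seq: str | np.ndarray) -> float | None:
    """CpG * N / (C * G); None (MISSING) when the window has no C or no G."""
    return dinuc_score(seq, "CG")


def cpg_content(seq: str | np.ndarray) -> float:
    """CpG count over the N - 1 dinucleotide slots (1/16 for random sequence)."""
    arr = encode(seq) if isinstance(seq, str) else seq
    if arr.size < 2:
        return 0.0
    pair = int(np.count_nonzero(_pair_codes(arr) == ((1 << 2) | 2)))
    return pair / (arr.size - 1)


def gc_content(seq: str | np.ndarray) -> float | None:
    """(C + G) fraction of unambiguous bases; None if every base is ambiguous."""
    arr = encode(seq) if isinstance(seq, str) else seq
    bc = _base_counts(arr)
    denom = int(bc.sum())
    if denom == 0:
        return None
    return float(bc[1] + bc[2]) / denom


@dataclass(slots=True)
class WindowMetric:
    """Per-window dinucleotide statistics from a genome scan."""

    contig: str
    start: int  # 0-based half-open
    end: int
    n: int
    counts: dict[str, int]
    c_count: int
    g_count: int
    a_count: int
    t_count: int
    cpg_score: float | None
    gc_content: float | None
    cpg_content: float
    ambiguous_frac: float = 0.0
    flagged: bool = False  # too many ambiguous bases; excluded from histograms


def window_metric(contig: str, start: int, arr: np.ndarray, max_ambiguous_frac: float = 0.0) -> WindowMetric:
    n = arr.size
    bc = _base_counts(arr)
    counts16 = np.bincount(_pair_codes(arr), minlength=16)
    counts = {d: int(counts16[i]) for i, d in enumerate(DINUCLEOTIDES)}
    c, g = int(bc[1]), int(bc[2])
    unamb = int(bc.sum())
    amb_frac = 1.0 - unamb / n if n else 0.0
    cg = counts["CG"]
    return WindowMetric(
        contig=contig,
        start=start,
        end=start + n,
        n=n,
        counts=counts,
        a_count=int(bc[0]),
        c_count=c,
        g_count=g,
        t_count=int(bc[3]),
        cpg_score=None if c == 0 or g == 0 else cg * n / (c * g),
        gc_content=None if unamb == 0 else (c + g) / unamb,
        cpg_content=cg / (n - 1) if n > 1 else 0.0,
        ambiguous_frac=amb_frac,
        flagged=amb_frac > max_ambiguous_frac,
    )


def sliding_window_scan(
    genome: Mapping[str, str],
    window_size: int = 1000,
    step: int | None = None,
    max_ambiguous_frac: float = 0.0,
) -> Iterator[WindowMetric]:
    """Scan every contig with fixed windows; truncated end windows are not emitted.

    Windows whose ambiguous-base fraction exceeds ``max_ambiguous_frac`` are
    emitted flagged so downstream histograms can exclude them.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    step = window_size if step is None else step
    for name, seq in genome.items():
        if len(seq) < window_size:
            log.warning("contig %s shorter than window (%d < %d): no windows", name, len(seq), window_size)
            continue
        arr = encode(seq)
        for start in range(0, len(seq) - window_size + 1, step):
            yield window_metric(name, start, arr[start : start + window_size], max_ambiguous_frac)


# ---------------------------------------------------------------------------
# vectorised window scores (used by meta-profiles and large scans)

def windowed_pair_scores(arr: np.ndarray, xy: str, window: int) -> np.ndarray:
    """Score XY*N/(X*Y) for every step-1 window; NaN where MISSING.

    Returns an array of length ``len(arr) - window + 1``.
    """
    x_i, y_i = BASES.index(xy[0]), BASES.index(xy[1])
    a, b = arr[:-1], arr[1:]
    pair = ((a == x_i) & (b == y_i)).astype(np.int32)
    xs = (arr == x_i).astype(np.int32)
    ys = (arr == y_i).astype(np.int32)
    # window [s, s+window): pairs start at s .. s+window-2
    pw = np.convolve(pair, np.ones(window - 1, dtype=np.int32), "valid")[: len(arr) - window + 1]
    xw = np.convolve(xs, np.ones(window, dtype=np.int32), "valid")
    yw = np.convolve(ys, np.ones(window, dtype=np.int32), "valid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = pw * window / (xw.astype(float) * yw)
    out[(xw == 0) | (yw == 0)] = np.nan
    return out


def windowed_gc(arr: np.ndarray, window: int) -> np.ndarray:
    gc = ((arr == 1) | (arr == 2)).astype(np.int32)
    unamb = (arr < N_CODE).astype(np.int32)
    gw = np.convolve(gc, np.ones(window, dtype=np.int32), "valid")
    uw = np.convolve(unamb, np.ones(window, dtype=np.int32), "valid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = gw / uw.astype(float)
    out[uw == 0] = np.nan
    return out


def windowed_pair_content(arr: np.ndarray, xy: str, window: int) -> np.ndarray:
    x_i, y_i = BASES.index(xy[0]), BASES.index(xy[1])
    a, b = arr[:-1], arr[1:]
    pair = ((a == x_i) & (b == y_i)).astype(np.int32)
    pw = np.convolve(pair, np.ones(window - 1, dtype=np.int32), "valid")[: len(arr) - window + 1]
    return pw / (window - 1)


# ---------------------------------------------------------------------------
# CpG islands and promoter classification

@dataclass(slots=True)
class IslandCall:
    """Result of the conventional CpG-island test on one sequence."""

    is_island: bool
    reason: str
    best_start: int | None = None
    best_gc: float | None = None
    best_score: float | None = None
    qualifying_runs: list[tuple[int, int]] = field(default_factory=list)


def is_cpg_island(
    seq: str,
    window: int = 200,
    gc_min: float = 0.5,
    score_min: float = 0.6,
) -> IslandCall:
    """Conventional vertebrate CpG-island test.

    TRUE iff some ``window``-nt stretch (scanned at step 1) has G+C content
    >= ``gc_min`` and CpG score >= ``score_min``.  The best window reported
    is the qualifying one with the highest CpG score (or, failing any, the
    highest-scoring window overall).  Runs of adjacent qualifying window
    starts are merged and reported but do not affect the boolean call.
    """
    if len(seq) < window:
        return IslandCall(False, "too short")
    arr = encode(seq)
    scores = windowed_pair_scores(arr, "CG", window)
    gcs = windowed_gc(arr, window)
    with np.errstate(invalid="ignore"):
        ok = (gcs >= gc_min) & (scores >= score_min)
    ok &= ~np.isnan(scores)
    runs: list[tuple[int, int]] = []
    if ok.any():
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        runs = [(int(idx[s]), int(idx[e]) + window) for s, e in zip(starts, ends)]
        cand = idx[np.nanargmax(scores[idx])]
        return IslandCall(True, "criteria met", int(cand), float(gcs[cand]), float(scores[cand]), runs)
    if np.all(np.isnan(scores)):
        return IslandCall(False, "no scorable window")
    best = int(np.nanargmax(scores))
    return IslandCall(False, "criteria not met", best, float(gcs[best]), float(scores[best]), runs)


def classify_promoter_cpg(
    seq200: str,
    poor_max: float = 0.5,
    rich_min: float = 0.6,
    expected_length: int = 200,
) -> str:
    """Classify the 200-nt window around a representative TSS by CpG score.

    poor if score < ``poor_max``; rich if score > ``rich_min`` (strict
    inequalities, so boundary scores fall in the intermediate class);
    unclassifiable when the score is MISSING.
    """
    if len(seq200) != expected_length:
        raise ValueError(f"classification window must be {expected_length} nt, got {len(seq200)}")
    score = cpg_score(seq200)
    if score is None:
        return "unclassifiable"
    if score < poor_max:
        return "poor"
    if score > rich_min:
        return "rich"
    return "intermediate"


def window_metric_table(metrics: Iterable[WindowMetric]):
    """WindowMetric stream -> pandas DataFrame (one row per window)."""
    import pandas as pd

    rows = []
    for m in metrics:
        row = {
            "contig": m.contig,
            "start": m.start,
            "end": m.end,
            "n": m.n,
            "a_count": m.a_count,
            "c_count": m.c_count,
            "g_count": m.g_count,
            "t_count": m.t_count,
            "cpg_score": np.nan if m.cpg_score is None else m.cpg_score,
            "gc_content": np.nan if m.gc_content is None else m.gc_content,
            "cpg_content": m.cpg_content,
            "ambiguous_frac": m.ambiguous_frac,
            "flagged": m.flagged,
        }
        for d in DINUCLEOTIDES:
            row[d] = m.counts[d]
        rows.append(row)
    return pd.DataFrame(rows)
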