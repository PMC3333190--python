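"""Promoter sequence profiling around representative TSSs.

Offsets follow the TSS-relative convention: the representative TSS base is
position 0, the next base upstream is -1 and downstream is +1.  The 1-kb
promoter is the fragment covering offsets -499..+500; meta-profiles use a
4-kb excision (offsets -2000..+1999) scanned with a centred 100-nt moving
window.  The initiator consensus at metazoan TSSs is pyrimidine-purine
(YR) across offsets (-1, 0); YR-usage statistics ignore non-YR TSSs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import seq_metrics
from .promoter_calling import PromoterCluster
from .seq_metrics import YR_DINUCLEOTIDES
from .sequence import N_CODE, encode, offset_window

log = logging.getLogger(__name__)


def extract_promoter_seq(
    genome: Mapping[str, str],
    contig: str,
    strand: str,
    tss_pos: int,
    upstream: int = 499,
    downstream: int = 501,
) -> str | None:
    """Strand-oriented sequence covering offsets [-upstream, downstream-1].

    The TSS base sits at index ``upstream`` of the returned string.  Returns
    None (caller tallies the exclusion) when the span leaves the contig.
    """
    return offset_window(genome[contig], strand, tss_pos, upstream, downstream)


def extract_promoter_set(
    genome: Mapping[str, str],
    promoters: Iterable[tuple[str, str, int]],
    upstream: int = 499,
    downstream: int = 501,
) -> tuple[list[str], int]:
    """Extract oriented windows for (contig, strand, tss) triples.

    Returns (sequences, n_excluded_at_edge).
    """
    seqs: list[str] = []
    excluded = 0
    for contig, strand, tss in promoters:
        s = extract_promoter_seq(genome, contig, strand, tss, upstream, downstream)
        if s is None:
            excluded += 1
        else:
            seqs.append(s)
    if excluded:
        log.info("extract_promoter_set: %d promoters excluded at contig edges", excluded)
    return seqs, excluded


# ---------------------------------------------------------------------------
# score distributions

@dataclass(slots=True)
class Histogram:
    metric: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    n_missing: int
    mean: float
    median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


DEFAULT_BIN_WIDTH = {"score": 0.05, "content": 0.01}


def score_values(seqs: Sequence[str], metric: str) -> list[float | None]:
    """Per-sequence metric values; None marks MISSING scores."""
    if metric == "cpg_score":
        return [seq_metrics.cpg_score(s) for s in seqs]
    if metric == "gc_content":
        return [seq_metrics.gc_content(s) for s in seqs]
    if metric == "cpg_content":
        return [seq_metrics.cpg_content(s) for s in seqs]
    if metric.startswith("dinuc_score:"):
        xy = metric.split(":", 1)[1]
        return [seq_metrics.dinuc_score(s, xy) for s in seqs]
    raise ValueError(f"unknown metric {metric!r}")


def score_distribution(
    values: Sequence[float | None],
    metric: str = "cpg_score",
    bin_width: float | None = None,
    upper: float | None = None,
) -> Histogram:
    """Histogram + summary of a score sample; MISSING values counted apart."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH["content" if "content" in metric else "score"]
    clean = np.array([v for v in values if v is not None], dtype=float)
    n_missing = len(values) - clean.size
    if clean.size == 0:
        edges = np.array([0.0, bin_width])
        return Histogram(metric, edges, np.zeros(1, dtype=int), 0, n_missing, math.nan, math.nan)
    top = upper if upper is not None else float(clean.max())
    n_bins = max(1, int(math.ceil(top / bin_width - 1e-9)))
    edges = np.arange(0, (n_bins + 1) * bin_width - 1e-12, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(clean, bins=edges)
    return Histogram(
        metric=metric,
        bin_edges=edges,
        counts=counts,
        n=int(clean.size),
        n_missing=n_missing,
        mean=float(clean.mean()),
        median=float(np.median(clean)),
    )


def count_modes(hist: Histogram, smooth_width: int = 3, min_prominence_frac: float = 0.10) -> int:
    """Number of modes of a histogram after moving-average smoothing.

    A mode is a peak of the smoothed counts whose prominence is at least
    ``min_prominence_frac`` of the maximum smoothed count; the ends are
    zero-padded so boundary modes are counted.
    """
    c = hist.counts.astype(float)
    if c.sum() == 0:
        return 0
    kernel = np.ones(smooth_width) / smooth_width
    smoothed = np.convolve(c, kernel, mode="same")
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    peaks, _ = signal.find_peaks(padded, prominence=min_prominence_frac * padded.max())
    return int(len(peaks))


def mass_split(values: Sequence[float | None], low: float = 0.5, high: float = 0.6) -> tuple[float, float]:
    """Fractions of non-missing scores below ``low`` and above ``high``."""
    clean = np.array([v for v in values if v is not None], dtype=float)
    if clean.size == 0:
        return (math.nan, math.nan)
    return (float(np.mean(clean < low)), float(np.mean(clean > high)))


def compare_distributions(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test; returns (D, p)."""
    a = np.asarray([v for v in sample_a if v is not None], dtype=float)
    b = np.asarray([v for v in sample_b if v is not None], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_to_normal(sample: Sequence[float]):
    """One-sample KS against a normal fitted to the sample; returns (D, p)."""
    a = np.asarray([v for v in sample if v is not None], dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    res = stats.kstest(a, "norm", args=(a.mean(), a.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# meta-profiles

@dataclass(slots=True)
class MetaProfile:
    metric: str
    offsets: np.ndarray  # TSS-relative; 0 = TSS
    mean_by_offset: np.ndarray  # NaN where every window was MISSING
    n_by_offset: np.ndarray
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean_by_offset, "n": self.n_by_offset})


def meta_profile(
    seqs: Sequence[str],
    metric: str = "cpg_score",
    window: int = 100,
    upstream: int = 2000,
    centered: bool = True,
) -> MetaProfile:
    """Average a windowed metric across aligned promoter excisions.

    Every sequence must have the TSS at index ``upstream``.  The window at
    offset x covers offsets [x - window//2, x + window - window//2 - 1]
    when centred (default), or [x, x + window - 1] when 5'-anchored.
    Offsets whose window leaves the excision are not emitted; MISSING
    windows are ignored in the average, tracked by ``n_by_offset``.
    """
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    half = window // 2 if centered else 0
    sums: np.ndarray | None = None
    ns: np.ndarray | None = None
    for s in seqs:
        arr = encode(s)
        if metric == "cpg_score":
            vals = seq_metrics.windowed_pair_scores(arr, "CG", window)
        elif metric.startswith("dinuc_score:"):
            vals = seq_metrics.windowed_pair_scores(arr, metric.split(":", 1)[1], window)
        elif metric == "gc_content":
            vals = seq_metrics.windowed_gc(arr, window)
        elif metric == "cpg_content":
            vals = seq_metrics.windowed_pair_content(arr, "CG", window)
        elif metric.startswith("dinuc_content:"):
            vals = seq_metrics.windowed_pair_content(arr, metric.split(":", 1)[1], window)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        ok = ~np.isnan(vals)
        if sums is None:
            sums = np.zeros(vals.size)
            ns = np.zeros(vals.size, dtype=int)
        sums[ok] += vals[ok]
        ns += ok
    assert sums is not None and ns is not None
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / ns
    means[ns == 0] = np.nan
    # window start index w corresponds to offset w - upstream + half
    offsets = np.arange(sums.size) - upstream + half
    return MetaProfile(metric=metric, offsets=offsets, mean_by_offset=means, n_by_offset=ns, window=window)


# ---------------------------------------------------------------------------
# logo matrix and YR usage

def logo_matrix(seqs: Sequence[str], offsets: Sequence[int], tss_index: int) -> pd.DataFrame:
    """Position x {A,C,G,T} frequency matrix around the TSS.

    ``tss_index`` is the string index of offset 0.  Columns sum to 1 over
    unambiguous bases; an ``info`` column carries 2 - H (bits) per position.
    """
    counts = np.zeros((len(offsets), 4), dtype=float)
    for s in seqs:
        arr = encode(s)
        for r, off in enumerate(offsets):
            i = tss_index + off
            if 0 <= i < arr.size and arr[i] < N_CODE:
                counts[r, arr[i]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    df = pd.DataFrame(freqs, columns=list("ACGT"))
    df.insert(0, "offset", list(offsets))
    df["info"] = info
    return df


@dataclass(slots=True)
class YrUsage:
    """Usage of the four YR initiator dinucleotides at offsets (-1, 0)."""

    counts: dict[str, int]
    proportions: dict[str, float]
    n_yr: int
    n_ignored: int
    n_edge: int = 0


def yr_usage(
    genome: Mapping[str, str],
    tss_list: Iterable[tuple[str, str, int]],
    ) -> YrUsage:
    """Count CpA/CpG/TpA/TpG at (-1, 0) of representative TSSs; others ignored."""
    counts = {d: 0 for d in YR_DINUCLEOTIDES}
    ignored = 0
    edge = 0
    for contig, strand, tss in tss_list:
        duo = offset_window(genome[contig], strand, tss, 1, 1)
        if duo is None:
            edge += 1
            continue
        if duo in counts:
            counts[duo] += 1
        else:
            ignored += 1
    n_yr = sum(counts.values())
    props = {d: (counts[d] / n_yr if n_yr else math.nan) for d in YR_DINUCLEOTIDES}
    return YrUsage(counts=counts, proportions=props, n_yr=n_yr, n_ignored=ignored, n_edge=edge)


# ---------------------------------------------------------------------------
# promoter-set classification

@dataclass(slots=True)
class PromoterSetClassification:
    per_promoter: pd.DataFrame
    n: int
    n_edge_excluded: int
    island_fraction: float
    class_fractions: dict[str, float]


def classify_promoter_set(
    genome: Mapping[str, str],
    tss_list: Sequence[tuple[str, str, int]],
    island_upstream: int = 499,
    island_downstream: int = 501,
    class_window: int = 200,
) -> PromoterSetClassification:
    """Island calls (on the 1-kb promoter) and CpG-score classes (200-nt window).

    The classification window is centred on the TSS (offsets -100..+99 for
    the 200-nt default).
    """
    rows = []
    edge = 0
    up_c = class_window // 2
    down_c = class_window - up_c
    for contig, strand, tss in tss_list:
        seq1k = extract_promoter_seq(genome, contig, strand, tss, island_upstream, island_downstream)
        seq_c = extract_promoter_seq(genome, contig, strand, tss, up_c, down_c)
        if seq1k is None or seq_c is None:
            edge += 1
            continue
        call = seq_metrics.is_cpg_island(seq1k)
        cls = seq_metrics.classify_promoter_cpg(seq_c, expected_length=class_window)
        rows.append(
            {
                "contig": contig,
                "strand": strand,
                "tss": tss,
                "is_island": call.is_island,
                "island_best_score": call.best_score,
                "cpg_class": cls,
            }
        )
    df = pd.DataFrame(rows)
    n = len(df)
    if n:
        island_frac = float(df["is_island"].mean())
        class_fracs = {k: float(v) for k, v in (df["cpg_class"].value_counts(normalize=True)).items()}
    else:
        island_frac = math.nan
        class_fracs = {}
    return PromoterSetClassification(
        per_promoter=df,
        n=n,
        n_edge_excluded=edge,
        island_fraction=island_frac,
        class_fractions=class_fracs,
    )


def cluster_tss_triples(clusters: Sequence[PromoterCluster]) -> list[tuple[str, str, int]]:
    """(contig, strand, representative TSS) triples from promoter clusters."""
    return [(c.contig, c.strand, c.representative.pos) for c in clusters]
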