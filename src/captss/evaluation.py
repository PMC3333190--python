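"""Recovery metrics against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .promoter_calling import PromoterCluster


@dataclass(slots=True)
class RecoveryReport:
    n_true: int  # true promoters above the abundance floor
    n_recovered: int
    recovery_rate: float
    n_calls: int
    n_false_calls: int  # calls outside any true cluster +/- slack
    false_call_rate: float
    spearman_rho: float  # called total_ppm vs true abundance, recovered set


def evaluate_promoter_recovery(
    clusters: list[PromoterCluster],
    truth: pd.DataFrame,
    min_true_ppm: float = 5.0,
    tss_tolerance: int = 10,
    false_slack: int = 100,
) -> RecoveryReport:
    """Match called representative TSSs against true dominant TSSs.

    ``truth`` needs columns contig, strand, tss, class_ppm (one row per
    gene whose 5' ends the clusters could capture — pass the non-trans-
    spliced genes for promoter clusters, using acceptor positions for
    trans-spliced first-exon clusters).  A true promoter is recovered when
    some cluster's representative lies within ``tss_tolerance`` of its
    dominant TSS on the same contig/strand.  A call is false when its
    representative lies farther than ``false_slack`` from every true TSS
    (of any abundance).
    """
    eligible = truth[truth["class_ppm"] >= min_true_ppm]
    recovered = 0
    matched_pairs: list[tuple[float, float]] = []
    by_key: dict[tuple[str, str], list[PromoterCluster]] = {}
    for c in clusters:
        by_key.setdefault((c.contig, c.strand), []).append(c)
    for key, group in by_key.items():
        group.sort(key=lambda c: c.representative.pos)
    for row in eligible.itertuples():
        best = None
        for c in by_key.get((row.contig, row.strand), ()):
            d = abs(c.representative.pos - row.tss)
            if d <= tss_tolerance and (best is None or d < best[0]):
                best = (d, c)
        if best is not None:
            recovered += 1
            matched_pairs.append((best[1].total_ppm, row.class_ppm))

    all_tss: dict[tuple[str, str], np.ndarray] = {
        (c, s): np.sort(sub["tss"].to_numpy())
        for (c, s), sub in truth.groupby(["contig", "strand"])
    }
    false_calls = 0
    for c in clusters:
        arr = all_tss.get((c.contig, c.strand))
        rep = c.representative.pos
        if arr is None or arr.size == 0:
            false_calls += 1
            continue
        i = np.searchsorted(arr, rep)
        near = min(
            abs(rep - arr[j]) for j in (max(i - 1, 0), min(i, arr.size - 1))
        )
        if near > false_slack:
            false_calls += 1

    rho = float("nan")
    if len(matched_pairs) >= 3:
        est, true = zip(*matched_pairs)
        rho = float(stats.spearmanr(est, true).statistic)
    n_true = len(eligible)
    n_calls = len(clusters)
    return RecoveryReport(
        n_true=n_true,
        n_recovered=recovered,
        recovery_rate=recovered / n_true if n_true else float("nan"),
        n_calls=n_calls,
        n_false_calls=false_calls,
        false_call_rate=false_calls / n_calls if n_calls else float("nan"),
        spearman_rho=rho,
    )


def classification_accuracy(predicted: pd.Series, truth: pd.Series) -> float:
    """Fraction of reads whose SL classification matches the simulator truth."""
    merged = predicted.align(truth, join="inner")
    if len(merged[0]) == 0:
        return float("nan")
    return float((merged[0] == merged[1]).mean())
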