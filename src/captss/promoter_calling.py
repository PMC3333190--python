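"""From mapped 5' ends to promoters.

Tag counts at each genomic position are converted to parts per million
(ppm) of the mapped total — interpretable as transcript copies per cell
under the ~10^6 mRNAs/cell assumption — separately for non-trans-spliced
and trans-spliced tags, pooling the sequencing datasets before
normalisation.  Positions at >= 0.5 ppm seed single-linkage clusters:
consecutive seeds no more than 100 bp apart belong to one promoter
(two tags more than 100 bp apart with nothing between them indicate two
promoters).  Once a cluster's span is fixed, every position inside it —
including sub-seed ones — contributes to the promoter's abundance, and
clusters totalling < 1.0 ppm are suppressed as transcriptional noise.
The representative TSS is the most abundant member position, ties going to
the most upstream (strand-aware).

Trans-spliced clusters locate first-exon 5' ends, not TSSs (the outron is
lost during trans-splicing); they are labelled accordingly in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .read_processing import NON_TRANS_SPLICED, TRANS_SPLICED
from .tag_mapping import MappedTag

log = logging.getLogger(__name__)


@dataclass(slots=True)
class TssPosition:
    contig: str
    strand: str
    pos: int
    count_by_dataset: dict[str, int]
    ppm: float

    @property
    def count(self) -> int:
        return sum(self.count_by_dataset.values())


@dataclass(slots=True)
class PromoterCluster:
    cluster_id: str
    contig: str
    strand: str
    start: int  # 0-based half-open span over member positions
    end: int
    members: list[TssPosition]
    total_ppm: float
    representative: TssPosition
    read_class: str
    gene_id: str | None = None
    gene_relation: str = "unannotated"

    @property
    def label(self) -> str:
        """Trans-spliced clusters are first-exon 5'-end clusters, not promoters."""
        return "promoter" if self.read_class == NON_TRANS_SPLICED else "first_exon_5p_cluster"


def ppm_normalize(
    mapped: Iterable[MappedTag],
    per_dataset_mean: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-position tag abundance tables, one per read class.

    Default normalisation pools counts across datasets and divides by the
    pooled mapped total (count-weighted merge); ``per_dataset_mean``
    instead averages per-dataset ppm values.  Columns: contig, strand, pos,
    count, ppm, plus count_<dataset> per dataset.
    """
    rows = [(m.read_class, m.dataset_id, m.contig, m.strand, m.tss_pos) for m in mapped]
    out: dict[str, pd.DataFrame] = {}
    if not rows:
        log.warning("ppm_normalize: no mapped tags")
        return out
    df = pd.DataFrame(rows, columns=["read_class", "dataset", "contig", "strand", "pos"])
    for read_class, sub in df.groupby("read_class", sort=False):
        totals = sub.groupby("dataset").size()
        counts = (
            sub.groupby(["contig", "strand", "pos", "dataset"])
            .size()
            .unstack("dataset", fill_value=0)
        )
        pooled = counts.sum(axis=1)
        if per_dataset_mean:
            ppm = sum((counts[d] / totals[d]) * 1e6 for d in counts.columns) / len(counts.columns)
        else:
            ppm = pooled / totals.sum() * 1e6
        table = counts.rename(columns=lambda d: f"count_{d}").reset_index()
        table["count"] = pooled.values
        table["ppm"] = np.asarray(ppm)
        out[read_class] = table.sort_values(["contig", "strand", "pos"]).reset_index(drop=True)
    return out


def _positions_from_table(table: pd.DataFrame) -> list[TssPosition]:
    count_cols = [c for c in table.columns if c.startswith("count_")]
    return [
        TssPosition(
            contig=r.contig,
            strand=r.strand,
            pos=int(r.pos),
            count_by_dataset={c[6:]: int(getattr(r, c)) for c in count_cols},
            ppm=float(r.ppm),
        )
        for r in table.itertuples()
    ]


def pick_representative(members: Sequence[TssPosition], strand: str) -> TssPosition:
    """Most abundant member; ties resolved to the most upstream position."""
    best_ppm = max(m.ppm for m in members)
    tied = [m for m in members if m.ppm == best_ppm]
    if strand == "+":
        return min(tied, key=lambda m: m.pos)
    return max(tied, key=lambda m: m.pos)


def cluster_tss(
    table: pd.DataFrame,
    read_class: str = NON_TRANS_SPLICED,
    gap: int = 100,
    seed_min_ppm: float = 0.5,
    promoter_min_ppm: float = 1.0,
    suppressed: list | None = None,
) -> list[PromoterCluster]:
    """Single-linkage clustering of TSS positions into promoters.

    Seeds (ppm >= ``seed_min_ppm``) chain while consecutive seeds are
    <= ``gap`` bp apart; the cluster span is [first seed, last seed + 1];
    all positions inside the span (any ppm) are members; clusters below
    ``promoter_min_ppm`` total are suppressed (collected into ``suppressed``
    if given, for logging).
    """
    clusters: list[PromoterCluster] = []
    serial = 0
    for (contig, strand), sub in table.groupby(["contig", "strand"], sort=True):
        sub = sub.sort_values("pos")
        positions = _positions_from_table(sub)
        seeds = [p for p in positions if p.ppm >= seed_min_ppm]
        if not seeds:
            continue
        runs: list[list[TssPosition]] = [[seeds[0]]]
        for p in seeds[1:]:
            if p.pos - runs[-1][-1].pos <= gap:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            start, end = run[0].pos, run[-1].pos + 1
            members = [p for p in positions if start <= p.pos < end]
            total = sum(p.ppm for p in members)
            serial += 1
            cluster = PromoterCluster(
                cluster_id=f"{'p' if read_class == NON_TRANS_SPLICED else 'ts'}{serial:05d}",
                contig=contig,
                strand=strand,
                start=start,
                end=end,
                members=members,
                total_ppm=total,
                representative=pick_representative(members, strand),
                read_class=read_class,
            )
            if total >= promoter_min_ppm:
                clusters.append(cluster)
            else:
                log.debug("suppressed cluster %s:%d-%d total %.3f ppm", contig, start, end, total)
                if suppressed is not None:
                    suppressed.append(cluster)
    return clusters


@dataclass(slots=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int  # 0-based half-open
    end: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def annotate_promoters(
    clusters: list[PromoterCluster],
    genes: Sequence[GeneModel],
    d_start: int = 500,
    d_upstream: int = 1000,
) -> list[PromoterCluster]:
    """Relate each cluster's representative TSS to a same-strand gene model.

    overlaps_gene_start: within ``d_start`` of the gene 5' end;
    within_gene: inside the gene span; upstream: <= ``d_upstream`` before
    the gene 5' end; otherwise unannotated.  A gene may receive several
    promoters (alternative promoters).
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.contig, g.strand), []).append(g)
    for c in clusters:
        rep = c.representative.pos
        best: tuple[int, int, str, str] | None = None  # (priority, distance, gene, relation)
        for g in by_key.get((c.contig, c.strand), ()):
            dist5 = abs(rep - g.five_prime)
            if dist5 <= d_start:
                cand = (0, dist5, g.gene_id, "overlaps_gene_start")
            elif g.start <= rep < g.end:
                cand = (1, dist5, g.gene_id, "within_gene")
            else:
                ahead = g.five_prime - rep if g.strand == "+" else rep - g.five_prime
                if 0 < ahead <= d_upstream:
                    cand = (2, dist5, g.gene_id, "upstream")
                else:
                    continue
            if best is None or cand < best:
                best = cand
        if best is not None:
            c.gene_id, c.gene_relation = best[2], best[3]
        else:
            c.gene_id, c.gene_relation = None, "unannotated"
    return clusters


def promoter_table(clusters: list[PromoterCluster]) -> pd.DataFrame:
    """Flat promoter table (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "label": c.label,
                "contig": c.contig,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "representative_tss": c.representative.pos,
                "total_ppm": c.total_ppm,
                "n_members": len(c.members),
                "gene_id": c.gene_id if c.gene_id else "",
                "gene_relation": c.gene_relation,
            }
            for c in clusters
        ]
    )
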