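"""ppm normalisation, 100-bp-gap clustering, representatives, annotation."""

import numpy as np
import pandas as pd
import pytest

from captss.promoter_calling import (
    GeneModel,
    TssPosition,
    annotate_promoters,
    cluster_tss,
    pick_representative,
    ppm_normalize,
    promoter_table,
)
from captss.read_processing import NON_TRANS_SPLICED, TRANS_SPLICED
from captss.tag_mapping import MappedTag

from conftest import position_table


def _tags(rows):
    return [MappedTag(f"r{i}", c, s, p, 0, rc, ds) for i, (c, s, p, rc, ds) in enumerate(rows)]


def test_ppm_single_dataset():
    rows = [("c", "+", 100, NON_TRANS_SPLICED, "d1")] * 3 + [
        ("c", "+", i, NON_TRANS_SPLICED, "d1") for i in range(1000, 1000 + 1_997)
    ]
    tables = ppm_normalize(_tags(rows))  # 2,000 mapped tags in the class
    t = tables[NON_TRANS_SPLICED]
    assert t.loc[t.pos == 100, "ppm"].item() == pytest.approx(3 / 2000 * 1e6)


def test_ppm_pooled_across_datasets():
    # datasets with 1e2 and 3e2 totals; a position with 2 tags in each
    rows = []
    rows += [("c", "+", 50, NON_TRANS_SPLICED, "a")] * 2
    rows += [("c", "+", 50, NON_TRANS_SPLICED, "b")] * 2
    rows += [("c", "+", 1000 + i, NON_TRANS_SPLICED, "a") for i in range(98)]
    rows += [("c", "+", 5000 + i, NON_TRANS_SPLICED, "b") for i in range(298)]
    t = ppm_normalize(_tags(rows))[NON_TRANS_SPLICED]
    assert t.loc[t.pos == 50, "ppm"].item() == pytest.approx(4 / 400 * 1e6)
    assert t.loc[t.pos == 50, "count_a"].item() == 2


def test_ppm_sums_to_one_million_per_class():
    rows = [("c", "+", int(p), NON_TRANS_SPLICED, "a") for p in np.random.default_rng(0).integers(0, 10_000, 500)]
    rows += [("c", "-", int(p), TRANS_SPLICED, "b") for p in np.random.default_rng(1).integers(0, 10_000, 300)]
    tables = ppm_normalize(_tags(rows))
    for table in tables.values():
        assert table["ppm"].sum() == pytest.approx(1e6)


def test_ppm_empty_input():
    assert ppm_normalize([]) == {}


def test_cluster_gap_rules():
    # gaps 80 and 120: two clusters
    t = position_table([("c", "+", 100, 0.6), ("c", "+", 180, 0.6), ("c", "+", 300, 0.6)])
    clusters = cluster_tss(t, promoter_min_ppm=0.0)
    assert [(c.start, c.end) for c in clusters] == [(100, 181), (300, 301)]
    # gap exactly 100 is NOT "more than 100 bp apart": one cluster
    t2 = position_table([("c", "+", 100, 0.6), ("c", "+", 200, 0.6)])
    assert [(c.start, c.end) for c in cluster_tss(t2)] == [(100, 201)]


def test_lone_subthreshold_cluster_suppressed():
    t = position_table([("c", "+", 100, 0.6)])
    suppressed = []
    assert cluster_tss(t, suppressed=suppressed) == []
    assert len(suppressed) == 1 and suppressed[0].total_ppm == pytest.approx(0.6)


def test_subseed_positions_counted_once_span_fixed():
    # 0.3-ppm position inside the span joins the total; one outside does not
    t = position_table(
        [("c", "+", 100, 0.6), ("c", "+", 150, 0.3), ("c", "+", 180, 0.6), ("c", "+", 400, 0.3)]
    )
    clusters = cluster_tss(t)
    assert len(clusters) == 1
    assert clusters[0].total_ppm == pytest.approx(1.5)
    assert len(clusters[0].members) == 3


def test_seed_threshold_excludes_weak_seeds():
    t = position_table([("c", "+", 100, 0.4), ("c", "+", 150, 2.0)])
    clusters = cluster_tss(t)
    assert [(c.start, c.end) for c in clusters] == [(150, 151)]


def test_representative_tie_breaks():
    def tp(pos, ppm):
        return TssPosition("c", "+", pos, {"d": 1}, ppm)

    members = [tp(100, 5.0), tp(120, 5.0), tp(140, 3.0)]
    assert pick_representative(members, "+").pos == 100
    assert pick_representative([tp(100, 5.0), tp(120, 5.0)], "-").pos == 120
    assert pick_representative([tp(7, 1.0)], "+").pos == 7


def test_monotonicity_in_promoter_threshold(rng):
    rows = [("c", "+", int(p), float(v)) for p, v in
            zip(rng.integers(0, 50_000, 200), rng.uniform(0.5, 3.0, 200))]
    t = position_table(sorted(set(rows), key=lambda r: r[2]))
    counts = [len(cluster_tss(t, promoter_min_ppm=thr)) for thr in (0.5, 1.0, 2.0, 4.0)]
    assert counts == sorted(counts, reverse=True)


def test_cluster_seed_separation_invariant(rng):
    rows = sorted({("c", "+", int(p), 0.7) for p in rng.integers(0, 20_000, 150)}, key=lambda r: r[2])
    clusters = cluster_tss(position_table(rows), promoter_min_ppm=0.0)
    gaps = [b.start - a.end + 1 for a, b in zip(clusters, clusters[1:])]
    assert all(g > 100 for g in gaps)


def test_annotation_relations():
    genes = [GeneModel("gA", "c", "+", 1000, 3000), GeneModel("gB", "c", "-", 5000, 7000)]

    def cluster_at(pos, strand="+"):
        tp = TssPosition("c", strand, pos, {"d": 1}, 2.0)
        from captss.promoter_calling import PromoterCluster

        return PromoterCluster("x", "c", strand, pos, pos + 1, [tp], 2.0, tp, NON_TRANS_SPLICED)

    near = cluster_at(970)  # 30 nt upstream of gA start
    inside = cluster_at(2500)
    upstream = cluster_at(250)
    wrong_strand = cluster_at(6000, "+")  # inside gB but opposite strand
    annotate_promoters([near, inside, upstream, wrong_strand], genes)
    assert (near.gene_id, near.gene_relation) == ("gA", "overlaps_gene_start")
    assert (inside.gene_id, inside.gene_relation) == ("gA", "within_gene")
    assert (upstream.gene_id, upstream.gene_relation) == ("gA", "upstream")
    assert wrong_strand.gene_relation == "unannotated"
    # empty gene model: everything unannotated
    again = cluster_at(970)
    annotate_promoters([again], [])
    assert again.gene_relation == "unannotated"


def test_promoter_table_labels_ts_clusters():
    tp = TssPosition("c", "+", 10, {"d": 1}, 2.0)
    from captss.promoter_calling import PromoterCluster

    pc = PromoterCluster("a", "c", "+", 10, 11, [tp], 2.0, tp, NON_TRANS_SPLICED)
    tc = PromoterCluster("b", "c", "+", 10, 11, [tp], 2.0, tp, TRANS_SPLICED)
    table = promoter_table([pc, tc])
    assert list(table["label"]) == ["promoter", "first_exon_5p_cluster"]
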