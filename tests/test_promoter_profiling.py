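"""Promoter extraction, histograms, meta-profiles, logo, YR usage, KS."""

import numpy as np
import pytest

from captss import promoter_profiling as prof
from captss.sequence import revcomp


def test_extract_promoter_offsets(small_genome):
    g = small_genome
    seq = prof.extract_promoter_seq(g, "c1", "+", 10_000, 499, 501)
    assert len(seq) == 1000
    assert seq[499] == g["c1"][10_000]  # TSS base at index `upstream`
    assert seq == g["c1"][9501:10_501]


def test_extract_minus_strand_is_revcomp(small_genome):
    g = small_genome
    plus = g["c1"][9501:10_501]
    minus = prof.extract_promoter_seq(g, "c1", "-", 10_000, 499, 501)
    # the '-' promoter covers genomic [tss-500, tss+499] reverse complemented
    assert minus == revcomp(g["c1"][9500:10_500])
    assert minus[499] == revcomp(g["c1"][10_000])


def test_extract_edge_exclusion(small_genome):
    assert prof.extract_promoter_seq(small_genome, "c1", "+", 10, 499, 501) is None
    seqs, excluded = prof.extract_promoter_set(
        small_genome, [("c1", "+", 10), ("c1", "+", 10_000)], 499, 501
    )
    assert len(seqs) == 1 and excluded == 1


def test_score_distribution_summary(rng):
    vals = [0.4] * 10 + [None] * 3
    h = prof.score_distribution(vals)
    assert h.n == 10 and h.n_missing == 3
    assert h.mean == pytest.approx(0.4) and h.counts.sum() == 10
    empty = prof.score_distribution([])
    assert empty.n == 0 and empty.counts.sum() == 0


def test_point_mass_single_sequence():
    h = prof.score_distribution(prof.score_values(["ACGCGT"], "cpg_score"))
    assert h.n == 1 and h.counts.max() == 1


def test_mode_counting_on_constructed_histograms(rng):
    uni = prof.score_distribution(list(rng.normal(1.0, 0.15, 4000)))
    assert prof.count_modes(uni) == 1
    bim = prof.score_distribution(
        list(rng.normal(0.25, 0.1, 3000)) + list(rng.normal(1.0, 0.12, 2000))
    )
    assert prof.count_modes(bim) == 2


def test_meta_profile_identical_seqs_equals_single_scan(rng):
    seq = "".join(rng.choice(list("ACGT"), 4000))
    mp1 = prof.meta_profile([seq], "cpg_score")
    mp3 = prof.meta_profile([seq, seq, seq], "cpg_score")
    assert np.allclose(mp1.mean_by_offset, mp3.mean_by_offset, equal_nan=True)
    assert mp1.offsets[0] == -1950 and mp1.offsets[-1] == 1950
    assert (mp3.n_by_offset <= 3).all()


def test_meta_profile_order_invariance(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 4000)) for _ in range(5)]
    a = prof.meta_profile(seqs, "gc_content")
    b = prof.meta_profile(seqs[::-1], "gc_content")
    assert np.allclose(a.mean_by_offset, b.mean_by_offset, equal_nan=True)


def test_meta_profile_cpg_content_baseline(rng):
    """Uniform random promoters have CpG content ~ 1/16 at every offset."""
    seqs = ["".join(rng.choice(list("ACGT"), 4000)) for _ in range(60)]
    mp = prof.meta_profile(seqs, "cpg_content")
    assert abs(np.nanmean(mp.mean_by_offset) - 1 / 16) < 0.003
    assert np.nanmax(np.abs(mp.mean_by_offset - 1 / 16)) < 0.04


def test_logo_matrix_pure_and_uniform(rng):
    seqs = ["ACAGT", "TCAGT"]  # index 1 = 'C' at offset -1, index 2 = 'A' at offset 0
    lm = prof.logo_matrix(seqs, [-1, 0], 2)
    assert lm.set_index("offset").loc[-1, "C"] == 1.0
    assert lm.set_index("offset").loc[0, "A"] == 1.0
    assert lm.set_index("offset").loc[0, "info"] == pytest.approx(2.0)
    rand = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(3000)]
    lm2 = prof.logo_matrix(rand, [-1, 0, 1], 2)
    assert np.allclose(lm2[list("ACGT")].sum(axis=1), 1.0, atol=1e-9)
    assert (lm2["info"] < 0.01).all()


def test_yr_usage_toy_set():
    genome = {"c": "ACATCATCGTGAT"}
    # (-1,0) duos: (1,2)=CA, (4,5)=CA, (7,8)=CG, (10,11)=GA (not YR -> ignored)
    tss = [("c", "+", 2), ("c", "+", 5), ("c", "+", 8), ("c", "+", 11)]
    u = prof.yr_usage(genome, tss)
    assert u.counts["CA"] == 2 and u.counts["CG"] == 1
    assert u.proportions["CA"] == pytest.approx(2 / 3)
    assert u.proportions["CG"] == pytest.approx(1 / 3)
    assert u.n_ignored == 1 and u.n_yr + u.n_ignored == 4


def test_yr_usage_duplication_invariance(small_genome, rng):
    tss = [("c1", "+", int(p)) for p in rng.integers(100, 100_000, 50)]
    u1 = prof.yr_usage(small_genome, tss)
    u2 = prof.yr_usage(small_genome, tss * 2)
    for d in u1.proportions:
        assert u1.proportions[d] == pytest.approx(u2.proportions[d], nan_ok=True)


def test_yr_usage_edge_tally():
    u = prof.yr_usage({"c": "ACGT"}, [("c", "+", 0)])
    assert u.n_edge == 1 and u.n_yr == 0


def test_ks_comparisons(rng):
    a = list(rng.normal(1.0, 0.1, 500))
    d, p = prof.compare_distributions(a, a)
    assert d == 0.0 and p == 1.0
    d2, _ = prof.compare_distributions([0.0] * 50, [1.0] * 50)
    assert d2 == 1.0
    x = rng.normal(1.14, 0.1, 5000)
    y = rng.normal(1.00, 0.1, 5000)
    _, p3 = prof.compare_distributions(list(x), list(y))
    assert p3 < 1e-15
    with pytest.raises(ValueError):
        prof.compare_distributions([1.0], [1.0, 2.0])


def test_classify_promoter_set_on_simulated_classes():
    """Island-like patches (GC 0.55) are called islands and rich; deaminated
    promoters are not islands."""
    from captss.synthetic_data import SimConfig, simulate_genome

    cfg = SimConfig.human(seed=3, genome_length=3_000_000, n_genes=120, gc_boost=0.14)
    sim = simulate_genome(cfg)
    truth = sim.gene_truth
    genome = sim.genome
    island = truth[truth.promoter_class == "island_like"]
    poor = truth[truth.promoter_class == "poor_like"]
    ci = prof.classify_promoter_set(genome, list(zip(island.contig, island.strand, island.tss)))
    cp = prof.classify_promoter_set(genome, list(zip(poor.contig, poor.strand, poor.tss)))
    assert ci.island_fraction > 0.9
    assert ci.class_fractions.get("rich", 0) > 0.9
    assert cp.island_fraction < 0.05
    assert cp.class_fractions.get("poor", 0) > 0.9
    empty = prof.classify_promoter_set(genome, [])
    assert empty.n == 0 and np.isnan(empty.island_fraction)


def test_promoter_dinuc_scores_track_promoter_deamination():
    """TpG/CpA means exceed 1 when promoters are partially deaminated and
    stay at 1 (within 3 SE) when they are not."""
    from captss.synthetic_data import SimConfig, simulate_genome

    base = dict(seed=9, genome_length=4_000_000, n_genes=300, island_fraction=1.0)
    for d_prom, elevated in ((0.3, True), (0.0, False)):
        cfg = SimConfig.ascidian(d=0.0, d_promoter=d_prom, gc_boost=0.0, **base)
        sim = simulate_genome(cfg)
        seqs, _ = prof.extract_promoter_set(
            sim.genome, [(g.contig, g.strand, g.tss) for g in sim.genes], 499, 501
        )
        means = {}
        for xy in ("TG", "CA"):
            vals = [v for v in prof.score_values(seqs, f"dinuc_score:{xy}") if v is not None]
            means[xy] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
        for xy, (m, se) in means.items():
            if elevated:
                assert m > 1.0 + 3 * se, f"{xy} mean {m} not elevated"
            else:
                assert abs(m - 1.0) < 3 * se + 0.01, f"{xy} mean {m} not ~1"
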