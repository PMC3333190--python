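#!/usr/bin/env python
"""Human-mode comparison: bimodal promoter classes from a methylated genome.

Simulates a human-like genome (globally methylated, d = 0.8, 40% of
promoters island-like) and contrasts its promoter CpG-score distribution
with the ascidian-mode one: bimodal vs unimodal, the poor/rich split at
CpG scores 0.5/0.6, and the bulk depletion to one-fifth of expectation.
"""

from pathlib import Path

import pandas as pd

from captss import promoter_profiling as prof
from captss.synthetic_data import SimConfig, bulk_cpg_score, simulate_genome

RESULTS = Path("results")
SEED = 20240902


def promoter_scores(sim):
    triples = [(g.contig, g.strand, g.tss) for g in sim.genes]
    seqs, _ = prof.extract_promoter_set(sim.genome, triples, 499, 501)
    return triples, seqs, prof.score_values(seqs, "cpg_score")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    human = simulate_genome(SimConfig.human(seed=SEED, genome_length=8_000_000, n_genes=800))
    asc = simulate_genome(SimConfig.ascidian(seed=SEED + 1, genome_length=8_000_000, n_genes=800))

    rows = []
    for name, sim in (("human", human), ("ascidian", asc)):
        triples, seqs, vals = promoter_scores(sim)
        hist = prof.score_distribution(vals)
        hist.to_frame().to_csv(RESULTS / f"04_{name}_promoter_cpg_score_hist.tsv", sep="\t", index=False)
        below, above = prof.mass_split(vals, 0.5, 0.6)
        cls = prof.classify_promoter_set(sim.genome, triples)
        rows.append(
            {
                "mode": name,
                "n_promoters": hist.n,
                "modes": prof.count_modes(hist),
                "mass_below_0.5": round(below, 3),
                "mass_above_0.6": round(above, 3),
                "island_fraction": round(cls.island_fraction, 3),
                "bulk_cpg_score": round(bulk_cpg_score(sim), 4),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "04_mode_comparison.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        "\nfinding: the globally methylated (human-mode) genome yields two promoter "
        "classes - CpG-poor (score < 0.5) and CpG-rich/island (score > 0.6) - while "
        "the half-methylated (ascidian-mode) genome yields one homogeneous, "
        "high-scoring class; bulk human-mode CpG sits at about one fifth of "
        "expectation (score ~0.2 at d = 0.8)."
    )


if __name__ == "__main__":
    main()
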