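"""Synthetic genomes, promoters and oligo-cap TSS-seq reads with ground truth.

The generator emulates the mutational landscape the analysis consumes.  A
genome is drawn i.i.d. from a configurable base composition and divided
into methylated and unmethylated domains (alternating domains of roughly
equal total size in ascidian mode; a globally methylated genome in human
mode).  In methylated DNA, deamination of 5-methylcytosine erodes CpG
dinucleotides into TpG or CpA (each half of the time).  Promoter patches
around each gene's dominant TSS are either island-like (exempt from the
bulk deamination, optionally G+C-elevated, with their own mild deamination
level ``d_promoter``) or poor-like (as methylated as the background).

Deamination strength ``d`` is specified on the observable scale: it is the
target depletion of the expected bulk CpG score, so a methylated domain
ends up with E[CpG score] = 1 - d.  Because every CpG->TpG/CpA event also
removes a C or a G from the score's denominator, the per-CpG conversion
probability that achieves this is slightly larger than ``d``; it is solved
from the base composition at generation time (`calibrate_conversion`).

Reads follow the oligo-cap design: each read is GG + transcript 5'
sequence, truncated to the cycle length (36 or 48 nt).  A configurable
fraction of expression is trans-spliced: those reads carry the 16-nt
spliced leader followed by the first-exon sequence that starts at the
splice acceptor (AG written into the genome immediately 5' of it), and the
outron — TSS through acceptor — is unobservable.  Non-trans-spliced reads
start at the dominant TSS plus a two-sided geometric scatter.  Dominant
TSSs sit on a pyrimidine-purine (YR) initiator with probability
``yr_bias``.  Per-gene expression is log-normal.  Everything is seeded and
byte-reproducible, and full ground truth is recorded per gene and per read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .read_processing import CANONICAL_SL, NON_TRANS_SPLICED, TRANS_SPLICED
from .sequence import decode, encode, oriented_slice

log = logging.getLogger(__name__)

ISLAND_LIKE = "island_like"
POOR_LIKE = "poor_like"


@dataclass
class SimConfig:
    """Parameters of the deamination-domain genome and read simulator."""

    seed: int = 0
    genome_length: int = 5_000_000
    contig_name: str = "chrS"
    mode: str = "ascidian"  # ascidian | human
    gc: float = 0.36  # genomic G+C fraction (0.41 in human mode)
    domain_mean_length: int = 25_000
    methylated_fraction: float = 0.5  # ascidian mode only
    d: float = 0.5  # target bulk CpG-score depletion in methylated domains
    d_promoter: float = 0.25  # same, inside island-like promoter patches
    island_fraction: float = 1.0  # fraction of genes with island-like promoters
    island_patch_halfwidth: int = 300  # 600-nt CpG-preserved patch
    gc_boost: float = 0.10  # G+C elevation inside island-like patches
    n_genes: int = 500
    trans_spliced_fraction: float = 0.56  # expression-weighted TS share
    sl_sequence: str = CANONICAL_SL
    outron_min: int = 200
    outron_max: int = 1500
    tss_scatter_p: float = 0.3  # geometric parameter of TSS scatter
    tss_scatter_max: int = 50
    yr_bias: float = 0.9  # probability the dominant TSS sits on a YR
    yr_probs: tuple[float, ...] = (0.50, 0.04, 0.16, 0.30)  # CA, CG, TA, TG
    abundance_mu: float = 0.0  # log-normal expression weights
    abundance_sigma: float = 1.5
    read_lengths: tuple[int, ...] = (36, 48)
    error_rate: float = 0.0  # per-base substitution probability
    n_reads: int = 500_000  # per dataset

    @classmethod
    def ascidian(cls, **kw) -> "SimConfig":
        return cls(**kw)

    @classmethod
    def human(cls, **kw) -> "SimConfig":
        defaults = dict(mode="human", gc=0.41, d=0.8, d_promoter=0.0, island_fraction=0.4)
        defaults.update(kw)
        return cls(**defaults)

    def validate(self) -> None:
        if not (0.0 <= self.d <= 1.0 and 0.0 <= self.d_promoter <= 1.0):
            raise ValueError("d and d_promoter must lie in [0, 1]")
        for name in ("methylated_fraction", "island_fraction", "trans_spliced_fraction", "yr_bias", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes and self.genome_length < 10 * self.n_genes * 4000:
            log.warning(
                "genome_length %d below the recommended 10 * n_genes * 4000 = %d",
                self.genome_length,
                10 * self.n_genes * 4000,
            )
        margin = 2000 + self.outron_max + max(self.read_lengths) + self.tss_scatter_max
        if self.n_genes and self.genome_length // max(self.n_genes, 1) < 2 * margin + 10:
            raise ValueError("genome too short for the requested gene count and spans")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(slots=True)
class TrueGene:
    gene_id: str
    contig: str
    strand: str
    tss: int
    promoter_class: str  # island_like | poor_like
    trans_spliced: bool
    outron_length: int
    acceptor_pos: int  # == tss for non-trans-spliced genes
    weight: float  # expression weight (sums to 1 over all genes)
    true_ppm: float  # weight * 1e6
    class_ppm: float  # ppm within the gene's read class


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    domains: list[tuple[int, int, bool]]  # (start, end, methylated)
    genes: list[TrueGene]

    @property
    def gene_truth(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.genes])


def calibrate_conversion(d: float, pc: float, pg: float) -> float:
    """Per-CpG conversion probability giving E[CpG score] = 1 - d.

    Converting a CpG to TpG removes a C, to CpA removes a G (half each), so
    the expected score after applying conversion probability r to an i.i.d.
    sequence with C/G frequencies pc, pg is
    (1 - r) * pc * pg / ((pc - r*pc*pg/2) * (pg - r*pc*pg/2)).
    Solved for the r at which this equals 1 - d.
    """
    if d <= 0.0:
        return 0.0
    if d >= 1.0:
        return 1.0

    def f(r: float) -> float:
        c_after = pc - r * pc * pg / 2.0
        g_after = pg - r * pc * pg / 2.0
        return (1.0 - r) * pc * pg / (c_after * g_after) - (1.0 - d)

    return float(brentq(f, 0.0, 1.0, xtol=1e-12))


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _lay_domains(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[int, int, bool]]:
    if cfg.mode == "human":
        return [(0, cfg.genome_length, True)]
    domains: list[tuple[int, int, bool]] = []
    pos = 0
    methylated = bool(rng.random() < cfg.methylated_fraction)
    while pos < cfg.genome_length:
        ln = max(1000, int(rng.exponential(cfg.domain_mean_length)))
        end = min(pos + ln, cfg.genome_length)
        domains.append((pos, end, methylated))
        pos = end
        methylated = not methylated
    return domains


_YR = ("CA", "CG", "TA", "TG")


def _write_oriented(arr: np.ndarray, strand: str, pos0: int, bases: str) -> None:
    """Write ``bases`` so that transcript-oriented offsets pos0, pos0+1, ... read them."""
    enc = encode(bases)
    for i, b in enumerate(enc):
        if strand == "+":
            arr[pos0 + i] = b
        else:
            arr[pos0 - i] = 3 - b  # complement of a 2-bit base code


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Draw the genome, lay methylation domains, place genes, deaminate."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    L = cfg.genome_length
    arr = _draw_bases(rng, L, cfg.gc)
    domains = _lay_domains(rng, cfg)

    meth = np.zeros(L, dtype=bool)
    for s, e, m in domains:
        if m:
            meth[s:e] = True

    # gene placement on a jittered grid: spans never overlap and promoters
    # never straddle contig edges
    genes: list[TrueGene] = []
    patch_mask = np.zeros(L, dtype=bool)
    if cfg.n_genes:
        margin = 2000 + cfg.outron_max + max(cfg.read_lengths) + cfg.tss_scatter_max
        slot = L // cfg.n_genes
        ts_flags = rng.random(cfg.n_genes) < cfg.trans_spliced_fraction
        island_flags = rng.random(cfg.n_genes) < cfg.island_fraction
        weights = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, cfg.n_genes)
        weights /= weights.sum()
        # rescale so the trans-spliced expression share equals the configured
        # fraction exactly (read class is then Bernoulli per read)
        w_ts = weights[ts_flags].sum()
        w_nts = weights[~ts_flags].sum()
        if 0 < cfg.trans_spliced_fraction < 1 and w_ts > 0 and w_nts > 0:
            weights[ts_flags] *= cfg.trans_spliced_fraction / w_ts
            weights[~ts_flags] *= (1 - cfg.trans_spliced_fraction) / w_nts
        for gi in range(cfg.n_genes):
            lo = gi * slot + margin
            hi = (gi + 1) * slot - margin
            if hi <= lo:
                raise ValueError("gene slots too small; reduce n_genes or enlarge genome")
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            trans = bool(ts_flags[gi])
            outron = int(rng.integers(cfg.outron_min, cfg.outron_max + 1)) if trans else 0
            sign = 1 if strand == "+" else -1
            acceptor = tss + sign * outron
            cls = ISLAND_LIKE if island_flags[gi] else POOR_LIKE
            hw = cfg.island_patch_halfwidth
            p_lo, p_hi = tss - hw, tss + hw
            patch_mask[p_lo:p_hi] = True
            if cls == ISLAND_LIKE and cfg.gc_boost > 0:
                arr[p_lo:p_hi] = _draw_bases(rng, p_hi - p_lo, cfg.gc + cfg.gc_boost)
            w = float(weights[gi])
            cls_w = cfg.trans_spliced_fraction if trans else (1 - cfg.trans_spliced_fraction)
            genes.append(
                TrueGene(
                    gene_id=f"g{gi:05d}",
                    contig=cfg.contig_name,
                    strand=strand,
                    tss=tss,
                    promoter_class=cls,
                    trans_spliced=trans,
                    outron_length=outron,
                    acceptor_pos=acceptor,
                    weight=w,
                    true_ppm=w * 1e6,
                    class_ppm=(w / cls_w * 1e6) if cls_w > 0 else 0.0,
                )
            )
        # initiator and acceptor signals are written after any patch redraw
        for g, island in zip(genes, island_flags):
            if rng.random() < cfg.yr_bias:
                duo = _YR[rng.choice(4, p=np.asarray(cfg.yr_probs))]
                _write_oriented(arr, g.strand, g.tss - (1 if g.strand == "+" else -1), duo)
            if g.trans_spliced:
                # splice acceptor AG occupies transcript offsets -2, -1
                _write_oriented(arr, g.strand, g.acceptor_pos - (2 if g.strand == "+" else -2), "AG")

    # deamination: one generation pass over every CpG, rate by region
    rate = np.zeros(L)
    r_bg = calibrate_conversion(cfg.d, cfg.gc / 2, cfg.gc / 2)
    rate[meth] = r_bg
    rate[~meth] = 0.0
    gc_patch = cfg.gc + cfg.gc_boost
    r_island = calibrate_conversion(cfg.d_promoter, gc_patch / 2, gc_patch / 2)
    hw = cfg.island_patch_halfwidth
    for g in genes:
        p_lo, p_hi = g.tss - hw, g.tss + hw
        rate[p_lo:p_hi] = r_island if g.promoter_class == ISLAND_LIKE else r_bg
    cg_idx = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2))
    if cg_idx.size:
        u = rng.random(cg_idx.size)
        hit = cg_idx[u < rate[cg_idx]]
        to_tpg = rng.random(hit.size) < 0.5
        arr[hit[to_tpg]] = 3  # CpG -> TpG
        arr[hit[~to_tpg] + 1] = 0  # CpG -> CpA

    genome = {cfg.contig_name: decode(arr)}
    sim = SimResult(config=cfg, genome=genome, domains=domains, genes=genes)
    sim._patch_mask = patch_mask  # type: ignore[attr-defined]
    log.info(
        "simulated %s genome: %d nt, %d domains, %d genes (config %s)",
        cfg.mode,
        L,
        len(domains),
        len(genes),
        cfg.config_hash(),
    )
    return sim


def simulate_reads(
    sim: SimResult,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Emit oligo-cap reads for each cycle length, plus a per-read truth table.

    Returns ({dataset_id: [(read_id, seq), ...]}, truth) where dataset ids
    are e.g. "36nt" and "48nt" and truth columns are read_id, gene_id,
    read_class, true_five_prime, dataset.
    """
    cfg = sim.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if not sim.genes:
        raise ValueError("simulate_reads needs genes")
    contig = sim.genome[cfg.contig_name]
    weights = np.array([g.weight for g in sim.genes])
    weights = weights / weights.sum()
    sl = cfg.sl_sequence
    datasets: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple[str, str, str, int, str]] = []
    for read_len in cfg.read_lengths:
        dataset = f"{read_len}nt"
        reads: list[tuple[str, str]] = []
        gene_idx = rng.choice(len(sim.genes), size=cfg.n_reads, p=weights)
        mags = rng.geometric(cfg.tss_scatter_p, size=cfg.n_reads) - 1
        mags = np.minimum(mags, cfg.tss_scatter_max)
        signs = rng.choice((-1, 1), size=cfg.n_reads)
        body_len = read_len - 2
        for i in range(cfg.n_reads):
            g = sim.genes[int(gene_idx[i])]
            rid = f"{dataset}:{i:07d}"
            if g.trans_spliced:
                five = g.acceptor_pos
                body = sl + oriented_slice(contig, g.strand, five, body_len - len(sl))
                read_class = TRANS_SPLICED
            else:
                off = int(mags[i]) * int(signs[i])
                five = g.tss + off if g.strand == "+" else g.tss - off
                body = oriented_slice(contig, g.strand, five, body_len)
                read_class = NON_TRANS_SPLICED
            seq = "GG" + body
            if cfg.error_rate > 0:
                chars = list(seq)
                hits = np.flatnonzero(rng.random(len(chars)) < cfg.error_rate)
                for h in hits:
                    chars[h] = "ACGT"[(("ACGT".index(chars[h]) + int(rng.integers(1, 4))) % 4)]
                seq = "".join(chars)
            reads.append((rid, seq))
            truth_rows.append((rid, g.gene_id, read_class, five, dataset))
        datasets[dataset] = reads
    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "read_class", "true_five_prime", "dataset"])
    return datasets, truth


# ---------------------------------------------------------------------------
# bulk deamination estimation

def bulk_cpg_score(sim: SimResult, methylated: bool = True) -> float:
    """Aggregate CpG score over (un)methylated-domain bases outside promoter patches."""
    cfg = sim.config
    arr = encode(sim.genome[cfg.contig_name])
    mask = np.zeros(arr.size, dtype=bool)
    for s, e, m in sim.domains:
        if m == methylated:
            mask[s:e] = True
    patch = getattr(sim, "_patch_mask", None)
    if patch is not None:
        mask &= ~patch
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no bases in the requested domain class")
    c = int(np.count_nonzero(arr[mask] == 1))
    g = int(np.count_nonzero(arr[mask] == 2))
    pair_ok = mask[:-1] & mask[1:]
    cg = int(np.count_nonzero((arr[:-1] == 1) & (arr[1:] == 2) & pair_ok))
    if c == 0 or g == 0:
        raise ValueError("degenerate composition")
    return cg * n / (c * g)


def estimate_deamination(sim: SimResult) -> float:
    """d-hat = 1 - bulk methylated-domain CpG score (patches excluded)."""
    return 1.0 - bulk_cpg_score(sim, methylated=True)


# ---------------------------------------------------------------------------
# fixture writers

def write_gene_truth(sim: SimResult, tsv_path: str, bed_path: str | None = None) -> None:
    """Write per-gene ground truth as TSV (lossless round-trip) and BED6."""
    df = sim.gene_truth
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path:
        with open(bed_path, "w") as fh:
            for g in sim.genes:
                fh.write(
                    f"{g.contig}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t"
                    f"{min(1000, int(round(g.true_ppm)))}\t{g.strand}\n"
                )


def read_gene_truth(tsv_path: str) -> pd.DataFrame:
    # round_trip parsing keeps write -> read -> write byte-identical
    return pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
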