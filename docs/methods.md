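# Methods

## Dinucleotide statistics

The package's central statistic is the observed/expected dinucleotide
score in a fixed window of size N:

    score(XY) = XY · N / (X · Y)

with X, Y, XY observed counts.  For XY = CpG this is the classical
CpG-island statistic: ≈ 1 where CpG occurs as composition predicts, < 1
where methylation-driven deamination has eroded CpG into TpG/CpA.  The
complementary TpG and CpA scores rise above 1 in methylated DNA.  CpG
*content* is the plain density CpG / (N − 1); its expectation on i.i.d.
sequence is 1/16 for any dinucleotide.

Conventions for ambiguous bases: overlapping pairs containing N are
dropped; mononucleotide counts and the G+C denominator exclude N; N (the
window size) includes every position.  A score whose mononucleotide
denominator is zero is MISSING (`None`), never 0 or infinity: MISSING
values are excluded from histograms and meta-profile averages but
counted, and promoters with MISSING classification scores are reported
`unclassifiable`.

CpG-island calls scan every 200-nt window (step 1) of the query and
require G+C ≥ 0.5 and CpG score ≥ 0.6 in at least one window; the
criteria, window length, and the 0.5/0.6 promoter-class cutoffs are
configuration values.  Runs of adjacent qualifying windows are reported
merged, but the boolean call uses single windows.  Promoter CpG classes
use the 200-nt window *centred* on the representative TSS (offsets
−100..+99) and strict inequalities: scores exactly at a cutoff fall into
the intermediate class.

## Read processing and mapping

Oligo-cap reads must start with `GG` (filtered, then trimmed); reads with
any ambiguous base are rejected; the two rules partition the input and
are tallied.  Spliced-leader detection is anchored at the 5' end and
accepts a configured leader set at edit distance ≤ 1 (one substitution,
one inserted or one deleted nucleotide); ties break
exact > mismatch > deletion > insertion, then fewest edits, then longest
leader.  The canonical 16-nt *Ciona* leader `ATTCTATTTGAATAAG` ships as
the default; the leader set in force is logged on every run.  For
throughput the matcher precompiles all ≤ 1-edit leader variants into hash
tables; a property test pins its decisions to the direct per-leader
algorithm.

The built-in aligner serves desk-scale genomes (up to a few tens of Mb).
Both strands are k-mer-indexed (default k = 12, sorted-array index).
Seed hits propose 5'-anchored candidate placements (± 1 to absorb
indel-induced diagonal shifts); each candidate is scored with edlib as
the edit distance of the whole tag against the reference window starting
at the candidate position, bounded by the allowance
floor(0.10 · tag length) — 3 edits for 34-nt and 4 for 46-nt tags, an
edit-count reading of a 90% match criterion (an identity-over-alignment
reading is available by changing the `identity` parameter).  Placements
within one tag length on the same contig/strand are clustered into a
locus so that indel jitter does not masquerade as a multiple hit; a tag
maps iff exactly one locus attains the minimal edit count.  The tag's
first base is anchored by construction, so a best alignment that would
clip or insert the 5'-terminal base surfaces at a neighbouring candidate
instead; tags whose only placements would begin before the contig are
reported `five_prime_unaligned`.  SAM ingestion applies the same
allowance, 5'-clip and equal-best-secondary rules to external alignments
(NM tag + clipped bases count against the allowance).  Trans-spliced tags
are mapped after leader stripping, and the `AG` acceptor expected
immediately 5' of the placement is checked post hoc and recorded
(strict mode drops failures); this is equivalent to the alternative of
prepending a literal `ag` before mapping, with a simpler contract.

## Promoter calling

Counts are normalised to ppm per read class, pooling datasets before
dividing by the pooled mapped total (a count-weighted merge; a
per-dataset-mean alternative is available).  The 0.5-ppm seed filter is
applied after merging.  Single-linkage chaining joins consecutive seeds
≤ 100 bp apart ("more than 100 bp apart" splits); the cluster span is
[first seed, last seed + 1); member positions of any abundance inside the
span contribute to the total; clusters under 1.0 ppm are suppressed and
logged.  Representative TSS: highest ppm, ties to the most upstream
position on the cluster's strand.  Trans-spliced clusters are labelled
`first_exon_5p_cluster` in all outputs, since the outron hides the true
TSS.  Gene annotation relates representatives to same-strand gene models:
within 500 nt of the gene 5' end → `overlaps_gene_start`; inside the span
→ `within_gene`; ≤ 1000 nt upstream → `upstream`; else `unannotated`.

## Profiling

Promoter sequences are strand-oriented with the TSS at offset 0 (−1 is
the next base upstream).  The 1-kb promoter covers −499..+500; 4-kb
meta-profiles average a 100-nt moving window, centred on each offset
(a 5'-anchored variant is available); offsets whose window would leave
the excision are not emitted.  Histogram bin widths default to 0.05 for
scores and 0.01 for contents.  Mode counting — used for the
unimodal/bimodal contrast — smooths histogram counts with a width-3
moving average and counts peaks with prominence ≥ 10% of the maximum
smoothed bin (ends zero-padded); the prominence floor suppresses
counting noise as modes and is a package choice, since "mode" is
otherwise not operational.  Distribution comparisons use the two-sample
Kolmogorov–Smirnov test; a one-sample KS against a fitted normal is
provided for homogeneity checks.  YR usage counts CpA/CpG/TpA/TpG at
offsets (−1, 0) of representative TSSs; non-YR TSSs are ignored but
tallied, as are TSSs too close to a contig edge to read.

## The synthetic-data generator

The generator defines the study conditions for every recovery test.  A
genome is drawn i.i.d. at G+C 0.36 (ascidian mode) or 0.41 (human mode).
Ascidian mode lays alternating methylated/unmethylated domains
(exponential lengths, mean 25 kb, methylated fraction 0.5); human mode
methylates everything.  Deamination is a single generation pass: each CpG
in methylated DNA converts with a fixed probability to TpG or CpA (half
each) — no iterated mutation–equilibrium model, which is sufficient to
produce the score contrasts the analysis consumes.

**Deamination parameter scale.**  The configured `d` is the *target
depletion of the expected bulk CpG score*, not the raw per-CpG conversion
probability.  Each conversion also removes a C or a G, shrinking the
score's denominator, so a raw conversion probability d would leave the
expected score at (1−d)·p_C p_G /((p_C −δ/2)(p_G −δ/2)) with
δ = d·p_C p_G — noticeably above 1−d at high d.  The generator therefore
solves the per-CpG conversion probability from the base composition so
that E[bulk score] = 1 − d exactly (`calibrate_conversion`).  This keeps
`d` interpretable on the scale every analysis reads, and makes
d̂ = 1 − (bulk methylated-domain CpG score) an asymptotically unbiased
estimator, which the deamination-recovery analysis verifies to ± 0.02 at
10 Mb for d ∈ {0.2, 0.5, 0.8}.  `bulk_cpg_score` aggregates counts over
all (un)methylated bases outside promoter patches rather than averaging
per-window ratios, avoiding ratio-estimator bias.

Genes sit on a jittered grid (no overlapping promoter spans, no contig
edges).  Each promoter carries a 600-nt patch centred on the dominant
TSS: island-like patches are exempt from bulk deamination, optionally
G+C-elevated (+0.10 by default, mimicking island G+C peaks), and receive
their own mild deamination `d_promoter` (0.25 in ascidian mode — this is
what pushes promoter TpG/CpA means above 1 — and 0 in human mode);
poor-like patches deaminate like methylated background.  Ascidian mode
makes every promoter island-like (one class → unimodal score
distribution); human mode draws island-like promoters with probability
0.4 (two classes → bimodal).  Dominant TSSs sit on a YR dinucleotide with
probability 0.9, drawn as CA:0.50, TG:0.30, TA:0.16, CG:0.04 (written
into the genome before deamination, so a CG initiator can still erode —
intentionally).  Expression weights are log-normal (μ = 0, σ = 1.5),
normalised so the trans-spliced share of expression equals the configured
fraction (0.56) exactly; each read then draws its gene from these
weights, making the trans-spliced read share binomial.  Non-trans-spliced
reads start at the dominant TSS plus a two-sided geometric offset
(p = 0.3, magnitude capped at 50 nt); trans-spliced reads start at the
splice acceptor (outron length uniform in [200, 1500], `AG` written
immediately 5' of the acceptor) and carry the full-length leader.  Every
read is `GG` + 5' sequence truncated to the cycle length (36 and 48 nt;
34/46 after trimming), with optional uniform substitution errors
(default 0).  Identical seed + config produce byte-identical outputs.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: cis-splicing within tags (the
historical motivation for a spliced aligner on longer reads), genuine
polymorphism between individuals (the motivation for the 90% criterion),
quality-score structure and position-dependent error profiles, repeats
and low-complexity DNA beyond what i.i.d. sequence produces, spliced-
leader variant families (variant leaders are configurable but reads
carry the canonical leader unless asked), operons, and any correlation
between expression level and promoter class.

## Problem sizes and numerical choices

Recovery analyses run at 5 Mb / 500 genes / 2 × 500k reads (end-to-end),
2 Mb / 10k planted tags (mapping), 20 Mb / 2000 genes (distribution
shapes) and 10 Mb (deamination recovery) — sizes at which every sampling
standard error is several times smaller than the margins being checked,
while a complete run stays in the tens of seconds on one CPU.  Mapping
memoises results by tag sequence, which TSS-seq's heavy read duplication
makes very effective.  The warning emitted when
genome_length < 10 · n_genes · 4000 is advisory; the study-scale
configuration intentionally runs denser than that rule of thumb.

Known limitations: the built-in aligner is heuristic (seed-based; a tag
whose every seed k-mer is corrupted can be missed) and targets desk-scale
genomes — real, large genomes should be aligned externally and ingested
from SAM; promoter-class fractions and island rates on synthetic data
depend directly on generator settings (patch width, G+C boost) and are
not calibrated to any real genome; and the island-criteria scan reports
single best windows rather than attempting island boundary calling.
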