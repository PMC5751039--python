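# Methods

This note documents the model and the numerical choices behind `cnvpop`:
what each pipeline stage assumes, which parameters matter and why their
defaults are what they are, what the simulator does and does not emulate,
and the decisions made where the design was genuinely open.

## Window grid

The reference — all sequences, including unplaced scaffolds — is tiled
with sliding windows of size *w* and step *w*/2, 0-based half-open, so
every base interior to a chromosome is covered by exactly two windows.
Trailing partial windows are dropped: depth statistics on truncated
windows are biased low and would need per-window length normalization for
no analytical gain. Windows with gap fraction > 0.5 (N/n bases over the
full window length; soft-masked lowercase ACGT is *not* counted as gap)
are removed from the grid, but the index space is the pre-filter
enumeration — removed windows leave holes rather than shifting indices, so
depth vectors, the duplicated-window record and the population matrix stay
aligned regardless of assembly gappiness.

Window size trades resolution against per-window counting noise. With
read length *r* and coverage *c*, the expected count per window is
λ = *c·w/r*; the defaults used in the benchmarks (*w* = 400, *c* = 20,
*r* = 100 → λ = 80, relative noise ≈ 11%) match the usual guidance of
800 bp for ×5–10 coverage and 400 bp for ×20. The mapping is exposed as
configuration only, never enforced.

## Duplicated-window record

Goal: link every pair of windows whose sequences are ≥97% identical, so
multi-mapped reads smeared across duplicate copies can be re-aggregated.
The record is built from *nonoverlapping* windows of size *w*. Each
window is searched against the whole reference with exact 16-mer seeds
(genome indexed at stride 8, so any identical stretch of ≥31 bases yields
a seed hit) followed by gap-free full-window identity scoring
(matches / *w*) at each candidate offset. This is a deterministic,
desk-scale stand-in for running a precise external aligner; it finds
ungapped duplicates of any offset but will miss duplicates fragmented by
indels — acceptable because the correction targets recent, high-identity
segmental duplications.

Numerical choices:

- A hit at genome position *g* is attributed to the nearest
  nonoverlapping window, `floor(g/w + 1/2)` (half-up). Duplicate copies
  whose offset is not a multiple of *w* (a 5-kb SD on a 400-bp grid is
  offset by 12.5 windows) therefore link to the nearest-aligned window;
  since depth across an SD is locally uniform, the summed signal is
  preserved to within edge effects of one window.
- Windows with more than `max_hits` (20) similar positions are treated as
  low-complexity and get a self-only link — excluded from correction, not
  from the grid, because deleting them would punch holes into CNVR
  assembly. The candidate set is additionally capped at 20×`max_hits`
  seed offsets before identity scoring; windows that exceed it
  (homopolymers, short tandem repeats) are handled the same way.
- The nonoverlapping record is projected onto the overlapping analysis
  grid by mapping each grid window to the one or two nonoverlapping
  windows it intersects and shifting the partner coordinates by the same
  sub-window offset, taking the union. This projection is an
  approximation (a window straddling a duplication boundary inherits
  partners from both sides), documented as such.

## Per-sample depth processing

Stages are ordered and enforced: raw → absolute → GC-corrected →
(sex-corrected) → normalized; each formula consumes the previous stage's
output.

- **Raw counting.** A read contributes +1 to every retained window
  containing its center, `floor((start + end)/2)` of the half-open
  aligned span. Reads with any of the 0x504 flags (unmapped, secondary,
  PCR duplicate) are skipped; both mates of a pair count independently,
  which keeps counting robust when gap structure breaks pairing.
- **Absolute correction** sums raw depths over each window's link group.
  Within a closed group of size *t* the corrected depths conserve
  *t*·(group raw sum) exactly — a tested invariant.
- **GC correction** uses 1% bins on the window GC fraction. Bins with
  fewer than `min_bin_windows` (default 100) windows borrow the nearest
  populated bin (ties to the lower bin); the 40% reference bin uses the
  same borrowing rule. 100 windows caps the bin-mean noise contribution
  at ~1% relative for λ ≈ 80. Bin means are computed over *all* windows,
  including eventual candidate CNV windows; at realistic CNV densities
  this biases the correction by well under the genotyping tolerance of a
  quarter copy.
- **Sexing** compares the sex chromosome's median depth with the median
  over placed autosomes jointly (unplaced scaffolds, recognized by name
  prefix `scaffold`/`chrUn`/`unplaced`, are excluded and never
  corrected). The 0.6× threshold sits between the 0.5 expected for
  heterogametic and 1.0 for homogametic individuals; a ratio of exactly
  0.6 calls homogametic (strict inequality).
- **Normalization** divides by the median over all retained windows
  (after sex doubling), anchoring diploid copy number 2 at depth 1.0.
  The median is robust to the CNV and SD windows in the tail.

The normalized profile is persisted to a small tab-separated file (full
float precision), so samples are processed once, in parallel, and reused
across cohorts; population assembly never re-touches alignments.

## CNVR discovery

Candidate flags are a pure function of depth, per-sample genome-wide
mean/STDEV, and mode. The statistical criterion (beyond mean ± 2·STDEV)
and the empirical criterion (outside 0.65/1.35) must both hold for a
heterozygous flag; the homozygous flags use 0.25/1.75 alone in outbred
mode, while self-bred mode requires both criteria at the homozygous
bounds (heterozygosity is not expected in strict selfers). The per-sample
(rather than per-window) mean/STDEV was chosen because per-window
statistics across samples are exactly what a common CNV shifts.

Window allele frequency is diploid bookkeeping,
AF = (#het + 2·#hom)/(2·N), pooling loss and gain carriers. Selection
requires AF ≥ 0.05 or ≥ 2 homozygous carriers (both configurable; a
keep-all-heterozygotes mode retains any window with one carrier).

Initial calls are runs of ≥ 5 consecutive grid positions that are
candidates, tolerating at most one non-candidate in any four consecutive
positions; tolerated windows are never members and never contribute to
region depth, and runs never start or end on one. Five windows at
400/200 means ≥ 1.2 kb of span with four independent half-overlapping
confirmations — single-window Poisson excursions cannot form a call.
Gap-dropped windows count as non-candidates for the tolerance rule.

Adjacent same-chromosome calls merge when the inter-call distance is
under 20% of their combined length *and* the Pearson correlation of
their per-sample region depths is positive and significant at P = 0.01
(Student *t*, df = n−2; two-sided p, with the sign requirement making it
effectively one-sided). Zero-variance depth vectors (e.g. a uniformly
hom-deleted region) are never "significant" by convention. The sweep is
strictly left-to-right and iterated to a fixpoint, which makes merging
deterministic and idempotent. A region whose member windows carry both
loss and gain flags is labelled `mixed` and genotyped multi-allelically.

## Genotyping

Per sample, the continuous copy number of a CNVR is 2× the median
normalized depth over member windows (median again for robustness to
boundary windows). The estimates are decomposed with a truncated
Dirichlet-process Gaussian mixture (stick-breaking, concentration 1.0,
10 components, variational EM, 5 initializations keeping the best bound).
Components with weight above 1/(10·n) are effective; each sample joins
its maximum-responsibility effective component and receives that
component's mean rounded half-up (clipped at 0) — component-level
rounding keeps genotypes cluster-coherent, so two samples in one cluster
can never disagree.

Two mixture priors are deliberately non-default. The component-mean prior
precision is weak (10⁻³): the sklearn default shrinks small clusters
toward the data mean hard enough to move a 2-sample CN-6 cluster by more
than half a copy. The covariance prior is 0.01 (σ ≈ 0.1 CN, the
depth-noise scale at recommended coverage): the default empirical-
covariance prior spans the whole cluster range and makes well-separated
clusters collapse into one broad Gaussian on small cohorts.

Components whose means round to the same integer are merged into one
genotype cluster; the silhouette coefficient (1-D Euclidean) is computed
over those clusters and reported per CNVR, but no silhouette cutoff is
applied — filtering is left to the user. Single-cluster CNVRs carry a
`single-cluster` quality flag instead of a score. CNVRs are genotyped
independently with a fixed seed, so any execution order (or
parallelization) yields identical output.

VCF output is symbolic (VCF 4.2): `<DEL>`, `<DUP>`, or both for mixed
regions; INFO END/SVTYPE/SVLEN/AF/SIL; FORMAT GT:CN. Biallelic losses map
CN 2/1/0 to 0/0, 0/1, 1/1; biallelic gains (max CN ≤ 4) map CN 2/3/4 the
same way; everything else gets `./.` with CN carried. AF is recomputed
from the integer copy numbers (per-allele for mixed records).

## Evaluation

Intervals match at ≥50% reciprocal overlap or ≥90% coverage of either
call. Sensitivity filters both callset and truth identically
(length > 2500 bp, AF ≥ 0.05) and reports the matched fraction of truth.
Mendelian scoring is restricted to biallelic CNVRs (losses with CN ⊆
{0,1,2}; gains with CN ⊆ {2,3,4}); CN maps to a diploid allele pair
(0↔aa, 1↔ar, 2↔rr for losses; 2↔rr, 3↔rD, 4↔DD for gains — CN 2 at a gain
CNVR is treated as homozygous reference), and a child is consistent when
some pairing of one allele from each parent reproduces its genotype.
Mixed CNVRs are excluded from Mendelian scoring. Genotype concordance
counts exact integer-CN agreement over record pairs matched at ≥90%
reciprocal overlap.

## Synthetic data

The simulator emulates the classic SD validation design: nonoverlapping
5-kb donor regions of a random uniform-composition sequence are inserted
as tandem duplications (`assembled_SD`) or flagged as duplicated while
left single-copy (`collapsed_SD`); individuals are assigned 2–6 total
diploid copies of each duplicated unit. Plain deletions/duplications are
planted without editing the sequence (they are individual-level variants)
and sampled under Hardy–Weinberg at configured frequencies; trio children
inherit one allele from each Hardy–Weinberg parent, so pedigrees are
Mendelian by construction.

Counts-level simulation is the default: window counts are
Poisson(λ · f) where the factor *f* encodes copy number (CN/2 over a
unique region), collapsed-duplication folding (both real copies map to
the single assembled locus), assembled-duplication smearing (reads split
uniformly across the two reference copies: CN/4 per copy), partial
window overlap (linear blend), sex-chromosome ploidy (×0.5 for
heterogametic individuals), and an optional multiplicative GC-bias curve
(off by default). Alignment emission writes minimal single-end SAM
records whose centers follow the same model, sufficient to exercise the
0x504-masked counting path end to end.

What the simulator does *not* emulate: sequencing errors, SNPs/indels,
mapping-quality structure, insert-size variation, GC-dependent coverage
of real libraries (beyond the optional smooth curve), and reference bias.
Passing tests therefore demonstrate the correctness of the depth model,
the corrections and the genotyping logic — not robustness to alignment
artefacts of real libraries.

## Benchmark designs and problem sizes

The built-in experiments (`cnvpop.experiments`) use a 5-Mb source
sequence, 20 SDs × 5 kb, 30 individuals at ×20 coverage with 400-bp
windows — a scaled version of the published 50-Mb / 100-SD /
100-individual design that preserves per-window statistics (λ = 80) and
SD density while keeping a full run in seconds. CNVR recovery plants 12
events of 4 kb (≈19 windows) at frequencies 0.1–0.3 — comfortably inside
the tool's stated domain of common variants — with a same-sized,
event-free null arm. Genotyping recovery uses 50 CNVRs × 60 samples with
unit cluster separation and σ = 0.1. The trio experiment runs 10 trios
at ×30 coverage through the complete pipeline, then corrupts one child
genotype at a biallelic CNVR to verify the inconsistency is detected.

## Known limitations

- The similarity search is gap-free; diverged or indel-fragmented
  duplications below ~97% ungapped identity are not linked.
- Breakpoints are window-resolution; no read-pair or split-read evidence
  is used, and no single-sample calling mode exists (the population is
  the signal).
- The dup-record projection onto the overlapping grid blurs duplication
  boundaries by up to half a window.
- Genotyping assumes depth clusters at half-integer spacing around
  integer copy numbers; heavily contaminated or low-coverage samples
  violate this before the pipeline can tell.
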