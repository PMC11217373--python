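# Methods

This note documents the models behind each `zfdelta` module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.  Coordinates are 0-based
half-open everywhere; bedGraph values apply to half-open bins.

## Spike-in differential ChIP quantification

The spike-in design assumes the exogenous chromatin's average binding
strength is identical across samples, so after RPGC normalization
(mean per-bp coverage scaled to 1 over the effective genome) the remaining
spike-signal difference measures global efficiency/depth imbalance.  The
per-sample factor is the ratio of spike-in *meta-profile summits*
(reference / sample): per spike peak the summit-centered window is
extracted, windows are averaged element-wise, and the profile maximum is
the summit.  The reference sample's factor is fixed at 1.  Using the
averaged-profile summit rather than per-peak ratios makes the estimator
robust to individual noisy peaks; with 200 spike peaks the factor is
recovered within ~1% on simulated 2-fold imbalances.

Per-site strength is the scaled coverage of the summit bin (leftmost argmax
of reference coverage inside the peak; the summit-value convention matches
the spike-in summit statistic and is deterministic under ties).  The
fold-change pseudocount ε defaults to 1% of the genome-wide mean scaled
coverage: large enough to stop empty bins producing infinite fold changes,
two orders of magnitude below real site strengths.  Four groups are
equal-count quantiles of `log2FC` ranked ascending (ties broken by genomic
position so the grouping is invariant to input order; remainder sites go
to earlier groups); the published analysis does not state its group
boundaries, so quantiles are the default and fixed thresholds are
available.  The downregulation rule `log2(ref/alt) > 1` is strict.

## PWM scanning with exact p-values

Log-odds scores (log2, probabilities over a background model with
pseudocount 0.25 per cell when converting counts) are discretized to an
integer grid of 1e-3 log-odds units.  The null score distribution is the
convolution of per-position score distributions under the background — the
standard FIMO-class dynamic program — and the scanner scores windows on
the *same* integer grid, so a window's reported p-value is exactly the DP
tail of its integer score.  For motif lengths ≤ 6 the DP tail equals
exhaustive 4^L enumeration to float round-off; this equivalence is a test.
Both strands are scanned; per peak the lowest-p match is primary, with
ties resolved leftmost then '+' strand.  Windows containing N are skipped.
A weak-motif mode (`best_window`) returns the best-scoring window
regardless of threshold, for promoter sites whose cores are degenerate.

## Upstream (U) motif typing

The 20 bp immediately 5′ of the primary core match, on the match strand,
is the upstream flank ('+' core `[s,e)` → `[s-20,s)`; '−' core → reverse
complement of `[e,e+20)`).  Flanks running off the contig are excluded and
counted.

Flanks are clustered by Hamming distance (comparisons involving N weigh
1/2) with k-medoids, default k = 10.  For determinism *and* invariance to
input order, candidates are ranked canonically (lexicographically by
sequence): the seeded start medoid is drawn from that canonical order,
remaining initial medoids are farthest-point picks, assignment and medoid
updates break ties canonically, and final cluster ids are ordered by
decreasing size.  The alternation (assign to nearest medoid, recenter each
cluster on its cost-minimizing member) stops when the medoid set is stable
or the objective stops decreasing, so the objective never increases.
Empty or duplicate-collapsed clusters reduce k with a warning.

A cluster is called U-motif-like when it has ≥ 6 consecutive positions of
information content ≥ 0.3 bits.  Information is measured per position as
the Kullback–Leibler divergence from the *cluster's own average base
composition*, minus the small-sample bias of the plug-in estimator
(≈ 3/(2·N·ln 2) bits for N sequences).  Both choices matter: divergence
from the cluster's composition keeps AT/GC-skewed but position-uniform
clusters from mimicking motifs, and the bias correction keeps small
clusters from being promoted by sampling noise.  U-like clusters whose
best ungapped alignment to the canonical U model reaches a mean
per-position Pearson r ≥ 0.8 (computed over the canonical model's
informative columns) are labeled U1; the rest are U2…Un by decreasing
size.  Per-group percentages count a site as U when its cluster carries
any U label; a canonical-only (U1) tally is reported alongside, since
published "percent U" figures do not state which tally they use.  Empty
groups report NaN, not 0.

## Insulation, boundaries, TAD changes

Low-coverage masking removes zero-marginal bins plus the lowest 5% of
nonzero marginals (floor of the count, so "100 distinct bins at 5%" masks
exactly 5).  Balancing is the symmetric fixed-point iteration
`x ← x / sqrt(rowsum(diag(x)·M·diag(x)))` run on the unmasked submatrix to
row sums 1 ± 1e-10; it reproduces the 2×2 closed form `[[2,1],[1,2]] →
[[2/3,1/3],[1/3,2/3]]` and is idempotent to tolerance.  Non-balanceable
support patterns raise an error naming the contig.

Insulation at bin b is the mean balanced contact in the square
`[b−w, b) × [b, b+w)` (default window 400 kb at 50-kb bins, i.e. w = 8; a
300-kb preset matches tissues profiled at that window), log2-ratioed to
the contig-wide mean of square means.  Scores are undefined within w of
contig ends and where more than 50% of the square is masked (this
tolerance prevents boundary artifacts at mask edges).  Boundaries are
local insulation minima whose strength — min(left flank max, right flank
max) − minimum, flanks bounded by neighboring minima — reaches 0.7.
Masked stretches split the track, so no boundary is called inside them.

TADs are the intervals between consecutive boundaries.  For two-condition
comparison, boundaries are greedily matched within ± 1 bin (nearest first,
leftmost on ties; insulation minima jitter by about one bin under Poisson
noise, which fixed the default).  Each region between consecutive shared
boundaries is classified stable / fusion / separation / confusion by
whether reference boundaries were lost and/or alternate boundaries gained
inside it; regions outside the outermost shared boundaries are not
analyzed.  Class proportions sum to 1 over analyzed regions.

## 4C viewpoint profiles

Viewpoint-anchored fragment counts are normalized to reads per million
over included fragments (viewpoint ± 2 excluded — self-ligation and
undigested template dominate there) and smoothed with a centered running
mean of 5 fragments (edges truncated, excluded fragments skipped).  This
deliberately replaces model-based 4C normalization with a transparent,
parameter-light scheme adequate for ratio-of-conditions claims; it does
not support significance statements.  Per-target signal is the mean
smoothed value over overlapping, non-excluded fragments; the change is the
alt/ref ratio (NaN when the reference signal is zero or the target is
fully excluded).  Two estimator biases are intrinsic and documented: the
running mean dilutes loss at target edges, and RPM renormalization
slightly inflates the mutant profile elsewhere when a target loses mass
(≈ +1–3% on the ratio for the simulated configurations).

## Synthetic-data generator

All randomness derives from one seed through named per-stage streams
(genome, sites, coverage per condition, spike, contact maps, visibility,
4C, boundary plan), so each stage is independently reproducible and
changing one stage's parameters does not perturb another's draws.

**Genome and sites.**  Background sequence has block-wise base composition
(4-kb blocks, Dirichlet(2.5) per block), an isochore-like heterogeneity.
Exactly round(fraction_u · n_sites) sites (default 30% of 400) receive a
20-mer sampled from one of three U families (canonical U1 60%, two
noncanonical variants 25%/15%; 12–13 informative positions at 0.92
dominant probability) written immediately 5′ of the core on the motif
strand; cores are sampled from a 19-bp CTCF-like PWM.  Non-U sites carry a
flank drawn from one of six weak context families whose moderately
conserved positions (0.85 dominant) alternate with fully degenerate ones.
This emulates the fact that real CTCF-site flanks share repeat/promoter
context rather than being uniform random: with uniform flanks, k-medoids
scatters ~1/k of the background into every cluster including U clusters,
which buries the per-group U-percentage signal under flat noise.  The
interspersed-informative design keeps background flanks in their own
clusters while guaranteeing they never show the ≥ 6-consecutive
informative run that defines a U motif.

**Occupancy and coverage.**  Wild-type occupancies (expected reads per
site) are lognormal(μ = 3.7, σ = 0.85) — median ≈ 40 reads with a
realistic dynamic range; mutant occupancy is exactly (1−δ)·occ at U sites
(default δ = 0.8) and unchanged elsewhere.  Reads are Poisson per site,
fragment midpoints truncated-normal around the summit (sd =
fragment_len/4, truncated at 2 sd), deposited on 10-bp bins, plus uniform
background at 5e-4 reads/bp.  The spike-in contig has 200 evenly spaced
sites whose occupancies are drawn once and shared by both conditions;
condition depth multiplies everything, so the spike summit ratio is the
depth ratio by construction.

**Contact maps.**  Expected contacts are
`base · (|i−j|+1)^(−0.75)`, multiplied by 5 within TADs (contig ends act
as implicit boundaries); Poisson noise is sampled on the upper triangle
and mirrored.  Per-bin visibility factors (lognormal, σ = 0.2) shared
between conditions emulate mappability/GC bias, and 5% of bins are
near-invisible "junk" (the intended target of the lowest-5% mask).  Junk
bins are kept ≥ 4 bins from planted boundaries and ≥ 6 bins apart so
ground-truth recovery stays well defined — without an explicit junk
population the 5% mask preferentially removes boundary bins, whose
marginals dip by construction.  The default boundary layout spaces
boundaries 20 bins apart (1 Mb TADs at 50-kb bins) with insertions at
mid-TAD, so every TAD — including insertion-created sub-TADs — is at
least as large as the 8-bin insulation window; smaller TADs measurably
depress their flanking boundaries' insulation strength.  Replacements
move a boundary by 3 bins, past the ± 1 matching tolerance.

**4C.**  Expected counts decay as `(distance+1)^(−1)` from the viewpoint
with amplitude 20 000 at the viewpoint (QHR-4C-scale depth); the planted
enhancer–promoter loss multiplies the mutant expectation on its target
fragments.  In pipeline runs the planted loss region extends 2 fragments
beyond the annotated element on each side, and measurement targets the
element, so the running mean sees only perturbed fragments; real
regulatory perturbations likewise do not stop at annotation edges.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors, mappability in ChIP tracks,
fragment-length variation, replicate structure, peak-calling uncertainty
(peaks are taken as given), partial or heterogeneous occupancy loss at U
sites (the loss is a single multiplicative δ), compartment-scale Hi-C
structure, loops, and 4C primer artifacts.

## Statistical behavior of the per-group U percentages

Because the planted effect is a sharp two-point law (all U sites lose the
same fraction δ, non-U sites lose nothing), measured fold changes form two
well-separated modes at any noise level compatible with accurate
downregulation calling (precision/recall ≥ 0.9).  Consequently
fold-change groups 1 and 2 contain essentially no true U sites, and their
U percentages are small iid counts of background flanks absorbed into
U-labeled clusters.  The enrichment signature — group 4 ≫ group 3 ≫
groups 1–2, with group 4 several-fold above group 1 — is reproduced
robustly (20/20 calibration seeds), but a *strict* ordering between
groups 1 and 2 is a coin flip by construction and ties occur.  Real data,
where binding loss is graded, produces the graded low-group percentages
that a fixed-δ simulation cannot.

## Problem sizes and runtime

Default study conditions: 400 sites on two 200-kb contigs plus a 100-kb
spike contig (ChIP chain ≈ 3 s); ten 240-bin contact-map contigs with 50
planted boundary edits (≈ 2 s); 200 4C fragments.  These sizes keep full
recovery experiments fast while leaving every estimator comfortably in
its asymptotic regime (spike factor ≈ 1%, boundary recall 1.0, 4C ratio
± 0.02).

## Known limitations

* Replicate-aware statistics are out of scope; fold changes carry no
  per-site significance.
* The canonical U-motif model used for U1 labeling is the simulator's
  canonical family; for real data a curated PFM should be supplied.
* k-medoids finds local optima; a different k or seed can split or merge
  clusters near family boundaries (labels are reported per run and are
  deterministic given the seed).
* Dense per-contig contact matrices only — suitable for toy/locus scale,
  not genome-wide maps.
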