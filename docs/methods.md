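# Methods

This note records the models behind each stage, the parameter choices that
matter, what the synthetic cohorts do and do not emulate, and the numerical
decisions a maintainer would want to know.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive coordinates used in printed reports happens only in report
writers. Interval merging requires ≥ 1 bp of overlap by default —
book-ended intervals are *not* merged — with the minimum overlap exposed as
a parameter. Chromosome names compare as exact strings; readers can
normalize a `chr` prefix.

## SV-HRR caller

Recurrence is the number of **distinct donors** whose qualifying SV touches
a window; call multiplicity never counts twice. DEL/DUP recurrence uses
fragment overlap with the window; INV/TRA use breakpoint containment,
consistent with the short (1 kb) windows used for those types. A
breakend-only mode for DEL/DUP exists behind a flag. Insertions are
rejected at parse; intra-chromosomal fragments strictly over 1 Mb are
removed (the boundary value 1 Mb is kept); translocations carry no
fragment length and always pass.

Region growth: repeatedly take the unconsumed window with the highest donor
count (ties: lowest-ordered chromosome, then leftmost), stop when the
maximum falls below the 4-donor seed threshold, and extend across
step-adjacent windows while each holds at least one donor (an alternative
threshold is a parameter). Consumed windows cannot seed or join another
region, preventing nested duplicates. The merged region is a candidate at
≥ 10 distinct donors. Iterating global maxima (rather than one maximum per
chromosome) is the implemented reading. Per-caller candidates are merged
with ≥ 1 bp overlap; `Dual` marks agreement of both callers. The cross-type
patient-level merge recomputes recurrence by scanning all filtered calls
against the merged interval under the same overlap semantics.

The caller is verified bitwise against a naive enumerate-and-grow oracle on
hundreds of random instances.

## Gamma-Poisson hotspot test

Hypothesis units are the 200 bp single-linkage clusters of pooled
mutations (a 201 bp gap splits), with the response counting distinct
(donor, site, alt) events; identical recurrent mutations in different
donors count separately because cross-donor recurrence is the signal. A
fixed-tile mode is available.

The background is NB2: Var(y) = mu + mu²/theta, log mu = log L (offset) +
beta0 + beta'x. Covariates are length-weighted means over the cluster
interval (numeric tracks), per-state bp fractions with the first state as
reference (categorical), GC fraction from sequence, and — by default —
standardized log cluster length as a *free* covariate on top of the
offset. The free length term matters: linkage clusters couple length to
count mechanically (long clusters exist because they were locally dense),
so a pure unit-coefficient offset badly mis-calibrates positional data;
the free term lets the fit learn the empirical sub-linear relation.
"Nucleotide context" enters as cluster GC fraction; the full 96-context
composition is over-parameterized at cluster scale. All covariates are
z-scored across clusters, and zero-variance covariates are dropped with a
warning.

Fitting alternates IRLS for beta with Newton steps for theta on the
profile likelihood in log-space (steps clipped to ±2), declaring
convergence at a relative log-likelihood change below 1e-8 within 100
outer iterations; non-convergence raises with the last iterate and
gradient norm. Under-dispersed (Poisson-like) data drive theta to a cap of
1e6 with a warning rather than an error. The fit is cross-checked against
an independent maximum-likelihood NB regression implementation on
simulated data.

`fit_and_test` adds a one-round robust refit: clusters significant in the
first pass are excluded from the second background fit, and all clusters
are retested. Without it, even 0.5% contamination by 5-fold hotspots
deflates the dispersion estimate (theta 10 → ~7) enough to mask the
hotspots themselves.

P-values are exact NB upper tails P(Y ≥ y); BH runs once genome-wide. The
calibration and power studies simulate at the cluster level with
beta0 = log(297 × 50e-6) ≈ −4.21 — 297 donors at 50 mutations/Mb, a
typical UV-melanoma burden, pooling to ~14.9 events per kb — one standard
normal covariate with unit effect, theta = 10, and 10 planted 5-fold
hotspots of 1 kb per 2000 clusters with covariates at the reference value,
so the fold is the only systematic difference from the matched background.
Detection of a planted hotspot on positional data still depends on its
local covariate-modulated background: a fold planted on a covariate-poor
tile can be genuinely undetectable at cohort scale, as the demonstration
cohort shows.

## Enhancer annotation and functional evaluation

An H3K27ac peak becomes HRR-associated on ≥ 1 bp overlap with any
qualifying HRR (SV candidates or q < 0.05 clusters); ids are assigned in
genomic order. Screen eligibility additionally requires an H3K4me1
overlap, and core regions are the intersections with ATAC peaks — one
enhancer may yield several cores, and enhancers without ATAC overlap leave
library design.

Presumed targets are genes whose TSS lies within 1,000,000 bp (inclusive)
of an enhancer edge. A gene reachable from both an HRR-associated and an
HRR-unrelated enhancer stays in the HRR-associated group only, keeping the
null group clean. Scores are compared per HRR type by two-sided
Mann–Whitney U (exact null for combined n ≤ 20 without ties, otherwise
normal approximation with tie correction), checked against exact
enumeration and a permutation oracle. At demonstration scale the 1 Mb
windows sweep in many unrelated genes, so the rank test is heavily diluted
— the demo reports the dilution fraction alongside the p-value.

## Guide design

Bins are 100 bp; a final remainder of at least 25 bp stays its own bin,
shorter remainders merge leftward (a sub-25 bp core still yields one bin).
Candidates are 20-mers fully inside the core with an NGG PAM on either
strand (the PAM may extend past the core) whose cut site — between
protospacer positions 17 and 18 — falls in the bin; TTTT stretches, Ns,
and GC outside [20%, 80%] are excluded. Scoring is a fully specified
surrogate (GC band term plus homopolymer term, range [0, 2]) behind a
pluggable interface; best per bin wins, ties to the smaller cut-site
coordinate, then the + strand. The external scorer the original design
space would use is intentionally replaced by this deterministic surrogate;
the best-per-bin tiling structure is what is preserved.

Non-targeting controls are seeded random 20-mers with GC in [40%, 60%] and
no TTTT, rejected when an exact match exists on either genome strand.
Membership tests use a sorted 2-bit-packed index of all genomic 20-mers;
the direct string scan of both strands remains as the independent slow
path used in verification. A stricter Hamming-distance-≥ 2 mode exists but
exact-match absence is the default, sufficient on synthetic genomes.

## Screen statistics

The 1% lowest-count guides of each sample are flagged (ties at the cutoff
included) and the union across samples is dropped so all samples share one
guide universe — ranks require it. Size factors are DESeq-style
median-of-ratios computed on control guides only, excluding controls with
any zero count. Guide scores are mean log2 fold changes across replicate
pairs with a pseudocount of 1.

alpha-RRA ranks all scored guides (controls shape the ranking but belong
to no enhancer), normalizes ranks to (0, 1] with mid-ranks for ties, and
aggregates each enhancer's sorted ranks u_(1..j ≤ alpha) through Beta
order-statistic probabilities; rho = 1 when no guide beats alpha.
alpha = 0.25 by default. The null permutes guide→enhancer labels over all
targeting guides with enhancer sizes preserved; p uses the add-one
estimator (so p ≥ 1/(1+n_perm)), with an exhaustive-enumeration mode for
small libraries. BH runs per direction; positive and negative selection
are separate analyses. Note one structural property: rho has an atom at 1
of size roughly (1−alpha)^m, so p-values are only approximately uniform
near 1 for small guide counts m; at the library's ~10 guides per enhancer
the atom is ~6% and global-null p-values pass KS uniformity.

## Loop targets

Loop distance is measured between anchor midpoints, bounds inclusive;
inter-chromosomal contacts are dropped. "Anchor falls inside" is read as
≥ 1 bp overlap — anchors are bins, containment would drop edge cases
arbitrarily. Both anchor orderings are checked; duplicate
(enhancer, gene) pairs collapse with the supporting-loop count recorded,
and links whose promoter anchor hosts several genes are flagged rather
than suppressed. Two promoter definitions coexist deliberately: 20 kb
upstream / 5 kb downstream for target assignment, TSS ± 3 kb for the
global enhancer–promoter loop census.

## Mutational signatures

SBS-96 categories are ordered substitution-class major (C>A, C>G, C>T,
T>A, T>C, T>G) with flanks alphabetical; purine-reference events are
reverse-complemented to the pyrimidine strand, and events with ambiguous
context are skipped and counted. Factorization minimizes generalized KL
divergence (the count-appropriate objective; Frobenius available) by
multiplicative updates, 2000 iterations or relative change < 1e-9, best of
n restarts, with the non-increase of the objective asserted on every run.
Signatures are column-normalized with exposures rescaled; components are
ordered by total exposure. k is user-specified (an elbow report over
k = 1..5 is available; no automatic choice). The bundled catalog contains
two *synthetic stand-in* profiles — a UV-like C>T-at-dipyrimidine profile
and a platinum-like profile — for tests and demos; matching against the
real COSMIC catalog requires supplying its file.

## Synthetic cohorts

The generators plant ground truth for every stage: dual-caller SV call
sets (per-call caller sensitivity 0.9, planted SVs emitted by both callers
with ≤ 100 bp breakpoint jitter, background lengths log-uniform on
[50 bp, 1 Mb] with 10% of draws in (1 Mb, 5 Mb] to exercise the length
filter), covariate-modulated SNVs whose substitution categories are drawn
from the configured signature mix *first* and then placed on
context-matching positions (so the emitted SBS-96 spectrum follows the mix
exactly), peak tracks covering every planted region, loops to dedicated
genes at 20 kb–2 Mb with sub- and super-threshold decoys, and
negative-binomial screen counts (Var = m + 0.05 m²) at 500× depth with two
replicates. Covariates are constant over 50 kb tiles so expected counts
integrate in closed form in tests. All outputs are deterministic under
(seed, config), with per-component sub-streams.

The demonstration cohort uses 120 donors over 2 × 8 Mb, an SV background
of 0.02 SV/Mb/donor/type (the low structural-variant density of real tumor
genomes), a point-mutation rate of 1.5e-5/bp/donor (~15/Mb,
melanoma-like), and an 80/20 UV/platinum signature mix.

What the synthetics do **not** emulate: real human genome composition and
repeat structure (guide off-target space is therefore trivial), indel
signatures, clustered rearrangement processes (chromothripsis), copy-number
interactions with screens, and donor-level burden heterogeneity beyond the
Poisson/NB models. Passing tests demonstrate the statistical machinery
behaves as specified under its stated models — not that those models
capture every property of real cohorts.

## Known limitations

- The hotspot test's cluster-length correction is empirical; clusters are
  conditioned on containing a mutation, so absolute rate parameters are
  identified only up to that selection.
- Permutation p-values are conditional on the observed rank pool; with few
  targeting guides the null is coarse (use the exact mode).
- Control-guide uniqueness is exact-match only by default.
- The dispersion estimate at very low mean counts is weakly identified;
  coefficient estimates are robust but theta can wander at the
  low-intensity settings used for coefficient-recovery examples.
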