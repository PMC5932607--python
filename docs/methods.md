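# Methods

This note documents the models implemented in `mmrsig`, their assumptions,
the defaults that matter, and the design decisions taken where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The 104-channel scheme

Base substitutions are classified by substitution class and ±1 bp context
on the pyrimidine strand: 6 classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16
flanking combinations = 96 channels, ordered class-major then 5′ then 3′
base alphabetically (the conventional layout).  A mutated purine is
reported as the reverse-complement event.  Indels occupy 8 channels:
{del1_AT, del1_CG, ins1_AT, ins1_CG, del_2to5, ins_2to5, del_gt5, ins_gt5}
— 1-bp events split by the base class of the inserted/deleted base, longer
events binned by length.  This 8-way partition follows the biology of
MMR-deficient indels (overwhelmingly 1-bp slippage events whose substrate
is the A/T vs C/G homopolymer class); it is a declared convention of this
package, versioned in the scheme string `mmrsig-104-v1`, and the NMF
treats the indel block opaquely so an alternative partition is pluggable.
Indels of ≥ 400 bp are treated as structural variants and excluded.

Indels are stored VCF-anchored at the I/O boundary and left-aligned
against the reference before classification, tract assignment or duplicate
filtering, so that placement within a repeat is deterministic.
Coordinates are 1-based at the I/O boundary and 0-based half-open
internally; `io.to_zero_based` is the single conversion point.

**Duplicate filter.** Calls observed at the same site in ≥ 2 samples are
removed from every sample: substitutions keyed by full allele identity
(chrom, pos, ref, alt), indels by left-aligned position only.  The
asymmetry is deliberate — two different substitutions at one site are
independent events, whereas two indels at one homopolymer are the same
slippage-prone locus firing twice, a hallmark of inheritance from a shared
ancestor or a recurrent artifact.

## Repeat tracts and the indel-rate spline

A repeat tract is a maximal run of ≥ 4 copies of a 1–3 bp unit ("n ≥ 4" is
read as unit copies for every unit length, so homopolymers span ≥ 4 bp,
dinucleotide tracts ≥ 8 bp, trinucleotide ≥ 12 bp).  Non-minimal units are
excluded (an A-run is a homopolymer, never an "AA" tract) and partial
trailing units do not extend a tract.  The scanner is a linear
`s[i] == s[i+u]` period scan; it is property-tested against a quadratic
maximal-periodic-interval oracle on random strings.

A 1-bp indel is "in" a homopolymer when its left-aligned position lies in
a tract of the inserted/deleted base; an insertion abutting the tract also
counts, since the slippage event lengthens the run (left-alignment places
it at the tract start).

The per-tract indel rate as a function of homopolymer length l is fitted
as a Poisson GAM, `k_l ~ Pois(N_l · r(l))` with the genomic tract census
`N_l` as exposure and `log r(l)` a cubic B-spline (statsmodels `GLMGam`).
Defaults: basis dimension adapts to the number of observed lengths (at
most 8); penalty weight `alpha = 1.0` fixed, with `alpha="gcv"` available.
The fixed mild default is deliberate: homopolymer profiles have few
distinct lengths (roughly 4–35, usually fewer with data), where GCV's
penalty choice is noisy; the fixed penalty leaves the linear trend
unpenalized and damps spurious wiggle, and the pointwise 95% intervals
(delta method on the linear predictor) then cover a log-linear truth at
the nominal rate in simulation.  All-zero profiles short-circuit to rate 0
with the exact-Poisson zero-count upper bound per length.

## Mutation rates in selfing MA lines

Mutation-accumulation lines pass through a single-cell bottleneck each
generation; sequencing the final animal detects a mutation if it is still
heterozygous or has fixed.  Under selfing, a het mutation is lost / stays
het / fixes with probability 1/4 : 1/2 : 1/4 per transmission, so after k
transmissions it is detectable with probability
`2^-k + (1 − 2^-k)/2 = 1/2 + 2^-(k+1)`.  Summing over the generation of
origin gives the detection factor `f(G) = G/2 + 1 − 2^-G` (f(1) = 1,
f(20) ≈ 11).  Counting heterozygous mutations as detected is the central
modelling decision: a fixed-only model (factor G/2) is inconsistent with
the observed per-line burdens and rates this model reproduces.

Detected counts are Poisson, `m_i ~ Pois(μ · d · L · f(G_i))` with d = 15
germ-cell divisions per generation and L the genome length (default
100,286,401 bp, the WBcel235 total).  The MLE pools lines of any
generation mix: `μ̂ = Σm_i / (d·L·Σf(G_i))`.  The 95% CI is the exact
Poisson (Garwood) interval on `Σm_i` divided by the same denominator; a
normal-approximation option exists and agrees to ~0.5% at thousands of
counts.  Where only per-genotype averages are available, 3 lines per
genotype is assumed (the design of the underlying experiments).

## KL-NMF signature extraction

The cohort count matrix V (samples × 104) is factorized as `V ≈ E·P`
minimizing generalized KL divergence — equivalently maximizing the Poisson
likelihood `V_ij ~ Pois((EP)_ij)` — with the classic multiplicative
updates.  The divergence is non-increasing per update (asserted in tests);
a 1e-12 pseudo-count guards 0·log 0.  Defaults: 50 random restarts (best
divergence kept), `max_iter = 2000`, relative tolerance 1e-6; a fixed
`random_state` makes the fit bit-reproducible.  Signature rows are
normalized to the simplex with the scale absorbed into exposures, so
exposures are attributable mutation counts.

**Rank selection.** For each candidate rank r,
`AIC_r = 2k_r − 2·logL_r` with the Poisson log-likelihood of the raw
counts at the fitted factorization and `k_r = r·(104 + S − 1)` free
parameters (signatures on the simplex) — the parameter-count convention is
ours and configurable.  The chosen rank is the smallest at which the AIC
improvement over the previous rank drops below 1% of the AIC magnitude
("saturation", mirroring elbow selection without a hard test); RSS is
reported alongside as the saturation cross-check.

## Cross-species comparison

Indel channels are excluded from all catalog and cross-species comparisons
(indel opportunity depends on both base and repeat content, which a
per-trinucleotide adjustment cannot capture); the 96-channel substitution
part is renormalized first.  Humanization multiplies channel c (context t)
by `f_target(t)/f_source(t)` over the 32 pyrimidine-centered
trinucleotide frequencies of the two sequence spaces, then renormalizes;
it is exactly invertible (round-trip identity to 1e-9, tested).  3-mers
containing N are skipped.  Cosine similarity ≥ 0.80 is labelled "high".
An option excludes the four N[C>T]G (CpG) channels from both sides and
renormalizes before comparing — removing the 5meC-deamination component
that has no counterpart in genomes without cytosine methylation;
renormalization happens after the exclusion (a declared convention).  The
embedding contract ends at the cosine-distance matrix
(`d_ij = 1 − cos(s_i, s_j)`); the t-SNE itself is external plumbing.

## Additive Poisson factor model

Per-genotype patterns come from identity-link non-negative Poisson
regression: with design X (entry (s, f) = generations propagated if factor
f is active in sample s), channel counts are `y_sc ~ Pois((Xβ)_sc)`,
β ≥ 0.  Identity link (additive rates) is the substantive choice:
mutational processes contribute counts additively, and β is then a
per-generation channel rate.  The per-channel problem is convex;
multiplicative updates (KL-NMF with the left factor frozen at X) converge
monotonically, so the fit is deterministic.  An interaction column for
double mutants is optional and off by default.  At realistic wild-type
burdens (a handful of mutations per line) the background factor's
104-channel pattern is statistically unrecoverable from a few lines — the
recovery guarantees in the test suite apply to the mutator factors, whose
per-generation rates are two orders of magnitude higher.

## MSI association

Relative signature contributions are compared between MSI and MSS samples
(MSI-H maps to MSI; MSI-L and MSS to MSS) with a one-tailed Wilcoxon
rank-sum test, alternative "greater in MSI": exact enumeration with
midranks for combined n ≤ 12, normal approximation with tie correction
otherwise; Bonferroni over the number of signatures tested.  AUC is the
Wilcoxon U divided by `n_MSI · n_MSS` (an identity asserted in tests);
its CI is DeLong's asymptotic interval, with a seeded stratified bootstrap
(2000 resamples) for groups smaller than 3 — the CI method is a package
choice, validated only on synthetic data.

## Synthetic data: what it emulates, and what not

`simulate_genome` draws an i.i.d. background at a given GC fraction
(default 0.36, worm-like) and can inject extra homopolymer tracts per
length to emulate a repeat-rich census; the realized census is emitted as
truth.  `simulate_ma_lines` draws Poisson(μ·d·L) mutations per generation
and thins each by the selfing detection probability — simulation is at
generation level, not per germ-cell division, which leaves the detection
mathematics identical at desk-scale runtimes.  Detected substitutions are
placed at genome positions matching their channel's trinucleotide context;
1-bp indels land in homopolymer tracts with probability proportional to a
length-bias curve (default: rising e^0.7 per bp to length 10, declining
beyond — the slippage shape).  Site collisions are resolved by rejection;
at desk-scale rates they are vanishingly rare.  Default worm-like channel
probabilities (~75% indels, T>C/C>T-heavy substitutions, elevated A[T>A]T
and G[C>T]N) are constructed constants, not measured data.

`simulate_cohort` draws per-(sample, signature) exposures log-normal
(default median 150 mutations, log-sd 0.7) over three constructed
signatures — MMR-like (indel-heavy), Clock-like (CpG C>T), and a fixed
context-structured background — and Poisson counts around the mixture.  A
sample is MSI with probability 0.2 (the MSI-H fraction of colorectal /
gastric cohorts) and has its MMR-like exposure multiplied by 20.  The
background signature is deliberately spiky rather than flat: a flat
profile sits near the cone spanned by the other signatures and is
unidentifiable to any NMF at desk scale, a degeneracy real context-biased
signatures do not share.  The log-sd default is calibrated so the
generator's contract holds (MSI/MSS separation of truth exposures at
AUC ≥ 0.95 under default coupling while the planted factorization remains
recoverable).

What passing tests on these generators shows: that the estimators recover
known truth under the stated noise models at the stated sizes.  What they
do not show: robustness to alignment and calling artifacts, clustered or
selection-filtered mutations, copy-number structure, sequencing error, or
signature shapes outside the planted family — none of which the
generators emulate.

## Numerical notes and problem sizes

Multiplicative updates use a 1e-12 floor inside divisions and logs.  The
duplicate filter, dedupe and classification are order-preserving and
deterministic.  Seeded runs are bit-reproducible on one platform
(numpy default_rng, PCG64).  The test suite runs its recovery checks at
desk scale — 120-sample cohorts, 200–400 kb genomes, 200–500 simulation
replicates — sizes chosen so the whole suite completes in well under a
minute while leaving the statistical assertions comfortable margins.

## Known limitations

* The 8-indel-channel partition and the AIC parameter count are
  conventions; results depending on them should be checked under the
  alternatives the APIs expose.
* The spline CI is pointwise and asymptotic; at lengths with very few
  tracts it widens but is not exact.
* The additive factor model gives point estimates only (no uncertainty on
  patterns).
* Multi-allelic VCF rows are split into independent records; the original
  studies' treatment of such calls is unknown.
* The ICGC dialect requires a reference genome to anchor '-'-allele
  indel rows.
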