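# Methods

## Block-level karyotype model

A karyotype is a gametic (n) complement; reported diploid numbers are
always 2 × n, matching how meiotic painting data are counted.  Each
chromosome is an ordered reading of segments, a segment being an oriented
sub-interval `[start, end)` of one homeolog copy of one of the 22
conserved genomic blocks (A–X; K-L and M-N behave as atomic painting
units).  Exactly one active centromere sits between two segments; at
block-level resolution the centromere has no extent.  There is no
sequence coordinate system: physical sizes (Mb) and flanking gene
identifiers ride along as free-text annotations on events and are never
computed with.

The ACK arm assignments are a packaged, user-overridable table
(`data/ack_blocks.tsv`).  The AK7 arm split is taken as S,T | U; the
alternative S | T,U produces the same AK5/AK7 fusion once the AK7
centromere is eliminated, and can be selected via an override table.

Operators:

* **WGD** duplicates every chromosome into homeolog copy 2.  Copy indices
  are bookkeeping only: structural comparison is copy-blind by default
  (painting cannot phase homeologs), and copy-aware comparison is
  available for serialization tests.
* **EET** joins two chromosomes at named termini; the reading of one
  partner is reversed as needed so the joined ends abut.  The dicentric is
  resolved by eliminating a named centromere, recorded in the product's
  history; no neocentromere support.
* **Reciprocal translocation** exchanges the fragments *distal* to two
  breakpoints, i.e. the acentric fragments, so both products are
  monocentric by construction.
* **Unequal translocation** is a reciprocal translocation whose second
  breakpoint is a chromosome terminus: a terminal fragment is donated.
* **Pericentric inversion** reverses the interval between two breakpoints
  that flank the centromere, flipping orientations and mirroring the
  centromere position; applying the same inversion twice is the identity.

Breakpoints address a chromosome either by terminus or by (block,
ancestral coordinate, copy); a coordinate strictly inside a segment splits
it, a coordinate at a segment edge addresses the adjacent junction.  After
inversions the same (block, copy) edge can occur at two positions of one
chromosome; an `occurrence` index disambiguates in reading order.
Breakpoints at the centromere gap are rejected.  Within-block cut
fractions default to block midpoints when a scenario does not specify
them; fractions never affect block-label-level output, only serialized
coordinates.

Sub-block display labels (Fa, Fb, Fc, …) are assigned per homeolog copy by
ancestral coordinate order of that copy's cut points, which reproduces the
published sub-block nomenclature of the rearranged chromosomes.

**Canonicalization.** A chromosome equals its full reversal; the canonical
form is the lexicographically smaller of the forward and reversed-flipped
token readings.  Adjacent segments that continue the same block copy in
unbroken ancestral order and orientation are merged first ("trivial cuts"
are physically invisible), which makes inversion involution exact.
Karyotype equality is the multiset of canonical chromosome forms,
copy-blind unless requested otherwise.

**Conservation.** Every operator except WGD preserves the multiset of
(block, copy, interval) coverage exactly; WGD doubles it.  This is
asserted in tests across random scenarios.

The packaged ACK→Catolobus scenario is: WGD; EET of the AK5/AK7 homeolog-b
pair keeping the AK5 centromere; reciprocal translocation of the fusion
with AK3b (cut inside F, cut at the U|T junction); pericentric inversion
of the U+Fb+G+H product (cuts inside Fb and H); pericentric inversion of
AK1a (cuts inside A and C); unequal translocation donating Aa of AK1b to
the upper-arm terminus of AK6b.  A separate optional one-event scenario
carries the pericentric Cp13 inversion private to a single eastern
population; it is not part of the canonical scenario.

## Parsimony search

The search formalizes what is traditionally reconstructed by expert
inspection.  It is iterative-deepening depth-first over operator
applications with canonical-form memoization.  WGD is never searched:
ploidy change is observed, not inferred, and belongs in an explicit
scenario prefix.

*Breakpoint policy.*  Within-block cuts are restricted to the cut
fractions visible anywhere in the target (plus all segment junctions and
termini).  Rationale: no operator can ever merge sub-blocks back, so a
minimal scenario reaching the target can only cut where the target shows a
cut.

*Admissible lower bounds* (a state is pruned when depth + bound exceeds
the current limit):

1. every event rewrites at most two chromosomes → at least
   ⌈mismatched/2⌉ events remain, where "mismatched" is the multiset
   difference from the target;
2. only EET changes complement size (there is no fission operator), so
   every completing path contains exactly n_state − n_target EETs, a state
   with fewer chromosomes than the target is dead, and — since EET makes
   no cuts and other events make at most two — at least
   (n_state − n_target) + ⌈cut_deficit/2⌉ events remain.  A state carrying
   a cut the target cannot absorb (under the best per-block pairing of
   homeolog copies) is dead;
3. each junction between segments is encoded as an unordered pair of block
   edges, invariant under reversal and under interval reversal away from
   the junction.  An EET creates exactly one new junction, any other event
   at most two, so at least (n_state − n_target) +
   ⌈(missing_adjacencies − n_EET)/2⌉ events remain.

The adjacency bound is the decisive one: for the published five-event
reconstruction it equals the true distance already at the root, and the
depth-5 search expands a few hundred nodes in about two seconds where the
first two bounds alone required minutes.

*Operand policy.*  By default every operand of a generated event must
currently differ from the target (`mismatch_only`).  This is a
completeness caveat: a minimal scenario could in principle route through
an event touching only target-matching chromosomes.  In practice such
scenarios can essentially always be reordered, the policy recovers all
seeded random scenarios in tests, and `operand_policy="any"` restores the
unrestricted search.

Equally parsimonious scenarios are all returned (bounded by
`max_scenarios`), deduplicated up to operand symmetry (breakpoint order,
end mirroring, homeolog-twin operands) and sorted by serialized form; no
single "true" history is claimed.  An exhausted depth bound reports
"not found ≤ max_depth" explicitly.

## Ploidy inference

Sites are filtered to coverage ≥ 10 and minor-allele reads ≥ 2 by default
(configurable; all discards are logged), frequencies are alt/(ref+alt)
restricted to the open interval (0, 1).  The published workflow's filter
settings are not recorded, so these defaults are this package's own.

Fixed-mean Gaussian mixtures with means {1/2}, {1/3, 2/3},
{1/4, 1/2, 3/4} are fitted by EM on weights and a standard deviation;
the free yardstick model has three free means.  Two deliberate choices
depart from the obvious parameterization:

* **Homoscedastic components** (one shared sd per model, floor 1e-3).
  Read-sampling spread is nearly equal at every dosage mean, while
  per-component deviations let spare components of an over-rich model
  collapse onto a handful of tail sites and inflate its likelihood
  spuriously.  Per-component deviations remain available
  (`shared_sd=False`).
* **Adequacy-based selection.**  Lower-ploidy fixed models are nested in
  higher ones (a diploid frequency cloud is a tetraploid mixture with all
  weight on the middle component), so the raw argmin of
  Δ = logL(free) − logL(fixed) can never prefer the simpler model.  The
  call is therefore the *lowest* ploidy whose Δ is within 0.02
  log-likelihood units per site of the free model.  Under the synthetic
  study conditions (5 000 sites, mean depth 40 with negative-binomial
  overdispersion 5, base error 0.01) adequate models show Δ/site ≤ ~0.01
  and wrong-ploidy models ≥ ~0.13, so the threshold separates the regimes
  with at least a six-fold margin on either side.

The free fit is restarted from every fixed solution (padding means when
the fixed model is smaller) in addition to a quantile start, so it truly
nests each fixed model and every Δ ≥ 0 up to EM tolerance.  EM runs to
tolerance 1e-8 on the log-likelihood, at most 500 iterations,
non-convergence flagged with the best fit returned; the log-likelihood
trace is monotone and asserted so in tests.

The histogram criterion uses 30 equal bins on (0, 1); expected bin counts
integrate the fitted fixed model per bin, and ordinary least squares of
empirical on expected counts yields slope, slope SE, SSR and R².  The
published workflow's first criterion — visual comparison of frequency
histograms — is inherently visual; the package generates the histograms
(with fitted curves) and automates only the quantitative proxies: the
best-R² model and the slope/R² quality gate (slope > 0, R² ≥ 0.8 by
default).

The median allele ratio (max/min read count per site, undefined at
monoallelic sites) is scale-free.  The reference-limit rule takes the
lowest and highest median ratios among reference samples of known ploidy
as acceptance limits; a query inside the limits is deemed the references'
ploidy.  The final call requires the Δ criterion and the median-ratio
placement to agree, otherwise it is `ambiguous`.

An optional denoise step adds a uniform(0,1) mixture component whose
weight is learned; it is off by default.

## D-statistic

Binary mode (default) takes one haplotype per sample, as in consensus
supercontig alignments; each site is polarized against the outgroup
allele, contributing 1 to ABBA when (P1,P2,P3) read (ancestral, derived,
derived) and to BABA when (derived, ancestral, derived).  Frequency mode
weights sites by derived-allele frequencies, (1−p1)p2p3(1−pO) and
p1(1−p2)p3(1−pO).  Sites with missing calls are skipped and counted.

The jackknife deletes one contiguous block of sites at a time (input
order, approximating per-locus linkage blocks in target-enrichment data;
default block size 2 000 sites, at least 20 non-empty blocks required),
estimates SE from the delete-one replicates, and reports Z = D/SE with a
one-sided normal p.  Significance is p < 0.01 and Z > 3.  A constant D
across blocks yields SE 0 and is flagged rather than divided by.  The
study's own D values on real data depend on the full deposited read set
and are context, not targets, for this package.

## Synthetic data

All generators are fully determined by their seed.

* **Allele counts**: dosage d drawn from per-ploidy dosage probabilities
  (defaults: diploid {1}; triploid {1: .5, 2: .5}; tetraploid
  {1: .4, 2: .2, 3: .4} — balanced heterozygous classes are rarer because
  intermediate dosages arise from fewer mutational routes), depth from a
  negative binomial (mean 40, dispersion 5 — capture data are
  overdispersed relative to Poisson; zero draws are lifted to one read),
  alternate reads Binomial(depth, p_eff) with
  p_eff = (d/p)(1−e) + (1−d/p)e and e = 0.01.
* **Quartet site patterns**: a site-pattern multinomial, not a coalescent:
  with probability g = 0.5 a site is informative and is ABBA with weight
  b + γ against BABA with weight b (b = 0.1), giving closed-form
  E[D] = γ/(2b + γ); remaining sites carry concordant or singleton
  variation that no D computation counts.  This is sufficient to calibrate
  D and its jackknife, and nothing more: no linkage, no drift, no
  population structure.
* **Cluster genotypes**: exact construction of requested shared /
  cluster-unique / singleton SNP counts (unique SNPs get ≥ 2 carriers so
  they survive singleton filtering); the truth record holds the expected
  partition.
* **Random scenarios**: k valid events rejection-sampled (identity events
  resampled); within-block cuts land on segment midpoints so the search's
  implied-cut policy can reconstruct them.

What passing tests on these generators do *not* show: robustness to
mapping bias, paralogy, allelic dropout in herbarium DNA, linkage
disequilibrium structure, or reference bias — none of which the
generators emulate.

## SNP partitioning

"Singleton" is read as a SNP whose alternate allele occurs in exactly one
sample of the analysis set (the subsampled set actually counted).
Cluster membership of a SNP is presence-based: at least one carrier among
the cluster's drawn samples.  With two clusters the mixed category is
empty by construction; it appears at K ≥ 3.  Subsampling is seeded and
deterministic.  Placement maps genes through their block to every
chromosome carrying any part of that block; with the unrearranged-only
display option, placements on chromosomes whose canonical structure
differs from the reference complement are flagged instead.  Upstream
variant-calling filters are accepted as already applied; the package takes
genotypes as given.

## Numerical and interface conventions

Site positions are 1-based (VCF); block fractions are half-open
[start, end) in ancestral block coordinates and serialized as floats that
arise from midpoint halving, so equality is exact.  Karyotype and scenario
files are versioned JSON; the reader/writer round-trip is byte-exact,
asserted in tests.  One global seed derives per-stage seeds by
stage-name hashing (CRC32 XOR), so pipeline stages are independently
reproducible; all filter discards are logged, never silent.

## Problem sizes

The test and acceptance workloads use the sizes the analyses are
calibrated at: 5 000 sites × 20 replicates per ploidy for mixture-model
selection, 20 000 sites × 40 null replicates (block size 500, 40 blocks)
for D calibration, 50 seeded random scenarios of ≤ 3 events for search
recovery, and the depth-5 reconstruction of the published karyotype.

## Known limitations

* The rearrangement model has no sequence coordinates, no neocentromeres,
  no rDNA loci beyond annotations, and no meiotic-pairing modeling.
* Search completeness is subject to the implied-breakpoint and
  operand-policy restrictions discussed above; distances are exact only
  relative to that move set.
* Ploidy inference makes no claim of output-identical behaviour to the
  published tool; it reimplements the model class and decision criteria.
* The D-statistic module computes single-quartet tests only: no f-branch
  statistics, no automatic trio enumeration.
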