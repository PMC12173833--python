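# Methods

This note records the models, the defaults and why they are what they
are, what the synthetic generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Insertion-time dating

A TE copy's age is estimated from its percent divergence *D* against its
family consensus, as reported in the `perc div.` column of a
RepeatMasker `.out` table. Two steps:

1. multiple-hit correction, on the percent scale:
   `K = -(300/4) ln(1 - 4D/300) = -75 ln(1 - D/75)`.
   This is a Jukes–Cantor-style saturation correction (conventionally
   cited as Kimura's in the repeat literature); it is defined on
   `0 <= D < 75`, is strictly increasing, and dominates the identity.
   Divergences at or beyond 75% are rejected at record validation — they
   are unresolvable by this correction.
2. molecular clock: `T = (K/100) / (2r)` My, with *r* the per-site
   substitution rate in substitutions/site/My. The factor 2 reflects
   that copy and consensus diverge along two lineages. *r* can be
   computed from a tree whose branch lengths are substitutions/site by
   dividing a root-to-tip path by its calibration date
   (`substitution_rate`); the packaged fig-wasp table carries
   per-species rates of (4.3–5.3) × 10⁻³ substitutions/site/My derived
   from a 485-My calibration.

*D* is taken raw from the annotation table and the printed correction is
applied on top; no CpG adjustment and no per-copy uncertainty
propagation (copies are dated by point estimate). Landscapes bin total
copy length (bases) by age with a default bin width of 1 My; the grand
total of the matrix equals the summed copy lengths exactly — summation
is in float64 over integer lengths, so conservation is bit-exact below
2⁵³ bases.

**Window fractions** are computed on the per-copy point ages (windows
closed on both ends), not on bin membership, so they do not inherit
binning artefacts.

**Burst peaks.** The per-bin total profile is smoothed with a centred
moving average (default 3 bins); local maxima with prominence at least a
fraction (default 0.1) of the global maximum are kept; each is reported
as the maximal contiguous run of bins at or above half the peak's
smoothed height, as a closed interval in My rounded to bin edges
("24–26 Mya" style), sorted by contained mass. The profile is
zero-padded so edge maxima are detectable. On planted bursts
(sd ≤ 2 My, n ≥ 2000 copies) the peak centre lands within one bin of
the true mean.

**Dominant families** rank classified (non-`Unknown`) families by total
length and return the minimal prefix whose cumulative share of
classified TE length exceeds the threshold (default 0.5); families tied
with the last kept one are all included so the output is deterministic.

## Phylogenetic signal

**Blomberg's K** uses the standard estimator: with C the shared
branch-length matrix and *â* the GLS (phylogenetic) mean,
`K = (MSE0/MSE) / [(tr C - n/1'C⁻¹1)/(n-1)]`, where MSE0 is the tip
variance about *â* and MSE the GLS error mean square. The no-signal
test permutes tip labels (default 999 permutations) and reports
`p = (#{K_perm >= K_obs} + 1)/(m + 1)` — the +1 smoothing means a
reported p is never exactly zero; published "P = 0" values correspond
to p < 1/(m+1). K is invariant to affine transforms of the trait. The
implementation is cross-checked in the test suite against an
independent dense-matrix evaluation and against R `phytools::phylosig`.

**Fritz–Purvis D** measures binary-trait clumping. The observed sum of
branch-wise state changes `d_obs` (internal states from the ML
Brownian / weighted squared-change parsimony reconstruction of the 0/1
coding, computed via a precomputed linear operator) is scaled between
its expectations under tip shuffling and under threshold-Brownian
simulation at the observed prevalence:
`D = (d_obs - mean d_BM) / (mean d_random - mean d_BM)`.
`p_random` is the fraction of shuffles with `d <= d_obs` (small values
reject randomness); `p_brownian` is the fraction of Brownian
simulations with `d >= d_obs` (values near 1 mean the trait is at least
as clumped as Brownian expectation). With this orientation an extremely
clumped trait yields a strongly negative D with `p_random ≈ 0` and
`p_brownian ≈ 1`, the regime reported for fig-wasp oviposition sites.
On trees as small as 11 tips the sampling distribution of D under
random traits is right-skewed (mean ≈ 1.0 but median ≈ 1.17 on our
11-tip reference tree); calibration checks therefore use a 32-tip tree,
where the median sits at ≈ 1.0.

**Power analysis.** "True K" targets are made operational by simulating
Brownian traits on a Pagel-λ-transformed tree, with λ calibrated by
bisection so the median realized K of a 200-draw pilot matches the
target; K = 1 is pure BM (λ = 1 exactly, no calibration), and λ may
exceed 1 slightly (within positive-definiteness) for targets above the
BM median. Power is the fraction of replicates whose permutation p is
≤ α. The test is correctly sized (type-I error ≈ α for i.i.d. traits)
and power grows with tree size. Note that on unit-depth Yule trees of
11 tips the power at K ≈ 1 is ~0.7–0.9, not the ~0.27 reported for the
wasps' own (unpublished) comparative tree — power at fixed n depends
strongly on tree shape, and `phytools::phylosig` gives the same ~0.7 on
our trees; the published figure evidently reflects a much more
star-like phylogeny.

## PGLS

`y = Xb + e`, `e ~ N(0, σ²C(λ))`, with C(λ) the BM covariance with
off-diagonals scaled by λ (diagonal kept). Fitting whitens by the
Cholesky factor of C(λ) and solves the least-squares problem; λ is
either fixed or profiled by bounded ML (tolerance 1e-6, with explicit
endpoint checks; boundary estimates are reported as exactly 0 or 1).
σ² is the ML estimate SSR/n; the log-likelihood includes ½ ln|C(λ)|.
The overall F compares the fit against the intercept-only GLS model
under the same C(λ). AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with k
counting intercept + slopes + σ² + (λ if estimated) by default; a
`k_convention="slopes"` switch gives the coefficients-only count — the
convention shifts AICc values but not rankings within a convention.
Categorical predictors are dummy-coded against their first category
(trait tables order oviposition as [inside, outside], so the reported
coefficient is the "outside" offset). λ = 0 reproduces OLS to 1e-8 on
ultrametric trees; λ = 1 matches a dense GLS solve to 1e-8; slope
recovery on 64-tip simulations is unbiased within 2 Monte-Carlo SE.

**Ancestral states** use the conditional-Gaussian (GLS) estimator:
`x̂_v = μ̂ + c_v'C⁻¹(y − μ̂1)` with `c_v` the vector of root-to-MRCA
path lengths between node v and each tip and μ̂ the phylogenetic mean;
this coincides with the joint-ML / weighted squared-change parsimony
reconstruction (verified against a direct numerical minimizer and
against `phytools::fastAnc`). Reported variances are
`σ̂²[t_v − c'C⁻¹c + (1 − c'C⁻¹1)²/(1'C⁻¹1)]`, which includes the
uncertainty from estimating the mean; the root estimate equals μ̂ by
construction. The recommended workflow reconstructs PGLS-fitted tip
values (the model's prediction of TE load); raw-trait reconstruction is
available by passing the trait directly.

## Group statistics

**Mann–Whitney U** is oriented: `U` counts (second-group, first-group)
pairs in which the second group's value is larger, +0.5 per tie, so
U = 28 of 30 for TE length with pollinators first and NPFWs second.
The asymptotic Z uses the tie-corrected variance
`σ² = (n₁n₂/12)[(N+1) − Σ(t³−t)/(N(N−1))]` with **no** continuity
correction — this is what reproduces the published Z values (e.g.
(28−15)/√30 = 2.373, and 2.745 rather than 2.739 for the tied family
counts). The exact two-sided p enumerates all C(N, n₂) assignments of
the observed values (ties handled by value comparison) and doubles the
one-sided tail in the observed direction, capped at 1; enumeration is
used when C(N, n₂) ≤ 10⁶ (configurable), otherwise the Z-based p is
reported. The enumeration engine is verified against an independent
rank-sum-formula oracle.

**One-sample t** reports t, df, two-sided p, the 95% CI, Cohen's d, and
the relative elevation `100(mean − μ₀)/μ₀` — the "135% elevation"
convention with the reference value as denominator.

**ANOVA + Tukey** wraps the standard one-way F and studentized-range
pairwise tests (statsmodels); compact letters are assigned from the
maximal cliques of the "not significantly different at α" graph, so
groups share a letter iff they are mutually non-separable.

## Genomic context

All intervals are normalized to 0-based half-open at ingestion (BED
kept, GFF3 start−1); only readers/writers convert. Gene proximity uses
a pyranges join with slack and an exact gap filter: a TE is assigned to
every gene with `gap ≤ window` (default 1000 bp, boundary inclusive;
overlap = distance 0); a TE may serve several genes. Normalized TE
length is `100·copy_length/consensus_length` percent and may exceed 100
(tandem expansions) unless capped.

TE/CRM overlap classification is total and mutually exclusive on
intersecting pairs: `te_within_crm` (CRM contains TE; identical
intervals count here by tie-break), `crm_within_te` (strict reverse
containment), `partial`, `none`. Reports attribute one configuration
per TE (containment beats partial, then leftmost CRM) so percentages
over overlapping TEs sum to 100; raw pair counts are reported
alongside. Strand is ignored. Window densities count interval midpoints
in non-overlapping windows and report a Spearman correlation between
two tracks (the "high CRM density, fewer TEs" reciprocal-density
check).

## Synthetic data: what it emulates, what it does not

- **TE bursts.** Ages are drawn from normals truncated at 0 (burst
  peaks are unimodal humps; truncated normals give interpretable ground
  truth), forward-converted with the exact algebraic inverse of the
  dating correction (`K = 200rT` percent, `D = 75(1 − e^{−K/75})`), and
  written as `.out` text with full-precision divergences so the
  forward/inverse round trip is exact to 1e-9 My at sd = 0. The unit
  under test is the dating pipeline, not a sequence evolver: there is
  no rate heterogeneity across sites, no CpG effect, no deletion bias,
  and no family-specific consensus error, so exact recovery here does
  not certify dating accuracy on real repeats — only the arithmetic and
  bookkeeping.
- **Trees.** Yule (pure-birth) with exponential waiting times, a final
  Exp(n) stem epoch so terminal branches are strictly positive, and
  depth rescaled to 1. Default study-scale tree: 11 tips, matching the
  number of sequenced wasp species.
- **Continuous traits.** Multivariate normal with covariance σ²C(λ);
  λ = 0 gives i.i.d. tips on an ultrametric tree.
- **Binary traits.** `random` is i.i.d. Bernoulli (resampled up to a
  retry cap if monomorphic). `clumped` plants state 1 on a union of
  whole clades chosen greedily (largest first, random among equals)
  until the prevalence count is met. A thresholded Brownian draw was
  considered and rejected: it is by construction the D statistic's own
  zero reference, so such "clumped" traits would be negative only about
  half the time; clade unions are super-Brownian, the regime of a
  strongly negative published D, and give D < 0 in ~100% of draws.
- **Interval sets.** Gene/TE/CRM features are planted in 1.2-kb slots
  with jittered offsets; the overlap plan pins the exact configuration
  of every planted TE–CRM pair in a truth ledger.

All generators are seed-deterministic: the same seed yields
byte-identical outputs.

## Numerical choices and degenerate inputs

- Covariance solves use Cholesky factorizations with a relative jitter
  of ~1e-10·tr(C)/n to guard zero-length cherries; dense inverses
  appear only in test oracles.
- Divergences ≥ 75%, inverted intervals, negative branch lengths,
  non-unique tip labels, monomorphic binary traits, constant continuous
  traits, empty groups and rank-deficient design matrices are rejected
  with specific errors; empty record lists and zero-length calibration
  paths warn and return empty/zero results.
- Trees are read as rooted; a basal polytomy is treated as unrooted and
  rejected. Internal polytomies elsewhere are preserved. Internal nodes
  receive stable preorder labels at construction.
- RepeatMasker `C` strands map to `-`; asterisked overlap rows are kept
  (flagged) and included by default, matching the annotator's default
  accounting; an optional Smith–Waterman score threshold is exposed
  instead of a hard-coded cutoff.

## Known limitations

- Printed comparative-analysis values that depend on the wasps'
  unpublished branch lengths (the specific K, D, PGLS F/AICc and
  coefficient values, and the 27–29% power figure) are anchors, not
  reproduction targets; the package reproduces every statistic that is
  computable from the shipped table, and validates the comparative
  machinery against independent oracles instead.
- Dating ignores divergence uncertainty and within-family rate
  variation; landscapes are point-estimate histograms.
- The Mann–Whitney exact engine enumerates complete assignments; for
  very large groups it falls back to the asymptotic p rather than a
  network/streaming algorithm.
- Overlap percentages are per-TE attributions; a TE overlapping many
  CRMs contributes once (pair counts are reported for the alternative
  reading).
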