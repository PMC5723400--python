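# Methods

## Clone identification and richness

A sample's multilocus genotype (MLG) is its vector of diploid allele
calls; allele pairs are stored order-normalized, so (A,B) ≡ (B,A), and a
call is missing as a whole when either allele carries the missing code —
a half-called diploid genotype cannot be matched meaningfully. Two
missing-data policies are implemented because field datasets rarely state
one:

* **strict** (default): samples share an MLG iff every call is equal,
  missing matching only missing. This is an equivalence relation, so the
  assignment is a true partition.
* **missing_wildcard**: samples are linked when all mutually non-missing
  loci agree; MLGs are connected components of the link graph. This is
  *not* transitive-by-locus — a heavily missing sample can bridge
  genuinely distinct genotypes — which is why it is opt-in and the policy
  used is recorded in every output.

Richness is R = (G − 1)/(N − 1), defined only for N ≥ 2 (a one-sample
site has no clonality information; the code refuses rather than returns
0/0). R is invariant to sample and locus order by construction.

## Probability of identity

Under Hardy–Weinberg equilibrium with allele frequencies p_i at one
locus, the probability that two random individuals share their genotype
is Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)² — the sum of squared genotype
probabilities over unordered genotypes. Independent loci multiply. The
implementation uses this basic form; small-sample-bias and sibling
corrections exist in the literature but are deliberately not defaults
here, since the basic form is what the marker-power tables of this kind
of survey report. The power curve orders loci most-discriminating-first
(ascending per-locus P_ID, ties by locus id); the full-panel cumulative
value is order-invariant.

"Expected duplicates" is reported in the pairwise form C(N,2)·P_ID.
P_ID is a two-individual probability, so its natural expectation is over
pairs; the per-individual form N·P_ID is exposed as an option because the
phrase "expected number of individuals with the same genotype" admits
either reading.

## Cyclone exposure

Hourly site winds are w·cyclone + (1−w)·synoptic with a piecewise-linear
weight: w = 1 inside 3 eye radii (radius of maximum winds), declining
linearly to 0 at 6 eye radii (configurable). The qualitative requirement —
cyclone winds dominate near the eye, synoptic winds dominate far away —
is made concrete with the simplest continuous, bounded, testable ramp.

Waves: where a significant-wave-height series is not supplied, a
configurable monotone wind→H_s map is applied; the default is linear and
calibrated so gale-force blended wind (17 m s⁻¹) meets the 4 m H_s
disturbance criterion exactly. No fetch or bathymetry adjustment is made.

An exposure *event* is a maximal contiguous run of hours with H_s ≥ 4 m
lasting ≥ 1 h (both configurable), counted in the year of its first hour;
record gaps break runs and are logged, and per-year coverage fractions
are reported so thin years can be excluded. This episode definition means
a three-day storm is one exposure, not 72. λ is the plain mean of the
yearly counts and Pr(X ≥ 1) = 1 − e^(−λ) follows from the Poisson
assumption on yearly event counts.

## Driver selection

Per species, with site-level R as a Gaussian response:

* **Transforms** (applied exactly once, recorded in column names):
  √cyclone probability, log SST, √KD490, √distance from shore. The
  cyclone transform is included by default to match the conventional
  labelling of such tables even though it is the mildest of the four.
* **Prefilter**: walking a priority order (cyclone, dugong, SST, KD490,
  distance, latitude), a predictor is dropped when |Pearson r| > 0.8
  against any already-retained predictor (latitude, tied to SST at
  r ≈ 0.96, is the designed casualty). Correlations are computed on
  transformed predictors over the species' own sites; the binary dugong
  factor enters 0/1-coded (point-biserial). Constant predictors are
  dropped with a warning — their correlation is undefined.
* **Candidate set**: null, all singles, all pairs with |r| ≤ 0.28, and —
  when enabled — factor + smooth-by-factor variants for admissible
  factor/continuous pairs. Models never exceed two predictors.
* **Fit**: ordinary least squares on a spline design built with patsy:
  each continuous predictor as a cubic B-spline with basis dimension 4
  (three basis columns plus the shared intercept), factors dummy-coded,
  by-factor smooths as per-level spline blocks. The basis is deliberately
  small and unpenalized: with 14–16 sites a smoothing penalty is not
  estimable in any stable way, a 4-dimensional basis is the most such a
  design supports, and an unpenalized fit gives an exact parameter count
  for AICc rather than an estimated effective df. k = mean parameters +
  1 (residual scale). A model whose sample size cannot support its basis
  is refused outright (never silently shrunk); in the full-subset sweep a
  refused or unidentifiable model (e.g. a by-factor smooth with a
  near-empty factor level) is skipped with a warning.
* **Random effects**: sites come in location pairs, and an optional
  location random intercept (ML, not REML, so likelihoods are comparable
  across mean structures) is available behind
  `DriverConfig(location_random_intercept=True)`. The default is the
  fixed-effects fit: with ≤ 16 sites in ≤ 9 locations a variance
  component is fragile, and the selection arithmetic — the reproducible
  part — is identical either way.
* **Ranking**: AICc = −2 logL + 2k + 2k(k+1)/(n−k−1); ΔAICc against the
  best; Akaike weights normalized over the fitted set; candidate set
  Δ ≤ 2; the selected model has the fewest predictors in the candidate
  set, ties broken by lower AICc then label — fully deterministic.
* **Importance**: Σ of weights over models containing the predictor,
  with a by-factor term crediting both participants. Computed from
  whatever weight column the table carries, so the same arithmetic runs
  on this package's fits and on published tables.

Published AICc values are not bit-reproducible even with the original
data — the original smoother, basis, and random structure are unknown —
so cross-checks against published tables exercise the selection and
importance arithmetic (exact) rather than refitting.

## Species and spatial comparisons

Kruskal–Wallis (tie-corrected) compares species medians; Mood's median
test is reported alongside as the distribution-level comparison, covering
both readings of a "test that the distribution varied". A fully tied
pooled sample returns H = 0, p = 1 rather than erroring. Pearson r with
two-sided p from the t distribution (n − 2 df) serves both the
latitude–richness and the between-species co-occurrence correlations;
latitude defaults to its absolute value (the study region lies wholly
south of the equator), switchable to signed.

## Synthetic data

The generators reproduce the *statistical structure* the analysis
assumes, not the biology:

* **Clonal populations**: genet centers uniform in a 50-m-diameter disc;
  50 sample points (dart-throwing, ≥ 2 m apart — infeasible packings
  raise an error naming the constraint) assigned to the nearest genet
  within a ramet-dispersion radius (default 25 m, i.e. full coverage;
  uncovered points are re-drawn); one HWE genotype per genet at
  independent loci (default panel: the seven-locus microsatellite allele
  counts 12, 2, 12, 7, 5, 7, 3); missing calls injected i.i.d. per
  call. No linkage, no somatic mutation, no allelic dropout — the
  simplest model under which the P_ID math being tested is exact. Truth
  (genet map, genotypes, coordinates) is always returned; tests never
  infer truth from the data.
* **Storms**: Poisson arrivals (default 2 yr⁻¹ over a 31-year horizon
  starting 1985), linear tracks at Rayleigh-distributed offsets, a
  radial vortex (linear ramp to 45 m s⁻¹ at a 30-km radius of maximum
  winds, power-law decay outside) that is explicitly *not* an
  operational cyclone wind model — only its hourly-winds interface
  matters; lognormal synoptic winds capped below gale force, so
  background seas alone never meet the 4 m criterion and a zero-storm
  climate yields exactly zero exposure.
* **Driver scenarios**: 16 sites over an 8° latitude span; SST linear in
  latitude plus small noise (corr ≥ 0.95, to exercise the prefilter);
  optional Gaussian-copula correlation between distance from shore and
  cyclone probability (e.g. 0.86); response = stored function of the
  transformed covariates + Gaussian noise (default SD 0.05), clipped to
  [0, 1]. The default response is a downward parabola in √cyclone with
  an interior peak — the simplest shape with "highest richness at
  intermediate disturbance".

Passing tests on these data show the estimators and the selection
arithmetic are correct under the stated assumptions; they do not show
robustness to linkage, scoring error, spatial clonal structure, or
non-Gaussian responses, none of which the generators emulate.

## Problem sizes and numerics

Simulation-based checks use 500 seeded populations (clone recovery and
P_ID collision rates), 10⁴ years of Poisson counts (exposure
probability), and 200 replicates per driver scenario — sizes at which
Monte-Carlo 3σ bands are decisively narrower than the effects being
checked while the full suite runs in well under a minute per module.
Weight sums are asserted to 1e-9, P_ID enumeration to 1e-12, and exact
rational results (R, ΔAICc) to machine precision. Degenerate inputs fail
loudly: one-sample richness, empty frequency tables, unsorted or
duplicated timestamps, constant vectors in correlations, and
under-supported spline bases are all explicit errors.
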