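# Methods

This note documents the models, conventions and numerical choices behind
chassiskit, in the order the pipeline runs them.

## Neutral-site discovery

A neutral site candidate is a maximal run of chromosome positions covered
by no annotated feature. Features are merged across strands and overlapping
or abutting intervals before complementing, because neutrality requires
the absence of annotation on *either* strand. Coordinates are 1-based
inclusive throughout (the GenBank convention, and the convention in which
the PCC 7002 site coordinates are published); the GFF3 reader keeps its
native 1-based coordinates and the GenBank reader converts Biopython's
0-based half-open locations. BED output converts back to 0-based half-open.

"Longer than 1 kb" is strict: a gap is reported only when
`end − start + 1 > min_len` (default 1000). The threshold is anti-monotone
by construction — raising it can only remove gaps.

The chromosome is treated as linear by default. A `--circular` flag joins
a run touching position 1 with a run touching the last position into one
origin-wrapping gap, represented with `start > end` and
`length = (chrom_len − start + 1) + end`; the three known PCC 7002 sites
are internal, so the default does not affect them.

Only `gene` features are considered by default, configurable via
`--feature-types`. Annotated pseudogenes carried as `gene` features are
deliberately kept: a locus annotated as a pseudogene can later prove
functional, so it is never offered as neutral ground.

Homology arms are placed immediately inside the gap boundaries (5′ arm
anchored at the gap start, 3′ arm at the gap end) so the integration
cassette replaces the middle of the gap and the flanking genes stay
untouched; placement fails when twice the arm length exceeds the gap. The
predicted integration tier reflects the empirical PCR-confirmation rates
by arm length in PCC 7002: below 250 bp transformation mostly fails
(`below_minimum`), 250–499 bp confirms in roughly a third of colonies
(`low`), 500–749 bp in about 60% (`moderate`), and ≥750 bp in the large
majority (`high`).

## Transformation efficiency

`efficiency = cfu × dilution / fmol × (n_positive / n_screened)`, with
`fmol = mass_µg × 10⁹ / (length_bp × 650)`. The average double-stranded DNA
weight of 650 g/mol per bp is the standard molecular-biology convention
and is configurable. Positive fractions are applied per plate (not pooled
across replicates) before averaging. Replicate aggregation is the
unweighted mean over biological replicates with the sample (n−1) SD.
Arm-length experiment summaries add simple monotonicity diagnostics: cell
means of efficiency should be non-decreasing in arm length and in
incubation time.

## Promoter characterization

Normalization divides each sample's undiluted signal
(fluorescence × dilution factor) by the wild-type undiluted signal linearly
interpolated at the same OD730. No extrapolation is ever performed: strain
samples outside the wild-type OD range are dropped with a warning, and grid
points outside the measured range are marked missing. Normalized values are
then interpolated onto the reference grid OD730 ∈ {0.4, 0.7, 1.0, 3.0,
5.0}; linear interpolation is exact for signals linear in OD, which makes
the noise-free synthetic round trip an identity.

Multiple wild-type replicates are pooled into one reference curve (mean
undiluted signal on the union of their OD supports restricted to the
overlap) before normalizing.

The regulatory class is decided on the OLS line fitted to the
replicate-mean gridded profile, evaluated at the grid endpoints: with
ρ = (f(5.0) − f(0.4))/f(0.4), ρ > +0.30 is stationary-phase, ρ < −0.30 is
linear-phase, otherwise constitutive. Operationalizing the ±30% rule on
the fitted line (rather than on raw endpoint measurements) makes the class
scale-invariant, robust to single-point noise, and reproducible; the
threshold is configurable.

Strength tiers cut the mean normalized fluorescence at 1.5 / 2 / 10 with a
significance gate (two-tailed equal-variance t test vs wild type,
α = 0.05, no multiple-testing correction). The 2 and 10 cuts separate the
empirically observed moderate (2–6-fold) and strong (>30-fold) groups of
the PCC 7002 library; since no library member falls between 6- and
30-fold, any cut in that interval partitions identically.

Which replicate sets enter the significance test is a genuinely open
design point; here the test compares per-replicate grid-mean normalized
fluorescence of the strain against wild-type replicates normalized to the
pooled wild-type curve. When both sides are exactly constant (noise-free
simulations) the t statistic is degenerate; unequal means are then treated
as infinitely separated (p = 0), equal means as p = 1.

Correlation against RNA-seq profiles is Pearson's product-moment r over
the shared non-missing grid points (at least 3 required; zero variance in
either vector yields a missing value). Replicates are averaged before
slope fitting and correlation.

## Diurnal qPCR

Technical replicates are averaged on the CT scale first (the stated order
of operations); no-template and no-RT control rows are excluded by gene
label. ΔCT = CT_target − CT_ref per condition, ΔΔCT = ΔCT_light −
ΔCT_dark, ratio = 2^−ΔΔCT per biological replicate. Amplification
efficiency is assumed exactly 2; no Pfaffl-style efficiency correction in
v1. Any constant plate offset added to all CT values of a replicate
cancels in ΔCT, which the simulation exercises explicitly.

Reported fold-changes use the signed convention (ratio ≥ 1 → +ratio,
ratio < 1 → −1/ratio), a lossless bijection on (0, ∞). Per-strain
aggregation takes the mean and SD of the per-replicate signed values;
significance is an equal-variance t test on the replicate ΔCT values,
light vs dark. When replicates straddle ratio 1, the signed mean can fall
inside (−1, 1), where the convention has no inverse; the aggregate ratio is
then taken as the mean itself (positive branch) rather than rejected.

The library-level summary counts strains above twofold, between 1.5- and
2-fold, and down-regulated, and averages expression *ratios* — negative
signed values are converted back via 1/|signed| before the mean. This
reciprocal-conversion convention is the one under which the 25-promoter
reference library's mean comes out at 1.31; averaging signed values
directly does not reproduce it.

## Synthetic-data generators

The generators emulate the study conditions so that the analysis stages
can be tested against planted truth:

* **Growth** is piecewise exponential-then-linear with continuity at the
  switch density — the qualitative shape of light-limited batch growth —
  with defaults od0 = 0.05, µ = 0.27 h⁻¹ (≈2.6 h doubling), switch at
  OD 0.3, and the measured wild-type linear rate 0.0334 OD730/h. The
  default 192 h course sampled every 48 h covers the OD 0.4–5.0 reference
  range; the late-culture plateau is not modeled, so the course is simply
  truncated once the range is covered.
* **Fluorescence** noise is multiplicative log-normal with unit mean
  (plate-reader error scales with signal); the default CV of 0.1 is a
  calibration choice — no noise magnitude is published for these
  measurements. The wild-type baseline is proportional to OD
  (1000 a.u./OD), and pattern shapes are linear in OD with a planted
  relative change of ±0.6 between the lowest and highest reference OD —
  comfortably past the ±0.30 classification boundary, as in the clearly
  regulated library members — rescaled so the grid-mean equals the planted
  strength. Signals above 20 000 a.u. are recorded diluted in decade
  steps, exercising the dilution-correction path. Because the noise-free
  normalized expectation is linear in OD, the analysis inverts it exactly.
* **qPCR** CT noise is additive Gaussian on the cycle scale (the
  cycle-domain convention), applied per technical replicate
  (default SD 0.2 cycles); a per-(replicate, condition) plate offset with
  SD 0.5 shifts target and reference together and must cancel downstream.
  Defaults: 3 technical replicates; biological replicates default to 3
  (the fluorescence protocol), with qPCR protocol emulation passing 2
  explicitly.
* **Annotations** tile the chromosome end to end except for the planted
  gaps and random inter-feature spacers ≤200 bp, far below any realistic
  detection threshold, so the planted gaps are provably the only large
  feature-free runs.
* **Transformation** draws colony counts Poisson with mean
  `efficiency × fmol / (dilution × frac_positive)` — the exact inverse of
  the efficiency estimator, making the estimator unbiased on simulated
  plates — and screening outcomes binomial.

Every generator call derives its own pseudo-random stream from
`(seed, call-site label)`, so fixed seeds give byte-identical outputs and
adding generators never perturbs existing fixtures.

What passing tests do and do not show: the generators reproduce the
*structure* of the real data (growth shape, saturation/dilution, replicate
layout, noise families) but not instrument-specific artifacts — detector
nonlinearity, pigment reabsorption of reporter emission, evaporative
drift, or qPCR efficiency below 2. Recovery results therefore validate the
analysis logic, not the instruments.

## Numerical choices

* Sample (n−1) SD throughout.
* Two-tailed t-test p values via the regularized incomplete beta function;
  agreement with a quadrature oracle to 1e−10 is asserted in tests.
* OLS by closed-form normal equations; Pearson r clamped to [−1, 1]
  against rounding.
* Degenerate inputs fail loudly (zero pooled variance, constant x in a
  fit, missing qPCR cells, arms exceeding gaps) rather than returning
  silent defaults, except where a principled value exists (identical
  constant samples → p = 1).
* CLI reports embed the package version and a config hash, but no
  wall-clock timestamp, so identical inputs and seed give byte-identical
  output trees.

## Known limitations

* The comparative-CT method assumes perfect doubling; primer efficiencies
  are not estimated.
* With the published qPCR replicate structure (2 biological × 3 technical)
  and 0.3-cycle technical noise, each replicate's ΔΔCT carries an SD of
  0.3·√(4/3) ≈ 0.35 cycles, so the median relative error of the recovered
  ratio is ≈11% — an irreducible noise floor of that design, reported
  as-is by the acceptance script.
* No background/blank subtraction beyond wild-type normalization and no
  spectral-overlap correction; strongly pigmented cultures can bias
  reporter quantification.
* The gap finder trusts the annotation: unannotated ORFs, sRNAs or
  regulatory elements inside a reported gap are not screened for.
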