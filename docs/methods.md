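# Methods

## The assay and its quantification

Each well of a 96-well plate holds a confluent endothelial monolayer onto
which 50,000 Calcein-labelled leukocyte-lineage cells are loaded. Wells are
read before washing and after the third wash; the primary phenotype is

    % input RFU = 100 · RFU(wash 3) / RFU(pre-wash),

the fraction of fluorescence (a proxy for cells) that stayed attached. A
second scale, % adherent cells, converts the post-wash read through a
four-parameter logistic (4PL) standard curve fitted to calibration wells of
known cell number,

    y(x) = d + (a − d) / (1 + (x/c)^b),

where `a` is the zero-cell asymptote (background RFU), `d` the saturation
asymptote, `c` the inflection point in cells/well and `b` the slope factor.
The curve is strictly monotone between its asymptotes, so inversion is the
closed form `x = c·((a−d)/(y−d) − 1)^(1/b)`; values on or beyond an
asymptote raise an error rather than extrapolate. Both scales are computed
whenever a curve is available; heritability defaults to % input RFU. The
fit is an ordinary least-squares `scipy.optimize.curve_fit` with a fixed
initialization (`a`,`d` from the RFU at the smallest/largest cell number,
`c` at the geometric midpoint of the cell range, `b` = 1) so that repeated
runs give identical parameters.

Plate-to-plate variation is handled by standardizing each sample's mean
adhesion to the positive control (a Trisomy 21 LCL, high adhesion via CD18
over-expression) on the same plate. A plate-wide gain multiplies sample and
control wells alike, so the standardized coefficient cancels it exactly —
this is property-tested, and a one-way ANOVA (`cross_plate_consistency`)
checks that a line's standardized values do not differ across plates.

## Assay quality control

Per-sample replicate precision is the coefficient of variation,
`CV = 100·s/mean` with the n−1 sample standard deviation (replicate counts
are small, typically 8). Control separation is the Z′-factor

    Z′ = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|,

under which Z′ = 0.5 corresponds exactly to a 12-σ band separation at equal
control sds (a unit test pins this equivalence). SNR defaults to
`(μ_pos − μ_neg)/σ_neg` with a pooled-sd variant available. The composite
Z′ pools control wells across plates; the pooled variance is the within-
plus between-plate sum of squares over the pooled within-plate df
Σ(nᵢ−1), so identical plates pool to themselves while shifted plate means
degrade the composite.

Default gates: Z′ ≥ 0.5 and **median** per-sample CV ≤ 10 %. The median is
deliberate: with 8 replicates the sample CV of a line whose true CV is
8.68 % exceeds 10 % about a quarter of the time, so a worst-case gate would
discard most plates of an assay operating exactly at its published
precision. The full per-sample CV distribution is reported so users can
gate differently. Plates failing their gates are excluded from
quantification; pairs that lose a member this way are dropped from the
heritability fit with a logged warning.

## Heritability model

MZ co-twins share all additive genetic variance; full siblings (treated as
dizygotic twins) share half on average. Intra-pair resemblance uses the
one-way random-effects ICC for exchangeable members,

    ICC = (MS_between − MS_within) / (MS_between + MS_within),

which is invariant to member order within pairs; the double-entry Pearson
correlation is available as an alternative estimator (the two agree to
O(1/n); the ANOVA form is the default because it is the operative
definition in classical twin analysis, e.g. the `twinan90` tradition).
Falconer's formula gives

    h² = 2 (r_MZ − r_SIB).

The raw value is reported even outside [0, 1] (with a flag); truncation is
opt-in, never silent.

**Permutation inference.** The default null pools all 2·N_MZ + 2·N_SIB
individual phenotypes and re-deals them into pseudo-pairs preserving the
group sizes; h² is recomputed per permutation and

    p = (1 + #{h²_null ≥ h²_obs}) / (1 + n_perm)

(add-one rule; p is never 0 and never claimed below 1/(n_perm+1)). An
alternative scheme permutes zygosity labels across intact pairs. Worth
knowing: at 23 pairs per group the pooled-re-dealing null of h² has sd
≈ 0.6, so even an observed h² of 0.7 yields p ≈ 0.1 under this scheme —
small empirical p-values at this sample size require either a different
randomization unit or a tighter null. The machinery is calibrated (type-I
error at α = 0.05 sits inside the binomial band under null data) but the
scheme choice materially changes power.

**Confounder screening.** Continuous covariates (age, transformation time)
are screened by Pearson correlation, binary ones (sex, growth class) by
two-sample t-test, multi-level ones (ethnicity) by one-way ANOVA;
unadjusted p-values are reported with a Bonferroni column. Group variance
equality uses the two-sided variance-ratio F-test (larger variance in the
numerator, one-tailed probability doubled and capped at 1); more than two
groups fall back to Bonferroni-adjusted pairwise tests, flagged as such.

## Synthetic study generator

Pair phenotypes follow the additive decomposition on the % input RFU scale:

    y = μ + σ (√h²·A + √c²·C + √(1−h²−c²)·E),

with A shared fully (MZ) or at correlation ½ (siblings), C shared within
every pair, E independent. Implied correlations are r_MZ = h²+c² and
r_SIB = h²/2+c², so Falconer's estimator targets h² by construction; this
identity and the estimator's unbiasedness (mean error < 0.02 at 2,000
pairs/group) are property-tested.

Defaults are the study conditions: 23 MZ + 23 sibling pairs, phenotype
mean 40.25 % and sd 10.37 %, replicate CV 8.68 %, positive/negative control
adhesion 35 %/5 % (a 7-fold dynamic range), 8 technical replicates per
line, 50,000 cells loaded per well. The generative h² = 0.6966 with
c² = 0.10; note the published correlations (0.60, 0.25) are jointly
incompatible with any non-negative shared-environment fraction
(c² = r_MZ − h² would be −0.10), so the generator matches the heritability
and a plausible c² rather than both correlations.

Plates hold 8 test samples × 8 wells plus 8 positive-control, 8
negative-control and 8 standard-curve wells (loads 625–80,000 cells/well,
2 % calibration noise); overflow paginates onto further plates. Controls
get the same 8-well replicate depth as samples because per-plate Z′
estimated from fewer control wells is noisy enough to fail gates routinely
at the assay's own operating point. Replicate noise is mean-one
multiplicative log-normal at the configured CV, applied to the post-wash
read only (the pre-wash read is noiseless), so the per-well % input RFU
carries exactly the configured CV; fluorescence noise scaling with signal
is the motivating assumption. An optional per-plate gain emulates batch
effects that standardization must cancel. Phenotypes are clipped to
(1, 99) % before plate simulation; the clip rate at defaults is far below
0.1 % (asserted), so the genetic signal is undistorted.

What the generator does **not** emulate: spatial plate artifacts (edge
effects, row/column drift), wash-step kinetics, background fluorescence
drift, EBV-transformation biology, or phenotype-covariate confounding
unless explicitly injected. Passing tests therefore demonstrate correctness
of the estimators and plumbing under the stated noise model, not robustness
to those real-data pathologies.

## Numerical and design choices

- The Z′ formula is the standard screening definition; it is the only form
  under which the 0.5 ⇔ 12 σ equivalence holds, which the tests pin down.
- CSV round-tripping is exact: floats are written with `%.17g` and read
  with pandas' `round_trip` parser, making write∘read the identity.
- Missing RFU cells are absent wells, never zeros; duplicate
  (plate, well, stage) rows are rejected at read time.
- Per-sample phenotype is the mean of technical replicates surviving QC;
  samples spanning plates average across plates.
- Degenerate inputs fail loudly and specifically: equal control means
  (Z′), zero replicate mean (CV), zero variance (ICC, permutations),
  curve asymptotes (inversion), a single plate (cross-plate ANOVA returns
  a flagged not-applicable result instead of a p-value).
- All randomness flows through seeded `numpy.random.Generator`s; a fixed
  seed makes `fit` results bit-identical and fixture files byte-identical.

## Problem sizes used in the shipped checks

The acceptance-style checks simulate 20 cohorts of 2,000 pairs per
zygosity group for recovery of the published heritability, 200 null
cohorts × 500 permutations for type-I-error calibration at the study's
23+23 size, and one full plate-level study (92 lines, 12 plates) for the
end-to-end fixture; the full suite runs in well under a minute. Recovery
tolerances are the estimators' own Monte-Carlo/sampling errors at those
sizes (e.g. 2 delta-method sds of ĥ² at ~23 pairs/group ≈ 0.73), not tuned
bands.

## Known limitations

- Falconer's formula assumes equal shared environment in MZ and sibling
  pairs and no dominance/epistasis; it is a method-of-moments estimate, not
  a variance-component ML fit (ACE/ADE modelling is out of scope).
- The permutation scheme choice is consequential at small n (see above).
- No spatial plate-effect correction; the cross-plate ANOVA and
  control standardization are the only batch-effect tools.
- Vendor-native plate-reader exports are not parsed; inputs are tidy CSV
  (an 8×12 matrix importer is provided as a convenience).
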