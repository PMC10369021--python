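# Methods

`eggsig` quantifies how well a brood parasite's eggs mimic its host's eggs,
how hosts exploit residual mismatches to reject foreign eggs, and what that
implies for the parasite's reproductive output. The package is organized
around the analysis chain of a host-parasite system in which both species
lay polymorphic eggs and each female lays one consistent egg type for life
(an individual "signature").

## Colour model (`eggsig.vision`)

Ground-colour reflectance spectra R(λ) on 300–700 nm are converted to
quantum catches

    Q_c = ∫ R(λ) I(λ) S_c(λ) dλ

for four single cones (UV/violet-, short-, medium-, long-wavelength
sensitive) and the double cone (luminance channel), by trapezoidal
integration on the receptor grid after linear interpolation. With von-Kries
normalization (the default) catches are divided by those of a perfect white
under the same illuminant, so illumination intensity cancels.

Colour differences use the receptor-noise-limited (RNL) model on log
signals Δf_c = ln(Q_ac/Q_bc):

    ΔS² = Σ_{i<j} (Π_{k≠i,j} e_k)² (Δf_i − Δf_j)² / Σ_i (Π_{k≠i} e_k)²

which reduces to the standard di-/tri-/tetrachromatic closed forms. Noise
per channel is e_i = w·√(n_max/n_i) with Weber fraction w = 0.1 anchored on
the most abundant cone and relative densities 1:2:2:4 (UV:SW:MW:LW). The
achromatic contrast is |ln(Q_a,dbl/Q_b,dbl)|/w_A with w_A = 0.34. Contrasts
are in just-noticeable differences (JND); values below 1 mean the receiver
is predicted not to distinguish the stimuli. All noise parameters are
constructor arguments of `ReceptorSet`.

Because measured receptor curves for the modelled viewer are not bundled,
the default `ReceptorSet` is built from the standard A1 visual-pigment
template (alpha plus beta band) with peak wavelengths (432, 477, 537, 605)
nm for the single cones and 567 nm for the double cone — a violet-sensitive
tetrachromat of the peafowl type. The default illuminant is a smooth
standard-daylight stand-in: a 6504 K black-body photon spectrum (the
correlated colour temperature of standard daylight). Both are swappable via
CSV-backed `ReceptorSet`/`Illuminant` objects; no quantity computed here
depends delicately on either choice, since host and parasite spectra are
evaluated under the same receiver.

Population colour centroids are arithmetic means in Cartesian tetrahedral
chromaticity coordinates (regular tetrahedron with the achromatic point at
the origin), mapped back to relative catches; because the map is affine
this equals the mean of relative catches, and the implementation is tested
against that brute-force mean.

## Pattern metrics (`eggsig.pattern`)

Images are calibrated grayscale photographs at 19 px/mm with an egg mask.

- **Adaptive thresholding.** A pixel is "pattern" iff its value is below
  the local mask-aware mean (3 mm square window, default offset 0.05).
  Only dark-on-light maculation is detected, appropriate for dark markings
  on a pale ground. *Proportion pattern* is the patterned fraction of the
  egg; *dispersion* is coverage in the blunt-pole third (equal-area thirds
  of mask pixels along the major axis) divided by overall coverage — 1 for
  uniform markings, 3 when all markings sit in the blunt third, undefined
  (NaN) for immaculate eggs.
- **Granularity.** The mean-padded image is decomposed into 7 octave-spaced
  Fourier bandpass annuli covering marking sizes 0.25–16 mm. Band energy is
  the variance of the band-filtered pixels inside the mask. Summaries:
  total energy (Σ bands), SD energy (spread across bands), contrast (peak
  band energy) and contrast variability (SD of the summed bandpassed
  image). Energies scale with the square of image contrast, and a
  sinusoidal grating peaks in the band containing its period (both tested).
- **Feature detection.** Markings are counted as Laplacian-of-Gaussian
  extrema of the inverted image (multi-scale blob detection, radii 0.15–3
  mm, threshold 0.05). Mean feature size (π r² in mm²) is NaN for
  immaculate eggs, where it is meaningless.

At the population level two correlation-matrix PC1 composites are fitted:
*pattern coverage* from (proportion pattern, dispersion), signed to
increase with coverage, and *PC energy* from (contrast, contrast
variability), signed to increase with contrast. Standardization statistics
are retained for out-of-sample scoring.

The **multidimensional pattern distance** between two eggs is the Euclidean
distance in the 5-D space (proportion pattern, dispersion, total energy,
SD energy, feature number) — the traits defined for immaculate and
patterned eggs alike. Traits are z-scored against the pooled population
under analysis so no trait dominates through its units; a raw-units mode
exists for sensitivity analysis. Immaculate eggs get dispersion imputed as
1 (uniform), keeping them inside the space.

## Mimicry statistics (`eggsig.fidelity`)

Per-trait host/parasite comparisons use two-sided Wilcoxon rank-sum tests
(exact enumeration when n₁·n₂ ≤ 400 and tie-free, tie-corrected normal
approximation otherwise). Signature strength is the one-way ANOVA
intraclass correlation ICC = (MSB − MSW)/(MSB + (k₀ − 1)MSW) with the usual
unbalanced-design k₀, plus its F test. Overall fidelity is measured by
jack-knifed (leave-one-out) linear discriminant analysis with equal priors
and pooled covariance — perfect mimicry leaves the classifier at chance —
preceded optionally by a Mahalanobis outlier filter (χ² quantile 0.999 at
the feature dimensionality; removals are recorded and reversible) and a
greedy collinearity screen (drop the highest-mean-|r| trait while any
pairwise |r| ≥ 0.7, ties alphabetical). Whether the confusion matrix beats
chance is assessed by Fisher's exact test (conditional-MLE odds ratio).
The LDA is hand-implemented (equal-prior LOO with pooled covariance) and
cross-checked in the tests against both a brute-force LOO oracle and
scikit-learn's discriminant direction. A seeded k-means labelling of eggs
into k = 4 phenotype clusters is provided as a convenience only.

## Rejection models (`eggsig.rejection`)

Rejection of a foreign egg (0 = accepted, 1 = rejected) is modelled with
logit-link binomial GLMs (IRLS, tolerance 1e-10):

- *Model 1 (traits):* absolute host−foreign differences in pattern
  coverage, PC energy and feature number. Absolute differences are the
  default (rejection should respond to mismatch magnitude); signed
  differences are a flag.
- *Model 2 (distance):* the single 5-D pattern distance.
- Variants: `plus_colour` appends the chromatic JND between host and
  foreign egg; `interactions` adds all two-way products of the model-1
  terms.

Models are compared by AIC and, when nested, likelihood-ratio tests.
Explanatory power is an adjusted deviance-explained R²,
1 − (1 − (1 − D/D₀))·(n−1)/(n−k), with McFadden's pseudo-R² reported
alongside as a labelled alternative. Multicollinearity is checked with
VIF_j = 1/(1 − R²_j). Variance explained is partitioned between predictors
by hierarchical partitioning: all 2^k subsets are fitted (k ≤ 8) and each
predictor's independent contribution is the level-averaged gain in deviance
explained, normalized to percentages (%I) summing to 100. Perfect
separation is detected (diverging coefficients / non-finite standard
errors) and raised as an explicit error rather than returning unstable
estimates.

## Parasitism simulation (`eggsig.simulate`)

Each of n iterations (default 1000) draws, with replacement, one host egg
and one parasite egg — one egg per female, since a female's eggs are not
independent phenotypes — computes their pattern distance, and predicts
p(reject) from the fitted distance model. `bernoulli` mode (default) draws
an outcome per iteration and reports the rejection fraction with a
Clopper–Pearson 95% interval; `expected` mode averages the probabilities
(normal-approximation interval). The two agree in mean over seeds (tested
at 3 Monte-Carlo SEs).

The **monomorphic counterfactual** collapses each species to its centroid
in the standardized 5-D pattern space and evaluates the fitted model at the
centroid-to-centroid distance: the rejection rate that would remain if all
between-female signature variation vanished. The gap between the simulated
polymorphic rate and this counterfactual is the contribution of signatures.

The **fecundity projection** is plain arithmetic: accepted eggs/yr =
eggs/yr × (1 − rejection rate); fledglings/yr = accepted × nest survival;
lifetime fledglings = fledglings/yr × lifespan (8 years used as the
conservative bound of an 8–9-year span); a comparator species' output is
eggs/yr × its laying-to-fledging success. Values are kept at full precision
with 2-significant-figure display strings.

## Synthetic data (`eggsig.synthdata`)

The generator emulates the statistical structure the analyses assume, so
the whole chain is testable without field data:

- Four soft morphs (immaculate, speckled, blotched, erythristic) with
  weights (0.30, 0.30, 0.25, 0.15) shared by both species — overlapping
  distributions, i.e. near-perfect population-level mimicry.
- Traits are latent-Gaussian: morph mean + female effect (SD
  `between_female_sd`) + egg effect (SD `within_female_sd`), transformed to
  their domain (logistic for proportions, exp for positive quantities,
  floored rounding for counts). Defaults put between-female SD at roughly
  three times within-female SD, giving ICC ≈ 0.9 for every trait — the
  strong-signature regime (> 0.69) the analyses require.
- Ground colour is a smooth sigmoid spectrum per female (morph-specific
  parameters, jittered per female), with an elevated long-wavelength
  shoulder for erythristic morphs and a small UV shoulder that is higher in
  hosts than parasites. Cone catches in the phenotype table are computed
  through the vision module.
- Egg images are pale ellipses (inscribed in the frame; blunt pole at +x)
  with dark discs; spot placement density can ramp linearly toward the
  blunt pole (`pole_bias`), and a non-overlap mode supports geometric
  round-trip tests.
- Experiments pair a host clutch with a conspecific egg from another
  female; outcomes are Bernoulli draws from logistic(β₀ + β₁·D) on the
  pattern distance. The default "biased" pairing picks the closest of 8
  random candidates, emulating giving hosts difficult decisions; "random"
  pairing emulates natural parasitism. The default true coefficients
  (β₀, β₁) = (−2.0, 2.5) were chosen once so the generated study conditions
  sit in the reported field regime: ≈ 0.92 rejection under random pairing,
  ≈ 0.7 under biased pairing, and a counterfactual rejection near 0.3.

All generators are pure functions of config + seed; child streams are
spawned from the root seed in the fixed order (morph, female, egg, colour,
experiment).

What the generator does **not** emulate: real spectral shapes and cone-catch
distributions (only their within/between-female structure), spatial
autocorrelation of markings beyond disc geometry, shared environmental
effects across clutches, observation error in field scoring, and any
difference between species beyond the UV shoulder and morph-frequency
choices. Passing tests therefore demonstrate that the *machinery* recovers
known structure, not that the field system has that structure.

## Numerical choices and problem sizes

- Integration: trapezoid on the receptor grid after linear interpolation;
  grids outside the data range are an error, not an extrapolation.
- JND forms require strictly positive catches (log signals); zero catches
  raise.
- The 2×2 correlation-matrix PCA uses the analytic PC1 (1, sign r)/√2,
  extended by continuity at r = 0.
- Exact branches: Wilcoxon exact for n₁·n₂ ≤ 400 without ties; Fisher's
  exact always on 2×2 tables.
- Default analysis sizes: populations of 60 host + 25 parasite females × 3
  eggs; 114 experiments; 1000 simulation iterations; the replication counts
  in the test suite (50 simulation replicates, 200 recovery replicates, 500
  calibration replicates) were chosen as the smallest sizes at which the
  binomial/KS tolerances used are meaningful.

## Known limitations

- The built-in receptor set and daylight illuminant are template-based
  stand-ins; exact replication of a specific toolbox requires supplying its
  curves.
- Dispersion is defined as the blunt-third coverage ratio; an alternative
  (regression of coverage along the axis) would weight gradients
  differently.
- The z-scoring population for the 5-D distance (pooled by default) is the
  most consequential free choice in the chain; both modes are exposed and
  reports record which was used.
- Hierarchical partitioning is exponential in predictors (capped at 8).
- No random-effects (per-female) rejection models; experiments are treated
  as independent.
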