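# Methods

## The inverse problem

Leaf reflectance between 401 and 1000 nm responds to nitrogen mainly
through chlorophyll: higher N darkens the visible region (stronger
absorption around the 555 nm green peak and the red trough) and shifts
the red edge toward longer wavelengths.  `leafndiff` estimates a leaf's
nitrogen *deficiency* — its N content minus the mean N content of a
max-yield reference ("standard") field — from the difference between
its spectrum and the standard field's mean spectrum.  Differencing
against a biologically meaningful reference removes the common leaf
profile and centres the regression problem on deviations that matter
agronomically: ΔN < 0 marks under-fertilization relative to the
best-yielding management.

All stages operate on a fixed grid of 600 bands at 1 nm from 401 to
1000 nm.  Interval k (1-based) of the 20-band tiling spans
401+20(k−1) … 400+20k nm, so interval 5 is 481–500 nm and interval 16
is 701–720 nm.

## Synthetic campaigns

Because no public data release exists, every analysis here runs on
synthetic campaigns from `simulate.generate_samples`.  The generator
emulates:

- **Design**: treatments 0/50/100/150 kg N/ha, 4 plots per treatment,
  16 leaves per plot (256 samples; the original campaign had 259).
- **Leaf N**: per-treatment normal draws with means 1.8/2.6/3.3/3.8
  mg/g and sd 0.45, clipped to [1, 5] mg/g.  Only pooled moments are
  reported for the real data (mean ≈ 2.90, sd ≈ 0.93, range
  1.06–4.87); the treatment means were chosen so the pooled mean
  matches while treatment ordering N0 < N1 < N2 ≤ N3 holds.
- **Spectra**: a stylized Gaussian-feature leaf curve — visible base
  0.07 with a green peak at 555 nm whose height falls as chlorophyll
  rises, a sigmoid red edge near 710–722 nm shifting up with
  chlorophyll, and a NIR plateau near 0.50.  The chlorophyll driver is
  a saturating (Michaelis–Menten, K = 2 mg/g) function of an
  *effective* N that decouples from true leaf N with a 15 % coefficient
  of variation, the loose chlorophyll–nitrogen coupling of field
  leaves.  Measured curves are further distorted by a per-leaf
  multiplicative scatter factor (sd 5 %; the leaf-clip repositioning
  variability that motivates MSC/SNV correction in spectroscopy), a NIR
  plateau offset (sd 2 %) and i.i.d. band noise (sd `noise_sd`, default
  0.01 reflectance units).  All stochastic spectrum components scale
  with `noise_sd`, so `noise_sd = 0` makes reflectance an exact
  function of leaf N.  With defaults, pipeline validation R² lands in
  the 0.6–0.86 range, the regime reported for real leaves.
- **Yields**: a deterministic quadratic in applied N with vertex at
  95 kg/ha calibrated to the observed extremes, so over the treatment
  grid yield(100) > yield(50) > yield(150) > yield(0) and the standard
  field is the 100 kg/ha treatment by construction.

What the generator does **not** emulate: radiative transfer (no
PROSPECT-style leaf optics), water/dry-matter absorption features,
growth-stage structure, plot random effects (no within- vs
between-plot variance decomposition is available to calibrate one),
and high-variance N-irrelevant spectral structure such as water-band
variability.  Consequences for interpreting results are noted below.

Two auxiliary benchmarks support model testing.
`make_nonlinear_problem` emulates *reduced* features: one latent
driver loads on all 10 features (the first three most strongly) and the
response is exponential in the mean of those three, plus noise of sd
0.2 mg/g — a low-effective-dimension, exponential-response regime in
which nonlinear regressors hold a genuine edge over linear ones, as
reported for the real data.  `make_planted_problem` plants
independent unit-variance signal in chosen bands over a lower-variance
background, giving wavelength-selection power studies a well-defined
notion of exact recovery.

## Differencing and splitting

The standard treatment is the strict arg-max of the yield table (a tie
raises).  The reference spectrum and N content are arithmetic means
over the standard-treatment samples.  Differences are **signed** and
standard-treatment samples are excluded from modelling, since their
differences cluster at zero.  One overall reference is used rather
than one per growth stage; users pooling multiple stages should be
aware the reference then mixes stages.  The train/validation split is
random uniform without stratification, size round(n·fraction); the
default fraction 0.73 reproduces a 189/70 split at n = 259.

## Wavelet reduction (DWMD)

The decimated DWT with half-point symmetric boundary extension is
applied recursively to the approximation branch; per level the
approximation length follows a_j = ⌊(a_{j−1} + L − 1)/2⌋ with L the
filter length (20/30/16 taps for db10/coif5/sym8).  This convention
reproduces the reference coefficient-count table exactly from n = 600.
Two numerical caveats:

- The recursion has a fixed point at L − 1, so the approximation never
  shrinks below that; "too deep" decompositions are well-defined and
  simply stop compressing.
- Symmetric extension is redundant, so Parseval does not hold across
  the transform; energy conservation of the orthonormal filter bank is
  a property of the periodized convention (`mode="periodization"`),
  and is only exact while lengths halve evenly (600 → 300 → 150 → 75,
  i.e. three levels).

Family/depth selection: each family is represented by its first
*stabilized* level (approximation count unchanged from the previous
level, or level ≥ 10 — compression has converged); among families the
lowest stabilized count wins, with ties broken by the highest
correlation between the mean training difference spectrum and its
approximation-only reconstruction.  On simulated campaigns this selects
sym8 at level 10 (15 coefficients).  The correlation is computed on the
mean training spectrum because the choice must be deterministic and
the per-sample curves only add noise around the same profile.

## Band selection

**SPA.**  Stage 1 builds a forward chain from every candidate start
band (the start band is not identifiable a priori): each step projects
all unselected columns orthogonally to the last selected one and picks
the largest projected norm.  Stage 2 scores each (start, N) candidate
subset by 10-fold cross-validated OLS RMSE and keeps the minimizer;
stage 3 backward-eliminates bands whose removal does not worsen RMSECV
by more than 1 % (relative) — the elimination criterion is a package
choice, as is scanning every start band.  The projection counter
verifies the closed-form operation count (N−1)(J−N/2).

**PCA.**  Five components by default, fitted on the training split;
held-out samples are projected with training loadings and means to
avoid leakage.

**IRIV.**  The synergy-interval pre-screen enumerates all 4-subsets of
the 30 intervals exhaustively (27,405 combinations) with a shared
seeded 10-fold partition; the PLS1 inner loop runs on per-fold
precomputed cross-product (Gram) matrices, which makes the enumeration
a ~half-minute operation; its SIMPLS solution is verified against the
standard NIPALS implementation in the test suite (identical for a
single response).  IRIV rounds then use a 50-row random inclusion
matrix (inclusion probability 0.5) over the surviving bands; each row
is scored by 5-fold PLS RMSECV, and each band is classified by the mean
RMSECV difference of rows excluding vs including it (positive =
informative) with a two-sided Mann–Whitney U test at α = 0.05
separating "strong" from "weak" informative (and "interfering" from
"uninformative" among the dropped).  Rounds iterate to stability or 5
rounds, then one backward-elimination pass removes bands whose removal
improves RMSECV.  Matrix size, inclusion probability, the two-sided
test and the iterate-then-eliminate order are package choices; the
method source describes the procedure without fixing them.  Finally,
mutually correlated survivors (|r| > 0.9, transitive grouping) collapse
to the member most correlated with ΔN.

## Inverse models

**PLSR** uses the NIPALS implementation of scikit-learn; the latent
dimension is chosen by 10-fold CV RMSE over 1..min(15, rank).

**ELM**: hidden activations g(Wᵀx̃ + b) with logistic sigmoid g, x̃
standardized by training mean/sd (random [−1, 1] weights on raw feature
scales would saturate the sigmoids), W, b ~ U(−1, 1); output weights
(plus intercept) by `lstsq`, with a ridge fallback (ε = 1e−8) for a
degenerate hidden matrix.  Default s₂ = 20 hidden nodes — no value is
documented for the reference study ("determined by repeated tests"), and
20 keeps the output solve well-conditioned at n ≈ 140–190 training
samples.

**GA-ELM**: genome of length l = s₁s₂ + s₂s₃ + s₂ + s₃ holding input
weights, output weights, hidden biases and output bias in that order
(the output block is carried for the stated genome length but re-solved
by least squares at every evaluation, since the closed-form solution is
always at least as good).  Population 30, generations 100, elitism 1,
k_c = k_m = 0.5; fitness 1/(1 + training RMSE); breeding restricted to
the above-average-fitness subpopulation with fitness-proportional
selection; arithmetic crossover and sparse Gaussian mutation (per-gene
probability 0.1, sd 0.1) gated by the adaptive rates.  A converged
population can make mean fitness exceed max fitness by an ulp; the
adaptive-rate function treats that as the degenerate uniform case
(rate 0) rather than an error.  Population size, generation count,
elitism and the mutation kernel are package choices.  Fitness on
training RMSE means the GA can overfit small noisy training sets; this
is retained deliberately (a holdout-fitness variant was evaluated
during design and offered no consistent advantage on the benchmarks
here).

## Experiment grid

`run_grid` derives one seed per stage from a master seed
(`numpy.random.SeedSequence`), simulates one campaign, builds one
reference/split, computes each requested reduction once (so every model
in a row consumes byte-identical features) and fits each requested
model.  Cell failures are recorded in the report and do not abort the
run.  Configuration can come from a YAML file
(`evaluation.load_config`) with sections `simulate` / `difference` /
`reduce` / `model`.

## What passing tests do and do not show

The acceptance-style tests verify: the exact coefficient-count and
compression-ratio table; the max-yield selection on the published
yield figures; the SPA operation-count formula; the GA algebra; the
recovery of planted bands by SPA and IRIV (≥ 90 % over 20 seeds, ≤
20 % noise-band retention); validation R² ≥ 0.5 for all three models on
the nonlinear benchmark; and the accuracy ordering GA-ELM ≥ ELM ≥ PLSR
(median over 11 seeds) on that benchmark.

One documented property does **not** hold on the synthetic campaigns:
the wavelet reduction is *not* more accurate than PCA as GA-ELM input
(median validation R² ≈ 0.64 vs ≈ 0.76 over 11 seeds).  In the
stylized generator the N-driven modulation is the dominant variance of
the difference spectra, so five unsupervised principal components
retain the full signal in fewer, better-conditioned features.  The
reported weakness of PCA on real leaves plausibly reflects
high-variance N-irrelevant spectral structure (water bands, stage
effects, pigment composition) that the generator deliberately does not
model; the corresponding test is left failing as an honest record of
this limitation rather than weakened.

Problem sizes throughout (256-sample campaigns, 20-seed power studies,
11-seed ordering studies, 5-fold/10-fold CV) were chosen so the whole
suite runs in minutes on one CPU while keeping the statistical checks
stable across seeds.
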