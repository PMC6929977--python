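# Methods

## The measurement model

A PCR amplicon of length `L` base pairs with `n_CpG` CpG dinucleotides on
its top strand is bisulfite-converted and amplified. Conversion is
modelled on the top strand only: methylation-independent primers select
one converted strand, and the duplex product's CG base-pair count equals
the C+G count of that converted strand. Every non-CpG cytosine converts;
a CpG cytosine survives iff its site is methylated. Population-level
partial methylation is modelled linearly — a level `m` scales the expected
number of retained CpG cytosines — because SERS measures bulk base-pair
composition, not per-molecule patterns; hemimethylation and per-molecule
pattern enumeration are deliberately out of scope. This yields the exact
affine calibration

```
f(m) = (N0 + m · n_CpG) / L
```

with `N0` the C:G count of the fully unmethylated converted duplex. The
three study genes are instantiated from their published constants
(`L`, `n_CpG`, one percentage endpoint printed to two decimals): `N0` is
recovered by rounding `f·L` to the nearest integer, with a 0.05 bp
tolerance reflecting two-decimal printing. Levels recovered from spectra
are *not* clipped to [0, 1]: negative estimates are legitimate noise
outcomes below the `f0` intercept, and the downstream state call
(`methylated iff m ≥ 0.05`) handles them explicitly.

## Deconvolution

The preprocessed product spectrum is regressed over every grid point onto
the preprocessed dsCG and dsAT reference spectra (ordinary least squares,
two regressors, intercept off by default since baseline correction
precedes the fit; an intercept flag exists for robustness checks).
Coefficients are unconstrained — negative coefficients, like negative
levels, are informative failures rather than errors. The composition
estimate is the renormalized ratio `c_CG / (c_CG + c_AT)`, the only
reading invariant to the target spectrum's overall intensity scale.

Two numerical guards: the reference design matrix's condition number must
stay below 1e8 (near-collinear references abort with a conditioning
error), and a non-positive coefficient sum aborts the fraction conversion
(non-physical fit).

**Reference-pair scale.** The renormalized ratio is *not* invariant to
rescaling one reference against the other. The references are prepared
equimolar precisely so that their relative per-unit-composition response
is pinned; the pipeline must preserve it. `build_reference_set` therefore
smooths and baseline-corrects each replicate measurement, averages
replicates per kind, and normalizes the averaged pair **jointly** (one
common maximum). Normalizing each reference to its own maximum would
rescale one component against the other and bias every downstream level
estimate by several tenths — the single most consequential design
constraint in the pipeline. For the same reason the simulated reference
acquisition carries no per-spectrum lognormal scale factor: the pair is
measured back-to-back on one substrate batch, so the scale variability
that affects independent sample measurements does not scramble the pair's
relative scale.

Replicates of a sample are combined by averaging the per-replicate levels
(three measurements per assay by default, matching the emulated
acquisition protocol); for this linear pipeline that is equivalent to
averaging spectra first and simpler to log.

## Preprocessing

Order: Savitzky–Golay smoothing, AsLS baseline subtraction, normalization;
each step independently switchable, the grid never altered. The
acquisition protocol names the steps but no methods or parameters, so all
choices here are this package's own and configurable:

- **Smoothing** — Savitzky–Golay, window 11 points, order 3: standard for
  ~1 cm⁻¹ Raman grids, testably preserves polynomials up to its order.
- **Baseline** — asymmetric least squares (Whittaker smoother with
  asymmetry `p = 0.01`, 10 reweighting iterations), stiffness
  `λ = 1e10`. The stiff default is deliberate and was chosen on two
  noise-independent criteria evaluated on noiseless synthetic spectra:
  (i) distortion of baseline-free signal — softer baselines (λ ≤ 1e6)
  creep into the Lorentzian tail pedestal and change assigned-band
  prominences by 5–8%, and bias verification estimates by ~2 percentage
  points, whereas at 1e10 prominence changes stay below 1%; (ii) drift
  capture — the second-difference penalty does not constrain linear
  baselines at all and barely constrains gentle quadratics, so even at
  1e10 a low-order drift of 5% of peak height is removed to ~0.5% of peak
  height. Note the baseline legitimately removes part of the Lorentzian
  tail pedestal; accordingly, invariance of *band prominence* (height
  above local background), not of raw at-center intensity, is the
  meaningful stability criterion and the one the tests enforce.
- **Normalization** — divide by the maximum in the analysis window
  (unit-area selectable). For targets the convention is immaterial (the
  coefficient ratio is scale-invariant); for references see above.
- **Analysis grid** — 600–1700 cm⁻¹ at 1 cm⁻¹, covering all assigned
  bands (644–1636 cm⁻¹).

## The synthetic instrument

`synthetic` stands in for the Raman spectrometer. Signal: a sum of
Lorentzian bands (the standard Raman line shape), FWHM 12 cm⁻¹, at the
assigned dsCG/dsAT band positions; three bands are CG-only (644, 1354,
1550 cm⁻¹), four AT-only (684, 734, 1336, 1575 cm⁻¹), the rest shared.
The 1024 and 1098 cm⁻¹ bands are treated as shared backbone/phosphate
modes. Band heights are plausible relative intensities, not measured
values; in reference-based deconvolution they cancel, and they remain
configurable for robustness studies. A product spectrum at CG fraction
`f` is exactly `f·S_CG + (1−f)·S_AT` before corruption — composition
linearity is the physical premise of the whole method.

Corruption models the dominant SERS variability modes with three
parameters (defaults): per-spectrum lognormal intensity scale
(σ = 0.05; substrate batch, focus), non-negative random quadratic
baseline (amplitude 0.05 of max peak; fluorescence/background), additive
white Gaussian noise (σ = 0.01 of max peak; shot/CCD). Every stochastic
operation is a pure function of (inputs, seed).

What the generator does **not** emulate: wavenumber miscalibration,
cosmic-ray spikes, peak-position shifts from adsorption conformation,
substrate-dependent band-shape changes, inter-batch substrate
irreproducibility. Passing tests therefore demonstrate the correctness
and noise-robustness of the *computational* chain under a credible
instrument model, not the wet-lab performance of the assay on real
plasma.

The verification design mirrors the assay's validation: 3 genes × levels
{0, 1, 5, 25, 50, 75, 100}% × 3 replicates (63 spectra), references
characterized from 3 replicate measurements.

## Simulated cohorts

The cohort generator emulates a 48-cancer / 51-control case/control
study. Clinical covariates are drawn from the study's marginal
frequencies (gender, age band, smoking pack-years band; stage and
histology cancer-only). Per-gene true levels follow a zero-inflated
distribution: with probability `p_methylated` a truncated normal on
[0.05, 1] (mean 0.15, sd 0.10), otherwise a near-zero background normal
(mean 0.005, sd 0.015, negatives allowed, truncated below 0.05).
Defaults `p_methylated = 0.50` (cancer) and `0.041` (control) are chosen
so that, under independence across the three genes, the any-gene
methylation design targets are 87.5% and 11.8% and group mean levels
differ by roughly 5 percentage points — design targets the tests check
within binomial sampling bands, not validation claims about real cohorts.
Association effects mirror the reported clinical correlations: p16 level
means shift upward with smoking band (+0.05 per band) and with
squamous/large-cell histology (+0.05); RASSF1 methylation probability is
redistributed between stage bands (odds 1.3 for III–IV, I–II compensated
so the gene's marginal — and hence the any-gene target — is unchanged).

## Evaluation statistics

- **Bland–Altman**: differences estimate − truth; limits
  `mean ± 1.96·sd` (sample sd, ddof 1).
- **ROC / Youden**: thresholds are midpoints between sorted distinct
  scores plus ∓∞ sentinels; positive call at `score ≥ threshold`; the
  optimum maximizes `J = sens + spec − 1` with ties broken toward the
  lower threshold (higher sensitivity); AUC by trapezoid along the
  threshold-descending staircase. Accuracy is unweighted (the emulated
  groups are near-balanced).
- **CART**: greedy binary splits minimizing weighted Gini impurity;
  candidate thresholds are midpoints of sorted distinct values; growth
  stops at pure nodes, `max_depth` (default 3), or children below
  `min_leaf` (default 5); split ties resolve by feature order then lower
  threshold; leaf ties by overall-majority class then lexicographic. A
  split is taken even at zero impurity gain (required to solve
  XOR-structured data). Reported tree performance is apparent
  (training-set) performance and labelled as such.
- **Fisher's exact test**, r×c: full depth-first enumeration of
  margin-fixed tables with pruning; two-sided p is the total null
  probability of tables whose point probability is ≤ the observed one
  (1e-12 relative slack for floating-point ties) — the standard exact
  definition, reducing to the textbook 2×2 rule. Capacity guards (total
  ≤ 200, cells ≤ 12) signal the caller to bin categories first.
- **Cohort report**: per-group/per-gene summaries, any-gene fractions,
  per-gene ROC on levels, CART on levels and on states, and Fisher tests
  of each gene against each clinical feature within the cancer group —
  computed twice per feature, once on states (5% threshold) and once on
  tertile-binned levels, both labelled explicitly since both readings of
  "levels vs clinical features" are defensible.

## Problem sizes

Defaults throughout are the emulated study's own sizes: 63-spectrum
verification sets, 99-subject cohorts, 1101-point spectra. The complete
test suite and the acceptance computation run in well under a minute.

## Known limitations

- Single-gene spectra only; multiplexed unmixing of several genes from
  one spectrum is out of scope.
- 5mC and 5hmC are indistinguishable to bisulfite chemistry; "methylation
  level" aggregates both.
- The calibration assumes complete bisulfite conversion and no primer
  bias; conversion-efficiency error models are not included.
- Clinical-scale diagnostic numbers (per-gene ROC operating points, CART
  accuracies, clinical-association p-values) depend on unpublished
  per-patient data; the package reproduces the *procedures* and validates
  them on simulated cohorts with stated design targets.
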