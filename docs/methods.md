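# Methods

## Problem and pipeline

Acute radiation dermatitis during whole-breast radiotherapy is usually
graded by eye on coarse ordinal scales. This package quantifies it
instead from close-up skin surface photographs (1 × 1 cm field,
1624 × 1212 px, RGB) taken in three device illumination modes — normal
(surface pores and redness), polarized (basal-layer melanin) and UV
(sub-surface melanin/sebum) — at four anatomical points per breast on
both the treated (ipsilateral) and untreated (contralateral) side, at
four visits: before treatment, around day 7, around day 14, and about
ten days after the end of treatment.

The measurement chain per capture is: split into R/G/B channels → keep
a centred circular region of interest of radius 300 px (which also
discards the vignetted periphery of UV frames) → quantize to
*N<sub>g</sub>* = 64 grey levels on the fixed 0–255 range → accumulate
a symmetric grey-level co-occurrence matrix (GLCM) at displacement
*d* = 1 for each of the four offsets θ ∈ {0°, 45°, 90°, 135°} → compute
18 Haralick-type statistics per matrix → average the four angle vectors
→ average the three channel vectors. Only pixel pairs with *both*
members inside the ROI mask are counted.

Per series (patient × side × point × mode) every feature is expressed
as its ratio to the pre-treatment value ("delta-radiomics"),
normalising inter-individual differences in skin tone and texture;
baseline rows are exactly 1. Point deltas are averaged to one value per
breast for the longitudinal statistics; the dose analysis keeps points
as the unit, pairing each point's delta with the dose measured at the
same point.

## Feature formula dialects

Implementations of the Haralick set in circulation disagree on three
features, and the package exposes the choice explicitly:

* `matlab_toolbox` (default) — the conventions of the widely used
  MATLAB GLCM feature script lineage: **variance** is centred on the
  mean of the *matrix entries* (a number near 1/N<sub>g</sub>², so the
  feature closely tracks autocorrelation), **sum variance** is centred
  on the *sum entropy*, and **difference variance** is the raw second
  moment Σk²p<sub>x−y</sub>(k), which is algebraically identical to
  contrast. These three quirks are exactly what longitudinal summary
  tables produced with that lineage show (a Variance row shadowing
  Autocorrelation and a Difference-variance row duplicating Contrast),
  so the default reproduces them deliberately.
* `haralick_1973` — the textbook definitions (variance about the
  marginal mean level, sum variance about the sum average, difference
  variance as the central variance of p<sub>x−y</sub>).

All entropies use the natural logarithm with 0·ln 0 ≡ 0. On a
degenerate matrix concentrated in one cell, correlation and IMC1 are
undefined (zero marginal variance/entropy); they become NaN sentinels
with a warning, are skipped by angle/channel averaging unless every
member is degenerate, and propagate as missing — never as zeros.

Numerical conventions pinned because they are not forced by the
problem: quantization is fixed-range (level = ⌊v·N<sub>g</sub>/256⌋+1),
never per-image min–max, so the intensity→level map is time-invariant
and baseline ratios are comparable; the ROI centre is ((H−1)/2,
(W−1)/2) with an inclusive boundary; levels are 1-based; GLCMs are
symmetric (so 0° and 180° coincide, matching the four-angle design).

## Statistical analysis

Per mode and feature, on the per-breast patient values:

* **Two-way repeated-measures ANOVA** with both factors within-subject
  (side: 2 levels; time: 4 levels), computed from orthonormal contrast
  scores. For an effect with q contrasts M, scores z<sub>i</sub> = M
  y<sub>i</sub> give F = (n·‖z̄‖²/q)/(Σ‖z<sub>i</sub>−z̄‖²/((n−1)q)).
  Mauchly's W = det S/(tr S/q)<sup>q</sup> on the contrast covariance S
  with the first-order χ² approximation; when its p < 0.05 the
  Greenhouse–Geisser ε = (tr S)²/(q·tr S²) deflates both degrees of
  freedom. A two-level effect has one contrast, so sphericity holds
  trivially and ε = 1. The implementation reproduces pingouin's F, p
  and ε to machine precision (pingouin is used only as a test oracle —
  it does not expose per-effect sphericity for two-way designs).
* **Paired side comparisons** at each post-baseline visit: Shapiro–Wilk
  on both samples; both p ≥ 0.05 → paired t, otherwise Wilcoxon
  signed-rank (zeros dropped; exact null up to n = 25 without ties,
  else normal approximation with tie correction), judged at the
  Bonferroni level 0.05/3 = 0.0167 for the three post-baseline visits.
  Every result records the branch taken and the gate p-values.
* **Correlations** (dose vs delta per point; day-7 delta vs later
  deltas per breast): Shapiro-gated Pearson/Spearman, two-sided, with
  Benjamini–Hochberg adjustment within each 18-feature family (one
  family per mode × analysis × timepoint, mirroring how such results
  are tabulated per mode).

Monte-Carlo calibration (seeded, 2,000 replicates at n = 20) confirms
that each test rejects at the nominal 5% under its null within binomial
error and that BH keeps the expected false-discovery proportion ≤ 5%.

## Synthetic cohort generator

No public image data exist for this design (prospective single-centre
cohort), so the package ships a seeded generator that emulates the
statistical structure the analysis assumes, not photorealistic skin:

* **Doses.** Four first-fraction point doses per patient, normal draws
  truncated at zero around the reported site means ± SD (upper
  253.1 ± 14.7, lower 247.8 ± 18.1, inner 212.4 ± 19.6, outer
  226.8 ± 23.5 cGy), sampled once per patient and reused across visits
  (doses are measured at the first fraction only).
* **Base texture.** Per (patient, side, point, mode): a Gaussian random
  field (SD 12 intensity units, correlation length 10 px) around a
  per-mode mean level (normal 150, polarized 135, UV 90 — UV frames are
  darkest), plus dark speckle (density 0.002, depth 45) emulating
  pores. The base field is identical across visits, so only the injury
  signal changes the texture.
* **Injury signal.** severity s = w<sub>mode</sub>(t)·dose/d̄ on the
  treated side and γ·w<sub>mode</sub>(t) (dose-independent, γ = 0.25)
  on the untreated side, with w ≡ 0 before treatment. Pixels become
  base − κ<sub>dark</sub>·s − κ<sub>het</sub>·s·blotch, with
  κ<sub>dark</sub> = 30 (mean darkening at unit severity),
  κ<sub>het</sub> = 25 and a smooth zero-mean blotch field (correlation
  length 40 px) fixed per series. Darkening drives the sum-variance
  delta down (the GLCM mass moves to lower levels); blotch
  heterogeneity widens the intensity distribution, driving energy down
  and entropy up — the directional pattern such cohorts show.
* **Severity profiles** are monotone in all modes (normal 0, 0.5,
  0.85, 1.0; polarized 0, 0.4, 0.7, 1.0; UV 0, 0.5, 0.8, 1.0):
  visible damage accumulates through treatment and has not resolved ten
  days after the end. An earlier design peaked the normal-mode profile
  at day 14, but in this single-severity render model that forces the
  energy delta to recover, contradicting the monotone energy decline
  the design is meant to exhibit; energy is the headline normal-mode
  feature, so the monotone profile is the default and all profiles are
  config-overridable. The contralateral attenuation γ has no measured
  anchor (no contralateral dosimetry is modelled) and is a free
  simulation parameter.
* **Determinism.** One master seed; every entity (dose set, base field,
  blotch field) draws from a substream keyed by a BLAKE2 hash of its
  metadata, so cohorts are reproducible across processes and any single
  image can be regenerated in isolation. Wide-correlation fields are
  synthesised on a coarse grid and bilinearly upsampled (identical
  statistics at large scales, ~4× cheaper); channels are rendered once
  and replicated when the per-mode channel weights are equal (the
  default (1, 1, 1), since the analysis averages channels anyway).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: illumination drift, registration error
between visits, colour (channels are equal by default), anatomy-scale
gradients, patient-level radiosensitivity variation (between-patient
delta SDs are therefore much smaller than in a real cohort), and any
relation between modes beyond their severity profiles.

## Problem sizes and runtime choices

The test suite runs the full-scale design where the identity being
checked depends on it (one 20-patient cohort at 1624 × 1212 for the
pattern-recovery and baseline-identity checks, ~2.5 min on one CPU;
single-patient and 1,000-patient dose checks as stated), and reduced
64 × 64 cohorts with ROI radius 24 and N<sub>g</sub> = 16 elsewhere,
chosen so the whole suite stays in single-digit minutes. Dual-route
oracle checks (vectorised vs literal enumeration) use ≥100 random grids
up to 12 × 12 at N<sub>g</sub> = 8 with 1e-10 tolerances.

## Known limitations

* The per-breast aggregation of the four points (arithmetic mean) is a
  modelling choice; points can instead be kept as the analysis unit.
* Mauchly's p uses the first-order χ² approximation; pingouin's
  higher-order version differs in the third decimal, which can flip the
  correction gate for p near 0.05 (the ε and corrected p themselves
  agree to machine precision).
* The Wilcoxon branch drops zero differences (classic convention;
  Pratt's method is not implemented).
* Degenerate baselines (a feature exactly zero before treatment) make
  that feature's deltas undefined for the series; they are reported as
  missing rather than imputed.
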