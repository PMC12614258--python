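# Methods

`ccfdgrid` quantifies choriocapillaris flow deficits (CCFD%) on en face
SS-OCTA slabs and tracks them in fixed grid boxes across a four-visit
longitudinal series centered on the onset of a large choroidal
hypertransmission defect (hyperTD).  This note documents the model, the
numerical choices, the synthetic-data generator that stands in for scanner
data, and what the test suite does and does not demonstrate.

## Quantification pipeline

**Inputs per visit.** Four grayscale en face rasters sharing one shape and
a uniform pixel pitch (default 12 µm/px, i.e. 500 A-scans across a 6-mm
scan): the CC flow slab (4–20 µm below Bruch's membrane), the CC structure
slab, the sub-RPE structure slab (64–400 µm below BM), and a retinal
vasculature image; plus binary masks: a manually outlined exclusion mask
covering hypotransmission defects (shadows from calcified drusen and
hyperreflective foci), a hyperTD annotation mask, and optionally a retinal
vessel mask.  Visit indices run 0–3: one year pre-onset, onset (T = 0, the
first visit whose hyperTD mask contains the target lesion), and one and two
years post-onset.

**Attenuation compensation.** Drusen attenuate the OCT signal reaching the
CC, darkening the CC slabs and inflating apparent flow deficits.  The
sub-RPE structure slab serves as the attenuation reference: shadows
originate above the CC, and this deep, thick average tracks them robustly.
The reference is Gaussian-smoothed (13 × 13-px kernel, σ = 15 px — with σ
this large relative to the kernel, effectively a box average that
suppresses the high-frequency noise which otherwise destabilizes the
optimization), floored at a small ε, and normalized into (0, 1] by its
99th percentile.  The percentile is computed over pixels *outside* the
hyperTD compensation mask: hyperTDs are never compensated, so their
brightness must not set the normalization ceiling (with a large lesion it
otherwise rescales the whole factor field).  Both CC slabs are multiplied
by `N(x)^(−γ)`; the factor is pinned to 1 under the compensation mask and
the output is clipped at the input dynamic-range ceiling.  γ is selected
per scan by exhaustive search over 0.0–5.0 in steps of 0.1, minimizing the
standard deviation of the compensated CC structure slab over eligible
pixels (outside both the compensation and exclusion masks; at least 100
required); ties break toward the smaller γ, so a scan needing no
correction selects γ = 0.

**Binarization.** A single global threshold separates deficit from flow
pixels: two-cluster fuzzy C-means with fuzzifier m = 2 on the 256-bin
intensity histogram of valid pixels, deterministically initialized at the
25th/75th percentiles, converged at 1e-6 center movement (≤ 500
iterations).  For m = 2 the equal-membership point of two clusters is the
midpoint of the centers, which is the threshold; intensity strictly below
it is deficit.  Running FCM on the histogram rather than raw pixels is
exact for a global threshold (the objective depends only on the intensity
distribution) and deterministic.  Deficit components (8-connected) with
equivalent circular diameter `2·s·sqrt(area/π)` below 24 µm — the
physiological intercapillary distance — are reassigned to flow.  Pixels
under the exclusion or vessel mask are a third state, *invalid*, excluded
from both numerator and denominator; marking vessel-projection pixels
invalid is a deliberate simplification of model-based artifact removal.

**Registration and the integrated mask.** Follow-up scans are
fovea-centered, so a rigid integer translation per visit suffices.  The
final visit is the reference; each visit's shift is the integer argmax of
zero-normalized cross-correlation of the vasculature images within
|dy|, |dx| ≤ 32 px (computed on a central window of up to 256 px — ample
vessel texture at friendlier FFT sizes).  Exact ties break toward the
smaller |dy| + |dx|, then lexicographically.  A peak below 0.2 raises a
registration failure and excludes the case.  The shift is applied to the
binary CCFD map and masks; border pixels shifted in from outside the field
become invalid (maps) or excluded (exclusion-type masks) while annotation
masks (hyperTD, vessel) fill with False.  The four registered exclusion
masks are unioned into one *integrated* mask applied to every visit, so
the same regions are excluded throughout the series.

**Grid boxes.** A 74 × 74-px box (≈ 0.9 × 0.9 mm, 0.81 mm²) is centered on
the rounded centroid of the target-hyperTD annotation (clamped inside the
raster), and a lattice of complete boxes with that anchor tiles the
raster.  Categories are frozen from the union of hyperTD masks over all
visits: the one target box; any other box overlapping hyperTD pixels
(including target-lesion spillover) is non-target hyperTD; remaining boxes
are adjacent background when 8-neighbouring a hyperTD box on the lattice,
else non-adjacent background.

**Availability and CCFD%.** Per box and visit, unavailable = invalid pixels
∪ low-signal pixels, where low-signal means intensity below
`background × 10^(5/10)` on the compensated structure slab and the
background level is the median of the darkest 5% of pixels (a robust
noise-floor proxy; the estimator presumes the scan contains a genuine dark
population, which vessel shadows provide).  A box is excluded when strictly
more than 25% of its area is unavailable at *any* visit, and then at all
visits, mirroring the integrated-mask philosophy.  CCFD% = 100 × deficit /
(deficit + flow) over available pixels.

**MDC rule.** For the target box, the change from the pre-onset baseline is
flagged as real when |Δ| strictly exceeds 5 percentage points, a margin
above published single-box test–retest repeatability (MDC ≈ 4.7%).

**Group inference.** Included box series are modelled with REML linear
mixed models, `ccfd_pct ~ visit` (categorical) with nested random
intercepts patient / eye-in-patient / box-in-eye.  A level that does not
refine the coarser level's partition (one eye per patient, one box per
eye) is unidentifiable and dropped up front; a level whose variance
estimates at zero (singular fit) is dropped and the model refit.
Estimated mean differences are reported against the onset visit with
Tukey-adjusted p-values over the family of all six pairwise visit
comparisons (studentized-range distribution) and unadjusted 95% CIs —
adjusted p with unadjusted intervals, stated explicitly because the
convention is ambiguous in the field.  Denominator degrees of freedom are
residual-type (n − p − number of random-effect units); at the package's
design sizes (df > 300) this is indistinguishable from Satterthwaite, and
the test suite verifies agreement of estimates, SEs, and adjusted p-values
with lme4/emmeans on shared data.

## Synthetic data generator

No public scans accompany this problem, so `ccfdgrid.synthetic` renders
four-visit cases with exact ground truth.  All content lives on an
oversized canvas; each visit is a window into it offset by a known integer
shift — the moving scan window over a fixed fundus — so true transforms
are exact and every visit has full field content.

* **Flow deficits** are non-overlapping 48-µm discs on a jittered hard-core
  lattice.  Each site is *active* at a given visit with probability 0.55,
  plus a small per-visit shift of that probability (sd 0.005) shared by
  the whole eye.  The lattice density is the target fraction divided by
  the persistence, so the expected CCFD% is the configured fraction
  (default 10%).  This transience is what gives the measurement its finite
  test–retest repeatability (repeat SD ≈ 1 point, MDC95 ≈ 2.8 — deliberately
  inside the 5% rule; published estimates are ≈ 1.7), while noise stays
  small.
* **The lesion neighborhood** is a disc (default radius 1250 µm) around the
  target center.  In effect scenarios the deficit fraction inside it rises
  post-onset (sites added, none moved); the default (null) keeps it equal.
  The default effect scenario uses a post fraction of 0.18 — a ≈ +8-point
  rise, the order of magnitude the method is meant to detect — chosen so
  the global FCM threshold is not measurably perturbed outside the
  neighborhood (measured coupling on non-adjacent boxes ≈ 0.002 points).
* **Drusen attenuation** is a product of Gaussian bumps (15 bumps, σ
  150 µm, depth 0.55), floored at 0.5 — stacked shadows never null the
  signal — and applied identically to flow and structure slabs; the
  hyperTD interior is never attenuated (RPE loss increases light
  penetration) and appears as doubled sub-RPE brightness.
* **HypoTDs** are near-zero discs (radius 100 µm) in all slabs; their
  exclusion outlines carry a 100-µm grading margin, as a human grader
  outlines beyond the visible shadow edge.  Without the margin, partially
  shadowed rim pixels are amplified by the compensation (the smoothed
  reference dips near the lesion) and destabilize the global threshold.
  Shadows are kept ≥ 1500 µm from the target, since cases whose target
  area is shadowed are excluded by design.
* **Retinal vasculature** is a branching random-walk tree with baked-in
  speckle, identical across visits up to the known shift, grown until it
  covers ≥ 8% of the raster.  The tree shadows the CC slabs (× 0.15) and,
  much more mildly, the deep sub-RPE average (× 0.85); it is also exposed
  as the vessel mask.  The shadow population is what the darkest-5%
  background estimator measures; without it the 5-dB rule would
  degenerately mask entire clean scans.
* **Noise** is additive Gaussian on linear intensity truncated at zero
  (flow sd 8, structure sd 6) with a mild lognormal per-visit noise-level
  jitter (sd 0.1).  Deficit pixels keep 30% of the baseline decorrelation
  signal.  Keeping the noise small matters: compensation is multiplicative
  and amplifies additive noise in attenuated regions.

**What the generator does not emulate:** OCT speckle statistics, B-scans
and segmentation, eye-motion artifacts beyond rigid translation, drusen
growth between visits, signal-strength variation with defocus or media
opacity, and non-target hyperTDs (the non-target category is exercised via
target-lesion spillover).  Passing tests therefore demonstrate the
correctness and calibration of the *measurement machinery* under known
truth, not performance on scanner data.

## Problem sizes in the test suite

Simulations are sized to run comfortably on one CPU: 20 synthetic eyes per
recovery condition; 200 eyes for the null MDC check; 100 replicates of a
24-patient (3 bilateral) × 9-box design for mixed-model effect recovery
and CI coverage; 300 replicates of a 12-patient × 6-box design for null
calibration; 12 eyes for the regional-pattern study.  The acceptance
script (`scripts/acceptance.py`) recomputes the same quantities at
somewhat smaller sizes, seeded from `--seed`.

## Known limitations

* The global FCM threshold couples, in principle, all image regions; a
  sufficiently dramatic focal change shifts the threshold and biases
  remote boxes by a few tenths of a point.  At paper-scale effect sizes
  the coupling is negligible (measured ≈ 0.002 points).
* The mixed model deliberately contains no eye-visit random effect (the
  random structure is patient / eye / box, matching how such studies are
  analysed), so visit-day shocks shared by all boxes of an eye inflate
  significance slightly; the generator keeps that component small relative
  to box-level variability.
* Translation-only registration; rotation, scaling, and subpixel alignment
  are out of scope.
* dB conversions use the power convention `10·log10` throughout.
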