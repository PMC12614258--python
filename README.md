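# ccfdgrid

Longitudinal grid-box quantification of **choriocapillaris flow deficits
(CCFD%)** from en face swept-source OCT angiography slabs, built for the
question: does choriocapillaris perfusion drop *before* or *after* a large
choroidal hypertransmission defect (hyperTD) appears in an eye with
intermediate AMD?

It is written for imaging scientists who have per-visit en face slabs (CC
flow, CC structure, sub-RPE structure, retinal vasculature) plus lesion
masks, and want reproducible per-box CCFD% trajectories and group-level
statistics — and for anyone who wants a fully synthetic, ground-truthed
test bench for this class of pipeline.

## The method

For each of four visits (1 y pre-onset, onset T = 0, +1 y, +2 y):

1. **Compensation.** Drusen shadow the CC, inflating apparent flow
   deficits.  The smoothed sub-RPE structure slab (13×13 px Gaussian,
   σ = 15), normalized by its 99th percentile to N(x) ∈ (0, 1], gives a
   multiplicative correction `N(x)^(−γ)` applied to both CC slabs.  γ is
   optimized per scan over 0.0–5.0 (step 0.1) to minimize the standard
   deviation of the compensated CC structure slab; hyperTDs are protected
   by a compensation mask (compensating areas of RPE loss would invert
   their brightness and fabricate deficits).
2. **Binarization.** Fuzzy C-means (m = 2, two clusters) on the 256-bin
   histogram of the compensated flow slab; threshold = midpoint of the
   cluster centers; deficits with equivalent diameter < 24 µm (the
   intercapillary distance) are removed.
3. **Registration.** Each visit is aligned to the final visit by integer
   translation maximizing the ZNCC of the retinal-vasculature images
   (search ± 32 px); per-visit exclusion masks are registered and merged
   into one *integrated mask* so the same regions are excluded everywhere.
4. **Grid tracking.** A 74 × 74-px box (≈ 0.9 × 0.9 mm, 0.81 mm²) is
   centered on the target hyperTD; a lattice of equal boxes tiles the
   scan.  Boxes are classified once — target / non-target hyperTD /
   adjacent background / non-adjacent background — and a box whose area is
   > 25% unavailable (masked, low-signal, or registration-cropped) at any
   visit is excluded at all visits.  Per box and visit,
   CCFD% = 100 · deficit / (deficit + flow) over available pixels.
5. **Inference.** A target-box change from baseline beyond the 5% minimal
   detectable change (MDC) counts as real.  Group contrasts come from REML
   linear mixed models (`ccfd_pct ~ visit`, random intercepts
   patient / eye / box, singular components dropped), with Tukey-adjusted
   p-values over all six pairwise visit comparisons.

Because no scans are distributed, `ccfdgrid.synthetic` generates complete
four-visit cases — drusen attenuation, growing hyperTDs, hypoTD shadows,
vessel shadows, known inter-visit shifts, and exact per-box ground truth —
used by the test suite and the acceptance script.

## Worked example

```python
from ccfdgrid import ScenarioParams, generate_case, run_case

# An eye whose CC perfusion drops around the lesion after hyperTD onset
params = ScenarioParams(rng_seed=11, deficit_fraction_post=0.22)
visits, truth = generate_case(params)
result = run_case(visits)

for v in result.manifest["visits"]:
    print(f"visit {v['visit_index']}: gamma*={v['gamma_star']:.1f}  "
          f"threshold={v['fcm_threshold']:.1f}  shift=({v['dy']},{v['dx']})")
print("target box CCFD% by visit:", [round(x, 1) for x in result.target_series])
print("MDC flags vs baseline:   ", result.mdc_flags)
```

prints

```
visit 0: gamma*=1.0  threshold=79.4  shift=(6,-9)
visit 1: gamma*=1.0  threshold=79.4  shift=(-5,7)
visit 2: gamma*=1.0  threshold=79.3  shift=(4,3)
visit 3: gamma*=1.0  threshold=79.4  shift=(0,0)
target box CCFD% by visit: [10.3, 9.6, 23.0, 21.4]
MDC flags vs baseline:    [None, False, True, True]
```

Reading it: every visit selected γ = 1.0 (the generator's drusen field is
fully corrected at that exponent), the FCM threshold is stable across
visits, and the known inter-visit shifts were recovered exactly.  The
target box sits near 10% CCFD before and at onset — no change beyond the
5% MDC — then jumps to ~22% at the post-onset visits, both flagged as real
change: perfusion loss after, not before, lesion onset.

Multi-eye studies (`run_study`) add the pooled box table and the four
category-level tables of estimated mean differences versus onset.  The
same workflow is scriptable from the shell:

```bash
ccfdgrid simulate --out case0 --seed 11
ccfdgrid analyze  --case case0 --out results0
ccfdgrid study    --study casedir/ --out study_results/
```

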