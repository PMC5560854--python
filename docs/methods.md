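# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `adipoct`, and what the synthetic validation does and
does not demonstrate about real scans.

## Quantification model

A micro-CT scan is a scalar HU field sampled on an isotropic 100 µm grid,
ordered (z, y, x) with z cranio-caudal. Tissue classes are modelled as HU
bands; all bands are closed intervals on integer-quantised HU:

| quantity | band (HU) | rationale |
|---|---|---|
| whole body | [−350, +3000] | separates the animal from air while keeping bone |
| fat (nominal) | [−350, −150] | adipose attenuates less than lean tissue |
| fat (calibrated) | [−350, *h*\*] | *h*\* from the fat-pad match, see below |
| lean | [*h*\*+1, +300] | abuts the fat band; excludes bone |

Whole-body volume is the largest 6-connected component of the body band
(26-connectivity is available; 6 resists noise bridges in large
structures), with enclosed cavities filled so lung interiors count toward
total volume — otherwise fat/total and lean/total ratios would not be
comparable across animals with different lung inflation.

### Fat-pad calibration

The identifiable free parameter is the upper fat bound *h*. A fat pad of
known mass *m* in the scan field has a density-derived reference volume
*V*<sub>pad</sub> = 1000·*m*/ρ mm³ (ρ in g/mL). The segmented pad volume
inside its ROI is nondecreasing in *h*, so the smallest integer *h* whose
pad volume covers *V*<sub>pad</sub> is well defined and found by bisection
(the unit tests assert equality with an exhaustive integer sweep). If even
the top of the search range (default [−349, 0]) under-covers the target,
the result is flagged non-converged; it is never reported as a success.
The default residual tolerance is 1% of the target volume.

Only the upper bound is calibrated; the lower bound stays at −350 HU and
is shared with the body band, so the fat mask is a subset of the body mask
by construction. Because the pad's boundary suffers the same
point-spread/filter blur as the fat depots inside the animal, matching the
pad volume transfers the correct fat/soft partial-volume cut-off to the
whole scan: on phantoms whose fat and soft means are −250 and +40 HU, the
calibrated bound lands near the blurred-interface midpoint (≈ −105 HU,
plus a small curvature offset — observed ≈ −94 HU), not at an arbitrary
printed value. For this transfer to exist at all, the pad must present a
fat/soft interface: a pad surrounded by air has a pad volume that is flat
in *h* (the blurred fat/air transition never rises above −350 HU), which
is why the phantom embeds the pad in a small tissue-equivalent support
block behind the animal — the synthetic analogue of a pad resting against
the animal's back.

### Density

Adipose density is the mean over replicates of d = m/v from the
displacement protocol (graduated-tube resolution 0.05 mL), default
0.92 ± 0.01 with n = 10. Densities are handled in g/mL (≡ g/cm³)
throughout; tables that print adipose density in "mg/mL" are read as g/mL
— the literal reading is three orders of magnitude below any condensed
tissue — and the interpretation is logged at run time rather than silently
applied.

### Surface peel

Partial-volume voxels where the blurred air/soft transition sweeps through
the fat band form a false-fat ring over the entire body surface. At
desk-scale phantom geometry (body ≈ 410 mm³, surface ≈ 300 mm²) this ring
would inflate the fat fraction by ≈ +0.06, an order of magnitude more than
in a real mouse, whose surface-to-volume ratio is ~8× smaller. The
pipeline therefore restricts adipose counting to the body core: the body
mask eroded by `surface_peel_vox` voxels (default 2, 26-connectivity).
This is the same artifact-suppression rationale as the manual lung-area
correction, applied automatically at the surface; it is a deliberate
refinement of the plain band-threshold recipe. The primitive
`segment_fat` defaults to peel 0 so its contract is the textbook
definition; the end-to-end estimator defaults to 2. Lean counting is not
peeled: the inner part of the ring is genuine lean tissue.

## Synthetic phantoms

`phantom.generate_phantom` builds a mouse-like scene with exact per-voxel
labels: air background; an ellipsoidal soft-tissue body (default semi-axes
0.45/0.26/0.42 of the grid extent); two prolate lungs (default 1.8% of the
analytic body volume, matching murine lung/body proportions); a dorsal
bone rod (default 5% of body voxels); compact subcutaneous (55%) and
visceral (45%) fat depots selected by exact voxel count so the realized
fat fraction equals the target to rounding; and the fat pad embedded in
its support block dorsal to the animal, with pad mass derived as realized
voxel volume × density so the calibration target is exactly consistent.

The ideal per-tissue HU field (air −1000, lung −700, fat −250, soft +40,
bone +1000) is degraded in order: Gaussian point-spread blur (default
σ = 0.4 voxels), optional 1-D cranio-caudal motion blur emulating an
ungated acquisition, additive Gaussian noise (default SD 25 HU, drawn once
as unit noise and scaled, so noise levels are comparable under a fixed
seed), and a CT clamp to [−1024, +3072]. Generation is pure in the seed:
identical spec + seed gives bit-identical volumes.

Deliberate departures from real anatomy, and why:

* **Depots are compact blobs buried ≥ 0.5 mm deep**, not a thin
  subcutaneous shell. At desk scale a realistic shell is sub-voxel and
  would be erased by blur — the test would measure the blur, not the
  segmentation. The burial depth also guarantees the surface peel can
  never remove true fat.
* **Default grid (160, 112, 112).** Chosen from a partial-volume error
  budget: the −350 HU body threshold erodes the blurred surface by
  ≈ 0.34 voxels, a −2.5% body-volume bias at this size (within the 3%
  the suite enforces) but −4.7% at 64³. Calibration-equivalence cohorts
  run at 64³, where the bias is irrelevant to the threshold search.
* **Phantom cohorts span fat fractions 0.12–0.35** (lean to obese mice);
  at 64³ the burial constraint caps the geometric fat budget near 0.38.
* No projection-space simulation, beam hardening or scatter; the HU field
  is modelled directly.

Consequently, passing phantom suites shows the *pipeline arithmetic and
calibration logic* are correct under controlled blur and noise; it does
not certify accuracy on real animals, where tissue heterogeneity, beam
hardening and anatomy-dependent partial-volume structure are richer.

## Reliability and statistics

CV = 100 × sample SD (ddof = 1)/mean; n−1 normalisation is conventional
for the small replicate counts involved (3, 5, 15). Identical values
return exactly 0 (no floating residue). Three raw-value grouping levels
are reported per animal and method — all sessions pooled, mean of
within-day CVs, mean of across-day CVs at a fixed session — and, because
published descriptions of this design are ambiguous between CVs of raw
values and CVs of means, the CVs of the 5 day-means and of the 3
session-means are emitted alongside rather than chosen silently. The
levels estimate the same noise CV only up to the small-sample SD bias
c4(n); the property suite checks agreement after dividing that factor out.

The repeated-measures generator uses multiplicative session/day effects
shared across methods plus per-method Gaussian noise; the default noise
scales (BIS-analogue 0.172, micro-CT-analogue 0.056) are the headline
test-retest CVs of the two instruments, giving the characteristic ≈ 3:1
uncertainty ratio.

Pearson/least-squares fits delegate to scipy (`pearsonr`, `linregress`).
ANOVA tables are computed from the definitional sums of squares so
degenerate conventions are explicit — a zero-SS effect gets F = 0, a
positive effect over a zero residual gets F = ∞ with p = 0 — and the
noisy-case tables are verified against statsmodels `anova_lm` in the
tests. Two-way ANOVA is restricted to balanced complete designs (where
Type I/II/III sums coincide); time is treated as a crossed fixed factor,
not a repeated measure. α = 0.05 throughout. Monte-Carlo power checks
plant effects sized a priori for ≈ 98% analytic power (e.g. a 3.5σ
interaction contrast at n = 6 per cell).

## Problem sizes

Seeded cohorts use 10 phantoms at (160, 112, 112) for recovery, 10 at 64³
for calibration equivalence, 3 static/motion pairs for the gating
analogue, 100 replicates for the CV-ratio and regression/ANOVA power
checks, and 500 for the CV-level agreement property. These sizes put the
full test suite and the acceptance script each well under a minute of
compute while keeping Monte-Carlo margins comfortable.

## Known limitations

* Subcutaneous vs visceral depots are labelled in phantoms (ground truth
  for tests) but the pipeline reports total fat only; automatic depot
  separation by body-contour parsing is out of scope.
* Bioimpedance values are consumed as tabular data; the instrument's
  internal Cole-model computation is not modelled.
* The calibrated bound is a single global threshold; spatially varying
  bias fields (beam hardening) would require per-region calibration.
* Raw+JSON, NIfTI-1 and MetaImage are supported; DICOM series are not.
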