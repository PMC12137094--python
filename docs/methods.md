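# Methods

## The measurement model

The Relaxation Index (RI) treats the retinal pigmented epithelium (RPE) as
an immobile reference frame: the outer retina is anchored to it, so any
tangential stretch of the inner retina by an epiretinal membrane (ERM)
shows up as movement of inner-retinal landmarks relative to their vertical
projections onto the RPE. The landmarks are vessel crossings marked on the
infrared (IR) fundus image; because the IR picture and the OCT B-scan are
acquired as a registered pair (the device's fundus-tracking follow-up mode
re-acquires the same scan location at every visit), a crossing's lateral
position along the green scan-position arrow identifies a unique B-scan
column, and the segmented RPE trace supplies its anchor point there.

For a pair of visits (T1→T2, T2→POST, T1→POST) the displacement of crossing
*i* is the Euclidean distance, in the B-scan plane (lateral + axial, μm),
between its two RPE anchors; the eye's RI is the mean over crossings,
reported in mm. This `rpe_anchored` definition is symmetric in the two
visits. A second reading of the construct — distance from the earlier
visit's ERM point to the later visit's RPE anchor — exists in the
literature describing it; it is provided as the `erm_to_rpe` mode but is
not the default, because it mixes membrane elevation into a tangential
measure and is order-dependent.

Displacements are in-plane only: the acquisition unit is a single
horizontal B-scan, so no en-face orthogonal component is observable.

## Segmentation chain (B-scan)

1. **Smoothing**: 5×5 uniform average, reflective borders.
2. **Enhancement**: unsharp mask, `s + α(s − G_σ s)` with Gaussian σ = 3 px,
   α = 1, clipped at 0. The high-pass term vanishes on flat input, which
   makes the stage an identity there — the property the tests pin.
3. **Envelope**: per-row maximum, moving-averaged over 5 rows (on by
   default; exposed as config because raw envelopes are noisier but
   sharper), then min–max normalized to exactly [0, 1].
4. **ROI**: rows between the outermost crossings of the 0.4 threshold.
   Interior dips below threshold are tolerated: the two bright layers are
   separated by darker retina whose envelope may fall under 0.4.
5. **Candidates**: per column, local maxima inside the ROI with prominence
   ≥ 5% of the column's dynamic range; the peak nearest the ROI top is the
   ERM candidate, nearest the bottom the RPE candidate. Columns with fewer
   than two peaks yield missing candidates (a single peak is ambiguous and
   by default assigned to neither layer).
6. **Outlier rejection**: a candidate is discarded when it deviates from
   the median of its (up to) 7 nearest-column neighbors by more than
   3 × max(MAD, 2 px). The 2-px floor keeps perfectly smooth neighborhoods
   from rejecting sub-pixel jitter; layers with fewer than 8 candidates
   skip rejection with a warning.
7. **Fitting**: ERM by cubic smoothing spline (residual budget 0.1 px² per
   point — small enough to track a few-pixel membrane undulation, large
   enough to absorb peak-quantization jitter); RPE by least-squares
   2nd-order polynomial (the posterior pole is approximately parabolic).
   Both are resampled at 100 evenly spaced columns over the common
   candidate span (not the full width: extrapolating a spline outside its
   support is not meaningful).

All thresholds are relative to the dynamic range, making the chain
equivariant under positive rescaling of the input — verified as a property
test. Requirements for a valid fit: ≥ 10 surviving candidates per layer
spanning ≥ 50% of the width.

## Panel splitting and registration

The composite export is converted to luminance (ITU weights 0.299/0.587/
0.114, pinned in config) and split at the strongest vertical edge: the
column-summed absolute forward difference, maximized over the interior
20–80% of the width. Forward differences locate the seam unambiguously
*between* two columns; the first column right of the edge becomes the
boundary, and the seam column belongs to the B-scan panel. A floor on the
seam strength (5% of rows × dynamic range) turns seamless or constant
images into an explicit error. The IR panel is assumed left by default
(`ir_side` override available).

The green arrow is the longest horizontal run of pixels whose green plane
exceeds both others by 0.2. Its `length_px − 1` intervals are mapped
linearly onto the B-scan's `n_cols − 1` column intervals (endpoints to
endpoints, exactly invertible). Physical scale on the IR panel uses
Bennett-style small-angle scaling, q [mm/deg] = 0.01306 × (axial length −
1.82 mm), with an emmetropic fallback of 23.3 mm when biometry is missing;
the B-scan lateral scale then follows from the arrow-length/B-scan-width
equality (`length_px × ir_scale = (n_cols − 1) × bscan_scale`, an identity
held to 1e-9). The axial scale is the device constant 3.9 μm/px and the
field of view 30°.

Interactive clicking is replaced by a marker CSV
(`eye_id,timepoint,marker_id,x_ir,y_ir`, 0-based pixels, timepoints
restricted to {T1, T2, POST}); validation reports all offending rows at
once.

## Statistics

Per-marker displacements are analyzed as
`d ~ pair + (1 | eye) + (1 | eye:marker)` by REML, the nested marker
intercept entering as a variance component within the eye group
(statsmodels `MixedLM`). Results are reported as level means with
Satterthwaite-style degrees of freedom assembled from the balanced-design
variance decomposition (eye df = E−1 dominates when the eye component
dominates); pairwise level contrasts, in which the random intercepts
cancel, carry the residual df and receive step-down Bonferroni-Holm
adjustment (authored here; cross-checked in the tests against a brute-force
oracle and statsmodels' `multipletests`). With 9 eyes, boundary (zero
variance) fits are expected occasionally; they are flagged on the result
(`singular`, `converged`) rather than raised, and an exactly noise-free
table falls back to per-level means with zero variance components.

BCVA is modeled the same way with only the eye intercept, in decimal units
(a logMAR conversion utility exists but is not the default). The RI–BCVA
association is `bcva ~ ri_mm + (1 | eye)` with an optional pre-operative
subset (T1, T2 only).

## What the phantom emulates — and what it does not

The generator produces the full composite: gray textured IR panel, dark
crossing strokes at the marker positions, a one-row green arrow at exact
recorded geometry, and a B-scan with Gaussian-profile ERM/RPE bands
(polynomial + sinusoid center-lines), optional vessel shadows at the
marker columns, and seeded additive Gaussian noise. Crossings drift
laterally between visits; drift is programmed in B-scan-plane μm and the
IR pixel shift is derived by inverting the arrow→B-scan mapping, so the
recorded truth displacement equals the programmed value exactly on a flat
RPE (and gains the implied axial component on a curved one, always equal to
the relaxation formula applied to the truth coordinates). Defaults mirror
the study conditions: 10 markers per eye, drifts of +150 μm (T1→T2) and
−120 μm (T2→POST) with 10 μm between-marker spread, 5%-of-range noise,
30° field, 3.9 μm/px axial, 24 mm axial length.

Not emulated: physically realistic OCT speckle (the noise is additive
Gaussian, not multiplicative Rayleigh-like), ERM elevation change between
visits, acquisition-to-acquisition tracking error, motion artifacts, media
opacity, or pathology beyond tangential drift. Passing phantom tests
therefore demonstrates correctness of the measurement chain and its
noise robustness at the modeled level — not segmentation performance on
pathological clinical scans.

`simulate_cohort` bypasses images entirely and draws displacement tables
from the assumed nested random-effects model (defaults: 9 eyes × 10
markers × 3 pairs; SDs 0.03/0.02/0.02 mm for eye/marker/residual, effect
sizes 0.15/0.12/0.05 mm), which is the appropriate test bed for the
statistical layer: model-recovery results there say nothing about image
processing, and vice versa.

## Numerical choices and degenerate inputs

- Intensities are [0, 1] floats internally; 8- and 16-bit PNG/TIFF accepted.
  Composites are written as 8-bit RGB (the interchange format of clinical
  exports), grayscale panels as 16-bit PNG.
- Constant images: splitting and envelope normalization raise explicit
  errors (`no boundary found`, normalization error) rather than returning
  arbitrary output.
- Ties in the seam search resolve to the leftmost maximal edge; ties in
  arrow detection to the topmost row.
- Trace evaluation between the 100 samples is linear interpolation;
  projections outside the trace span are errors, not extrapolations.
- A marker count ≠ 10 warns (`ShortMarkerCountWarning`) but does not abort;
  missing timepoints drop the affected pairs with a logged warning.
- All stage parameters live in one serializable `RunConfig`; the effective
  config written into a run directory reproduces the run bit-identically.

## Problem sizes used in the validation suite

Phantom images are 320 × 1024 composites (two 512-wide panels). The
validation suite uses 20 phantoms per noise level for segmentation
accuracy, single series for RI recovery/null/monotonicity, 200 simulated
cohorts for mixed-model recovery and coverage, 500 for the familywise-error
null, and 1000 random vectors for the Holm oracle — sizes at which the
Monte-Carlo standard errors are comfortably below the acceptance margins.

## Known limitations

- The degrees-to-μm conversion on the IR panel is a stated Bennett-style
  substitute; devices apply their own (undocumented) scaling, so absolute
  μm values on real exports carry that systematic uncertainty (relative
  comparisons across visits of the same eye are unaffected).
- The Satterthwaite-style df assumes a near-balanced design; severely
  unbalanced tables fall back to conservative component dfs.
- Segmentation assumes exactly two dominant bright bands inside the ROI;
  eyes with additional hyper-reflective pathology would need a stronger
  peak-assignment rule.
- BCVA in decimal units is retained for comparability; decimal acuity is
  not interval-scaled, which the logMAR utility can mitigate.
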