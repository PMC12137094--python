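# relaxindex

Quantification of tangential epiretinal-membrane (ERM) traction from paired
infrared (IR) fundus + OCT B-scan images, via the **Relaxation Index (RI)**.

An ERM is a fibrocellular sheet on the inner retinal surface whose
contraction drags the retina tangentially, distorting vision. Clinicians
currently judge its progression by eye; the RI replaces that with a number:
vessel crossings are marked on the IR fundus image at each visit, each
crossing is projected vertically onto the retinal pigmented epithelium
(RPE) — a deep layer assumed immobile — and the RI for a pair of visits is
the mean shift of those RPE anchor points,

&nbsp;&nbsp;&nbsp;&nbsp;RI = (1/n) Σᵢ ‖R′ᵢ(t₂) − R′ᵢ(t₁)‖&nbsp;&nbsp;[mm],

with n ≈ 10 crossings per eye and R′ᵢ the anchor of crossing *i* in the
B-scan plane (lateral + axial, micrometres). Traction pulls the crossings
outward between visits (RI grows); surgical peeling releases it (RI falls).

The package implements the whole measurement chain for composite clinical
exports (IR panel and B-scan panel side by side):

- **composite_io** — grayscale conversion and gradient-based panel splitting;
- **bscan_segmentation** — ERM/RPE boundary segmentation: 5×5 smoothing,
  unsharp-mask enhancement, row-maximum envelope, 0.4-threshold ROI,
  per-column dual-peak detection, median/MAD outlier rejection, smoothing
  spline (ERM) + 2nd-order polynomial (RPE) fits resampled at 100 points;
- **ir_registration** — green scan-arrow detection, marker CSV loading, the
  arrow-length↔B-scan-width mapping, Bennett-scaled μm conversion, marker
  projection onto the traces;
- **relaxation** — per-marker displacements and per-eye RI;
- **stats_models** — linear mixed models (pair as fixed effect, nested
  eye/marker random intercepts), Holm-corrected post-hoc contrasts, BCVA
  models and the RI–BCVA association;
- **phantom** — synthetic IR+B-scan series with exact ground truth, and a
  cohort simulator for the statistical models;
- **pipeline / cli** — one-command orchestration (`ri run`).

## Worked example

Generate a three-eye synthetic cohort with programmed drifts of +150 μm
(T1→T2, traction building) and −120 μm (T2→POST, surgical release), then run
the full pipeline:

```python
import yaml, pathlib
from relaxindex import PhantomSpec, generate_series, run_pipeline, RunConfig
from relaxindex.pipeline import load_manifest

out = pathlib.Path("demo"); out.mkdir()
eyes = []
for seed in (101, 102, 103):
    eye = f"E{seed}"
    generate_series(PhantomSpec(seed=seed, eye_id=eye), out_dir=out)
    eyes.append({"eye_id": eye, "axial_length_mm": 24.0,
                 "markers": f"{eye}_markers.csv",
                 "timepoints": {tp: f"{eye}_{tp}.png" for tp in ("T1", "T2", "POST")}})
(out / "manifest.yaml").write_text(yaml.safe_dump({"eyes": eyes}))

result = run_pipeline(RunConfig(), load_manifest(out / "manifest.yaml"), out / "run")
print(result.summary.to_string(index=False))
```

prints

```
eye_id   pair    ri_mm  n_markers
  E101 T1POST 0.027770         10
  E101   T1T2 0.149126         10
  E101 T2POST 0.121357         10
  E102 T1POST 0.029096         10
  E102   T1T2 0.150205         10
  E102 T2POST 0.121109         10
  E103 T1POST 0.029413         10
  E103   T1T2 0.151466         10
  E103 T2POST 0.122055         10
```

The estimated RI per eye recovers the programmed ~0.150 mm build-up and
~0.120 mm release to within a fraction of a lateral pixel (≈13 μm here);
the T1→POST values show the post-operative retina back near its baseline
configuration. The attached mixed model contrasts every pair of intervals:

```
T1POST vs T1T2:  diff = -0.1215 mm, Holm-adjusted p = 2.08e-46
T1POST vs T2POST: diff = -0.0927 mm, Holm-adjusted p = 5.04e-40
T1T2 vs T2POST:  diff = +0.0288 mm, Holm-adjusted p = 2.51e-15
```

The same steps are available from the shell: `ri phantom`, `ri split`,
`ri segment`, `ri project`, `ri measure`, `ri run`, `ri stats`.

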