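# choromet

Choroidal morphometry and stress-session analysis for wide-field swept-source
OCT (SS-OCT), with paired heart-rate-variability metrics.

`choromet` is for researchers studying how the posterior segment of the eye —
above all the choroid, the vascular layer between the retinal pigment
epithelium (RPE) and the sclera — responds to an acute intervention measured
in a paired design: two baseline scans, then scans during a condition (for
example a mental-arithmetic stressor), with RR-interval recordings running
throughout. The package covers the complete chain from raw volumes to a
cohort statistics table:

1. **Synthetic data** — ground-truthed eye phantoms (sphere-cap posterior
   pole, foveal pit, optic disc, retinal-vessel shadows, choroidal texture,
   speckle, attenuation) and autoregressive RR-interval series, so the whole
   pipeline is testable without patient data.
2. **Enhancement** — Perona–Malik anisotropic diffusion (edge-preserving
   denoising) followed by adaptive compensation, the column-wise attenuation
   correction `I(z)^n / (2 Σ_{z'≥z} I(z')^n)` that restores contrast at the
   choroid–scleral interface (CSI).
3. **Registration** — rigid alignment of the condition volume to baseline
   (en-face projection registration + axial alignment + least-squares
   polish), with symmetric half-transform resampling so interpolation
   effects cancel in paired differences.
4. **Segmentation** — ILM, mid-RPE and CSI boundaries per B-scan by
   dynamic-programming minimum-cost paths with anatomical band constraints
   and sub-pixel refinement; Dice overlap scoring against reference masks.
5. **Morphometry** — Bennett magnification scaling
   (`ratio = 3.382 × 0.013062 × (axial length − 1.82)`), fovea-centered mean
   thicknesses RT/CT over 1 mm and 3 mm circles, and best-fit-circle radii
   R₀, R₄₅, R₉₀, R₁₃₅ of the mid-RPE along four en-face directions with
   direction-specific inclusion windows.
6. **HRV** — event-anchored 20 s RR windows, time-weighted mean HR
   (`60000·n/Σrr`) and RMSSD (root mean square of successive differences).
7. **Statistics** — Shapiro–Wilk-gated paired t / Wilcoxon signed-rank
   comparisons, Pearson/Spearman correlations, and Bland–Altman limits of
   agreement (mean ± 1.96 SD) for within-session repeatability.

## Worked example

Simulate one subject (baseline + stressed eye with a +10 µm choroidal
thickening and a small repositioning) and run the per-subject analysis:

```python
from choromet.pipeline import simulate_subject

r = simulate_subject(seed=5, delta_ct_um=10.0)
print(f"CT_3mm baseline {r.baseline.ct_3mm_um:.1f} um, "
      f"stress {r.stress.ct_3mm_um:.1f} um, "
      f"change {r.stress.ct_3mm_um - r.baseline.ct_3mm_um:+.1f} um")
print(f"HR {r.hrv_baseline.mean_hr_bpm:.1f} -> {r.hrv_stress.mean_hr_bpm:.1f} bpm, "
      f"RMSSD {r.hrv_baseline.rmssd_ms:.1f} -> {r.hrv_stress.rmssd_ms:.1f} ms")
```

```
CT_3mm baseline 264.6 um, stress 278.4 um, change +13.8 um
HR 62.7 -> 74.0 bpm, RMSSD 33.4 -> 22.8 ms
```

The measured CT change recovers the simulated +10 µm effect to within the
per-subject measurement noise (a few µm at the reduced 64×64×256 test
geometry); HR rises and RMSSD falls as in a genuine stress session. A full
cohort (default n = 33, per-subject ΔCT ~ Normal(3.3, 6.1) µm) runs through
`choromet.pipeline.simulate_cohort`, which returns the per-endpoint paired
comparisons, Bland–Altman repeatability and the correlation battery.

File-based processing uses the same functions through the CLI:

```bash
choromet simulate --seed 1 --out-dir subj01 --delta-ct-um 10
choromet run manifest.csv --out-dir report/
```

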