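# renofur

Quantitative analysis of dynamic ⁹⁹ᵐTc-MAG3 renography for small-animal
studies: fractional uptake rate (FUR) and differential renal function (DRF)
from region-of-interest time-activity curves, plus a synthetic renography
generator with closed-form ground truth and the longitudinal statistics
needed for follow-up cohorts (e.g. ischemia-reperfusion models).

## The problem and the method

A dynamic renography study records a planar gamma-camera frame every 5 s for
10 min after a MAG3 bolus. From ROI curves over the kidneys, their
backgrounds, the heart (blood pool), the whole body and the injection site,
the package computes a renal clearance surrogate that is robust to animal
size, camera and examination timing:

**FUR = P(0) · (k_l + k_r) / ID**, reported in %ID/min,

where

- *k_l*, *k_r* (1/s) are the slopes of the linear uptake (LU) segment of the
  Patlak-Rutland plot of each background-corrected kidney curve *R(t)*
  against the plasma curve *P(t)* — here plotted as *y = R/P* versus
  *x = ∫₀ᵗP / P*, so the slope carries units of 1/s;
- *P(0)* (counts/s) is the plasma curve back-extrapolated to injection time
  with a mono-exponential fit over the combined extent of the two LU
  segments;
- *ID* (counts/s) is the injected dose, estimated as the whole-body count
  rate averaged over the first minute minus the injection-site residual.

The LU segment is found automatically from the impulse retention function
(IRF), obtained by constrained least-squares deconvolution (*H* ≥ 0,
non-increasing, lightly smoothed): the dominant IRF plateau before the
renogram peak marks the uptake phase, its height equals the PR slope in
theory, and an IRF-derived intercept enters the LU fit as a pseudo data
point. DRF — each kidney's percent of total uptake — is computed three ways
(renogram integrals, PR slopes, IRF plateau heights) whose agreement is a
built-in quality check; split FUR is total FUR × DRF/100.

A standalone attenuation tool quantifies how a depth difference between the
kidneys distorts the split under a linear attenuation coefficient
(0.12 cm⁻¹ for ⁹⁹ᵐTc); the main pipeline applies no depth correction.

## Worked example

```python
import renofur as rf

config = rf.SimulationConfig()            # 120 frames x 5 s, two kidneys
study = rf.simulate_study(config)         # named ROI curves + ground truth
result = rf.analyze_study(study.curves)   # full FUR/DRF pipeline

print(f"true  FUR total {study.truth.fur_total_true:.2f} %ID/min, "
      f"DRF {study.truth.drf_true[0]:.1f}:{study.truth.drf_true[1]:.1f}")
print(f"est.  FUR total {result.fur_total:.2f} %ID/min "
      f"(L {result.fur_left:.2f}, R {result.fur_right:.2f})")
for name, pair in result.drf.as_dict().items():
    print(f"      DRF {name:18s} {pair[0]:.1f}:{pair[1]:.1f}")
```

prints

```
true  FUR total 33.18 %ID/min, DRF 44.3:55.7
est.  FUR total 33.11 %ID/min (L 14.50, R 18.61)
      DRF renogram_integral  44.2:55.8
      DRF pr_slope           43.8:56.2
      DRF irf_plateau        44.3:55.7
```

The default generator emulates a healthy baseline study (total FUR
33.2 %ID/min split 44.3:55.7 between left and right kidney); on this
noise-free study the pipeline recovers the total within 0.3% and the split
within 0.7 percentage points, with all three DRF methods inside the
5-point QC band.

The same pipeline is scriptable from the shell:

```sh
renofur simulate -o study/ --noise poisson --seed 7
renofur analyze study/curves.csv -o out/        # result.json + QC figures
renofur cohort manifest.yaml -o tables/         # mean ± SEM follow-up tables
```

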