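# betapet

Penalized-likelihood PET simulation and beta-sweep quantification.

Modern clinical PET reconstructs images with Bayesian penalized-likelihood
(BPL/BSREM) algorithms whose single user-facing knob is the penalty weight
**beta**: it trades noise against quantitative accuracy, and the "right"
value is disputed, especially for small pulmonary nodules whose uptake is
already suppressed by the partial-volume effect (PVE). `betapet` is a
fully synthetic, desk-scale laboratory for that question. It implements

* a digital NEMA-IQ-like six-sphere phantom (10–37 mm, 4:1 sphere to
  background, 13.2 kBq/mL) and a clinical-lesion phantom (5.7–29.4 mm
  nodules at 4:1 contrast with a liver-like noise reference region);
* a finite-resolution Poisson acquisition model (image-space Gaussian PSF,
  parallel-beam sparse projector with exact adjoint);
* BSREM-style maximization of the penalized Poisson likelihood

      x^ = argmax_{x>=0}  sum_i [ y_i log(Px)_i - (Px)_i ] - beta R(x),

  with the relative difference penalty

      R(x) = sum_j sum_{k in N_j} w_j w_k (x_j - x_k)^2
                                  / (x_j + x_k + gamma |x_j - x_k|),

  swept over beta = 100..1000 in steps of 50 (with one subset and
  beta = 0 the update is exactly ML-EM);
* the standard quantification chain: recovery coefficient
  RC = A_M/A_K x 100%, contrast recovery CR = (A_M/A_B - 1)/(C - 1) x 100%,
  background variability BV = SD_B/C_B x 100% over the 12 x 5 = 60
  background-ROI scheme, SUV_bw = r/(a'/w) with SUVmean/SUVmax/SUVpeak
  (1 mL peak kernel), SNR and CNR;
* the recovery-coefficient regression partial-volume correction (PVC):
  per beta, an OLS line RC = slope·d + intercept over the six spheres,
  used to predict a nodule's RC from its diameter and divide its SUVs;
* study endpoints: Pearson correlation of SUVs with beta, paired t-test
  between the beta extremes, Cohen's kappa between two readers, and
  aggregation of a packaged two-reader subjective score table.

The package is aimed at physicists and methodologists who want to probe
how beta-dependent bias and noise propagate into SUV metrics and whether
a phantom-derived PVC stabilizes them — without scanner time.

## Worked example

Fit the per-beta PVC model from a noise-free phantom sweep and correct a
17 mm sphere:

```python
from betapet.study import SweepConfig, run_sweep
from betapet.pvc import fit_rc_models, predict_rc

nema = run_sweep(SweepConfig(mode="nema", noiseless=True, seed=1))
at350 = nema.query("beta == 350")[["diameter_mm", "rc_pct", "cr_pct", "bv_pct"]]
print(at350.round(2).to_string(index=False))
model = fit_rc_models(nema)[350.0]
print(f"slope {model.slope:.3f} intercept {model.intercept:.2f} r2 {model.r_squared:.3f}")
for d in (17.0, 5.7):
    p = predict_rc(model, d)
    print(f"d={d} mm: RC={p.rc:.3f} extrapolated={p.extrapolated}")
```

prints (a few minutes on one CPU):

```
 diameter_mm  rc_pct  cr_pct  bv_pct
        10.0   29.90    5.82    0.83
        13.0   32.20    8.83    0.79
        17.0   36.08   13.90    0.75
        22.0   50.26   32.44    0.67
        28.0   62.16   48.06    0.58
        37.0   71.49   60.63    1.00
slope 1.680 intercept 11.46 r2 0.972
d=17.0 mm: RC=0.400 extrapolated=False
d=5.7 mm: RC=0.210 extrapolated=True
```

Reading this: at beta 350 only ~36% of the 17 mm sphere's true
concentration is recovered (PVE), recovery grows with diameter, and the
fitted line (slope 1.68 %/mm, r² = 0.97) predicts RC = 0.400 for a 17 mm
lesion — dividing the measured mean by it recovers the true concentration
to within ~10%. The 5.7 mm prediction carries the `extrapolated` flag:
the phantom has no sub-centimeter sphere, a stated gap of this PVC.

Aggregating the packaged reader scores:

```python
from betapet.study import load_reader_scores, best_beta_by_group
print(best_beta_by_group(load_reader_scores()).to_string(index=False))
```

```
   group  reader  best_beta
10-30 mm       1      400.0
10-30 mm       2      400.0
  <10 mm       1      300.0
  <10 mm       2      300.0
```

Both readers prefer beta 300 for sub-centimeter nodules and 400 for
10–30 mm nodules — while the noise metrics alone (BV, SNR) keep improving
far beyond those values, which is the study's central tension.

The same stages are scriptable from the shell:

```sh
betapet simulate --spec phantom.yaml --out sim/ --seed 1
betapet reconstruct --counts sim/counts.nii --beta 350 --out recon.nii
betapet quantify --image recon.nii --beta 350 --out metrics.csv
betapet pvc fit --metrics metrics.csv --out rc_models.csv
betapet sweep --config sweep.yaml --out results/
betapet report --metrics results/metrics.csv --out report/
```

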