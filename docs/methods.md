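# Methods

## Scope and model

`betapet` is a desk-scale, fully synthetic re-creation of a PET
image-quality study built around the single user-facing knob of Bayesian
penalized-likelihood (BPL/BSREM-style) reconstruction: the penalty weight
beta. The pipeline is

1. digital phantom (NEMA-IQ-like six-sphere phantom, or a lesion field
   emulating small pulmonary nodules),
2. finite-resolution Poisson acquisition (parallel-beam),
3. penalized-likelihood reconstruction with the relative difference
   penalty, swept over beta = 100..1000 in steps of 50,
4. quantification (RC/CR/BV on the phantom; SUVmean/SUVmax/SUVpeak, SNR,
   CNR on lesions),
5. recovery-coefficient (RC) regression partial-volume correction (PVC)
   and the statistical endpoints (Pearson r vs beta, paired t between the
   beta extremes, Cohen's kappa on reader scores).

Everything is synthetic; no scanner data are used. Conclusions supported
by the test suite are therefore *trend* statements (directions of change
across the sweep), never absolute agreement with any particular scanner.

## Acquisition model

The scanner stand-in is a slice-by-slice parallel-beam projector realized
as an explicit sparse matrix (pixel-driven, linear interpolation onto
radial bins). This makes forward projection exactly linear and gives the
reconstruction an exact adjoint. Resolution is modeled as an isotropic
Gaussian point-spread function applied in image space *before* projection
(default FWHM 4.5 mm). The value is a free simulator parameter, chosen as
a plausible whole-body PET reconstructed resolution; it is the sole source
of the partial-volume effect. Attenuation, scatter, randoms, TOF and
detector geometry are not simulated: the model emulates fully corrected
data directly.

Expected counts are `count_scale` times the line integral (kBq·mm/mL);
measured data are independent Poisson draws per bin. The default
`count_scale = 0.03` yields roughly 10^5 counts per slice on the NEMA
phantom — a deliberately modest statistic so that the noise-driven
behavior of SUVmax (inflation at weak regularization) is visible, as it
is in short clinical acquisitions.

## Reconstruction

The objective is the Poisson log-likelihood minus beta times the relative
difference penalty (RDP)

    R(x) = sum_j sum_{k in N_j} w_j w_k (x_j - x_k)^2
                                / (x_j + x_k + gamma |x_j - x_k|).

* gamma defaults to 2.0 (the conventional edge-preservation setting in
  the penalty literature; exposed as a parameter).
* The neighborhood defaults to 6-connectivity in 3-D (8 in-plane for
  single-slice volumes); 18 and 26 are available. Pair weights are
  inverse Euclidean center distance, normalized so the nearest neighbor
  has weight 1.
* Pairs with a zero denominator (both voxels zero) contribute zero — the
  penalty's removable singularity.

The optimizer is block-sequential preconditioned gradient ascent with the
EM preconditioner x/s (s the subset sensitivity image) and relaxation
alpha_n = alpha0/(1 + decay·n). With one subset, beta = 0 and unit step
this is *exactly* ML-EM, which anchors the implementation: count
preservation and the EM fixed point are testable identities. The
objective is evaluated every full iteration; a decreasing iteration is
rolled back and the relaxation halved, and only if that safeguard is
exhausted is the run flagged as a convergence failure. A floor of 1e-9
kBq/mL keeps logarithms and the RDP denominator defined. Defaults: 25
iterations, 6 subsets — enough for the trend statements on the default
grid to stabilize.

Vendor beta magnitudes are not calibrated to this simulator. The sweep
grid 100..1000 is kept for interface parity and mapped onto this count
level by `beta_scale` (default 0.002), chosen once so that the swept
range covers visible-but-not-destructive regularization: background noise
drops severalfold from beta 100 to 1000 while the 37 mm sphere still
recovers most of its contrast. Absolute RC/SUV values are therefore not
comparable to any vendor console; trends across the sweep are.

## Phantoms

*NEMA-like phantom.* Six spheres (10, 13, 17, 22, 28, 37 mm) at a 4:1
activity ratio (13.2 kBq/mL in the spheres, 3.3 in the background) on a
52 mm ring inside an elliptical body (semi-axes 125 x 98 mm) — a modest
scale-down of the physical phantom so the default 96 x 96 grid at 2.73 mm
(slice thickness 2.8 mm, 32 slices) holds it with room for background
ROIs. The full 256 x 256 matrix is available by configuration.
Voxelization is corner-subsampled fractional fill (3^3 subsamples by
default), which brings the rasterized 37 mm sphere volume within 1% of
(pi/6)·37^3 on a 1 mm grid.

*Clinical-lesion phantom.* Spherical lesions at 4:1 contrast in a uniform
low-uptake body (1.0 kBq/mL), placed by seeded rejection sampling with
clearance constraints, plus a uniform liver-like cylinder (1.5 kBq/mL)
used only as the noise reference region. The default catalog draws 7
sub-centimeter (5.7–9.9 mm) and 16 medium (10–29.4 mm) diameters
uniformly, mirroring the two lesion-size groups of a small-nodule cohort.
The SUV context fixes injected dose / body weight so that the background
concentration maps to SUV = 1.

What the generator does **not** emulate: anatomical texture, respiratory
motion, spill-in from adjacent hot organs, attenuation/scatter residuals,
TOF weighting, inter-patient variability. Passing tests therefore show
that the *analysis chain* reproduces the physics-driven trends, not that
it would reproduce any particular patient measurement.

## Quantification choices

* VOIs are drawn once at the 42% of maximum threshold on the reference
  reconstruction (beta 350 by default) and propagated unchanged to every
  other beta. Thresholding is bounded by the object's known (CT-like)
  extent: in a warm background, 42% of a partial-volume-suppressed
  maximum can fall below the background level, and an unbounded connected
  component would flood the phantom. The bound mirrors the operator
  delineating within the object's CT footprint.
* Background ROIs follow the 12-positions x 5-slices = 60 scheme; the 12
  centers are found greedily at the 37 mm diameter and reused
  concentrically for the smaller diameters, as in the standard phantom
  analysis.
* SUVpeak is the maximum 1 mL spherical-kernel mean over kernel centers
  inside the VOI (kernel diameter 12.4 mm; ties resolved in scan order).
* SNR = lesion SUVmax / SD of SUVs in 1 cm spherical VOIs in the
  reference region (mean of three deterministic placements). CNR uses a
  background annulus between 1.5x and 2.5x the VOI-equivalent radius,
  clipped to lesion-free background.

## Partial-volume correction

Per beta, ordinary least squares of RC (%) on sphere diameter (mm) over
the six spheres, fitted at the single 4:1 contrast. A lesion's RC is
predicted from its true (catalog) diameter with the matching beta's
model, clamped to (0.05, 1.0], and its SUVs are divided by it.
Predictions outside the fitted 10–37 mm range carry an `extrapolated`
flag — every sub-centimeter lesion is such an extrapolation, an
acknowledged gap of the method. Because the true RC-vs-diameter curve is
concave, the straight line over-predicts RC at mid diameters; the 17 mm
self-consistency check recovers truth to ~10%, which is the accuracy
ceiling of the linear simplification, not a fitting defect.

## Why BV needs noise

Background variability (SD/mean over the 60 background ROI means) is a
noise metric. On noisy data, raising beta suppresses the Poisson noise
and BV falls — the behavior the package reproduces on its replicated
noisy sweep. On *noiseless* (expected-count) data the only background
variation left is regularization-induced bias: the RDP drags the
background near spheres and near the body edge, and that bias spread
*grows* with beta (from ~0.4% to ~2.5% over the sweep for the 37 mm ROI
set). The same mechanism produces a late BV uptick for the largest ROI
sets even on noisy data, because on the desk-scale grid those ROIs sit
close to the body edge. The monotone-decrease claims are therefore tested
on the noisy sweep (strictly for the 10–22 mm ROI sets, endpoint-wise for
all), while the noiseless sweep carries the RC/CR monotonicity and
diameter-ordering claims.

## Numerical and testing conventions

* All randomness flows through explicit integer seeds; reconstruction is
  deterministic given (counts, grid, parameters).
* Oracles are independent of the code paths they check: the RDP against a
  brute-force double loop, its gradient against central finite
  differences (away from the |x| kinks, where the penalty is not
  differentiable), SUVpeak against exhaustive search, the statistics
  against textbook formulas, ML-EM against its count-preservation and
  fixed-point identities, and the projector against the analytic
  chord-length profile of a disc.
* Default problem sizes (96 x 96 x 32 grid; 19-beta noiseless sweep; 7-beta
  3-replicate noisy sweep; 19-beta 3-replicate clinical sweep) keep a full
  run of the end-to-end suite in the tens of minutes on one CPU.

## Known limitations

* Single-contrast (4:1) PVC only; no multi-contrast lookup.
* No image-domain PVC (deconvolution/GTM); the correction is regional.
* Parallel-beam 2-D projection per slice; no axial cross-talk beyond the
  PSF.
* Beta values are not comparable to any vendor's scale.
* Reader scores are a fixed fixture; the subjective reading process is
  not simulated, only aggregated.
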