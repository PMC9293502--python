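# Methods

This note documents the models implemented in `renalbold`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Fuzzy clustering engines

All four engines minimize an objective over a row-stochastic membership
matrix U (n masked pixels × c clusters) and intensity centers y_k by
alternating exact coordinate updates, stopping when the maximum absolute
membership change falls below `tol` (default 1e-5) or after `max_iter`
(default 100) iterations. The fuzzifier s defaults to 2, the standard
choice that balances partition softness against segmentation sharpness.

- **FCM.** J = Σ_k Σ_i u_ik^s h_ik with h_ik = (p_i − y_k)². Both
  half-steps are exact minimizers, so the recorded objective trace is
  mathematically nonincreasing.
- **KFCM.** J = Σ_k Σ_i u_ik^s · 2(1 − K(p_i, y_k)) with the Gaussian
  RBF K(x,y) = exp(−(x−y)²/σ²). The membership update uses the
  kernel-induced distance 1 − K (the factor 2 cancels in the
  normalization); the center update is one Gaussian mean-shift step
  y_k ← Σ u^s K p / Σ u^s K, which is monotone for this objective by the
  mean-shift ascent property. Bandwidth σ = "auto" resolves to the
  standard deviation of the masked intensities (scale-free; falls back
  to 1 for constant data). 1 − K is evaluated as `-expm1(-d²/σ²)` so the
  large-σ limit degrades gracefully to the Euclidean engine instead of
  losing precision to cancellation.
- **BCFCM.** Adds (α/|N_i|) Σ_{r∈N_i} (p_r − y_k)² inside the bracket,
  where N_i is the Chebyshev-radius-1 neighborhood (3×3 minus center)
  clipped at image edges and restricted to masked pixels; |N_i| is the
  actual neighbor count, so border pixels are not over- or
  under-regularized. α defaults to 0.85. α = 0 reduces exactly to FCM.
- **EnFCM.** Builds the filtered image ξ_i = (p_i + α·mean_{N_i} p)/(1+α),
  quantizes it to at most `n_bins` (default 256) gray levels — losslessly
  when the distinct values fit, else uniform bins represented by their
  centers — and clusters the levels with their counts as weights. With
  α = 0 and lossless bins this is an exact reweighting of pixel-level
  FCM; in general it reproduces the pixel-level solution up to
  quantization at class margins at a small fraction of the distance
  evaluations (instrumented in `ClusteringResult.n_distance_evals`).

**Initialization.** Default "quantile" places centers at the
(k + 0.5)/c intensity quantiles — deterministic, permutation-invariant,
and exactly reproducible; "random" draws c distinct observed intensities
using the config seed. **Degenerate cases:** a pixel at zero distance
from a center gets full membership in the lowest-index such center; a
cluster losing all membership mass raises an error naming it; constant
images and n < c are rejected up front. Defuzzification is per-pixel
argmax with ties to the lowest cluster index; pixels outside the mask
are labeled −1.

**Default c = 3** reflects the three intensity classes of a coronal
kidney BOLD slice: background, cortex, medulla.

## Validity indices

Vpc = (1/n) ΣΣ u² ∈ [1/c, 1] and Vpe = −(1/n) ΣΣ u log₂ u ∈ [0, log₂ c],
with 0·log 0 := 0, computed over masked pixels only. A hard partition
attains exactly (1, 0).

A caveat worth stating explicitly: Vpc/Vpe measure partition crispness
*under each engine's own distance geometry*, so cross-engine comparisons
are biased. Because g(x) = 1 − e^{−x/σ²} is concave with g(0) = 0,
g(a)/g(b) ≥ a/b for a ≤ b: kernel-induced near/far distance ratios are
always closer to 1 than their Euclidean counterparts, so at the same
centers KFCM memberships are strictly fuzzier than FCM memberships and
Vpc(KFCM) < Vpc(FCM) whenever both engines converge to comparable
solutions — at any finite bandwidth. The neighborhood term of BCFCM
adds a nearly common positive offset to all distances and fuzzes
memberships the same way. Dice against ground truth is the
geometry-neutral comparison and is what the engine ordering claims in
this package rest on; EnFCM, which shares FCM's distance geometry while
denoising the histogram, does also improve Vpc.

## Relaxometry

Signal model: S(TE) = S0·exp(−TE·R2\*), fit per pixel by weighted least
squares of ln S on TE with weights S² (the delta-method variance of
ln S is σ²/S², so these are the standard linearization weights).
TE is carried in ms; R2\* is reported in 1/s (factor 1000). Pixels with
any non-positive echo signal or a non-positive fitted decay rate are
excluded from `fit_mask` and carry NaN. With exactly two echoes the fit
coincides with the closed form T2\* = (TE₂−TE₁)/ln(S₁/S₂).

At simulation SNR 20 (noise σ = mean S0 / 20) this estimator is close
to the information bound: over the default test fixture the
two-parameter Cramér–Rao bound gives a median relative R2\* standard
error of ≈ 7.9% (hence a median absolute error floor of ≈ 5.3% for any
unbiased estimator), and the weighted log-linear fit measures ≈ 5–6%.
Sub-5% median error at that noise level would require a different
acquisition or a nonlinear maximum-likelihood fit, which is outside
this package's scope.

**ROI protocol.** The compartment value for one kidney is the unweighted
mean of per-ROI means (not a pooled pixel mean), matching the manual
workflow of drawing nine small ROIs on the upper/middle/lower poles per
compartment; counts other than nine warn but do not fail. MCR =
RM-R2\*/RC-R2\* is dimensionless and invariant to global signal scaling.

## CKD-EPI eGFR

eGFR = 141·min(Scr/κ,1)^γ·max(Scr/κ,1)^{−1.209}·0.993^Age·1.018[female]·1.159[black],
κ = 0.7 (women) / 0.9 (men), γ = −0.329 / −0.411. Scr is taken in
mg/dL; values reported in µmol/L divide by 88.4 (`scr_mgdl_from_umol`,
or `--units umol` at the CLI). The function is strictly decreasing in
Scr, which the cohort generator exploits to invert it by Brent's method
on Scr ∈ [0.1, 20] mg/dL.

## Synthetic generators

All generators are pure functions of their spec and seed
(`numpy.random.default_rng`), so replays are bit-identical.

**Phantom.** A nested-ellipse cartoon of a coronal kidney slice:
background 0, an outer cortical ring at 140, an inner medullary ellipse
at 70, with the kidney filling most of the field of view (outer
semi-axes 0.92/0.78, inner 0.52/0.40 of the half-extent). Two
considerations fix these defaults. First, with the spatial engines'
α = 0.85, pixels on a sharp two-class edge flip to the middle-intensity
class whenever the neighborhood mixture favors it; at a 50/50
background/cortex edge the margin is
D_med − D_cortex = (C − m)[(C − m) − αm], so edge pixels are classified
correctly only if cortex > (1+α)·medulla — the 2:1 contrast satisfies
this (and is plausible for a short-TE gradient-echo image where cortex
is markedly brighter than medulla). Second, comparably sized classes
keep the deterministic quantile initialization from seeding two centers
inside one class. Noise is Gaussian or Rician (magnitude of a complex
signal with iid Gaussian parts — strictly nonnegative) with
σ = (max class mean − min class mean)/SNR; the bias field is a smooth
multiplicative field 1 + a·g with g a unit-peak Gaussian-smoothed random
field and a the fractional amplitude (0.2 models visible coil shading).
The phantom does **not** model partial-volume averaging, anatomy beyond
two compartments, k-space acquisition, or motion; passing tests on it
demonstrate correctness of the estimators under the stated intensity
model, not clinical performance.

**Echo series.** S(TE) = S0·exp(−TE·R2\*/1000) plus optional noise
(σ = mean S0 / SNR). The default protocol is 12 echoes starting at
TE₁ = 3.8 ms with 4.86 ms spacing (so the second echo falls at 8.66 ms,
the echo conventionally used for ROI drawing), a typical renal
multi-gradient-echo acquisition at 3 T.

**Cohort.** Two groups: diabetic nephropathy (DN, 57/121 of subjects by
default) and diabetes without nephropathy (DM). Group eGFR means
54.65 / 92.03 mL/min/1.73 m² and hemoglobin means 108.65 / 119.8 g/L;
the standard deviations (15/12 for eGFR, 12 for Hb) are assumptions, as
is the age distribution (57 ± 6.7 y, clipped to 30–80) and the 60/40
male/female mix. Each imaging covariate is generated as
mean + sd·(r·z + √(1−r²)·ε) with z the pooled eGFR z-score, so its
population correlation with eGFR equals the target r; defaults are
−0.57 (RC-R2\*), −0.62 (RM-R2\*), +0.49 (RC-D), +0.38 (RM-D) on
marginal scales of 19 ± 4 and 25 ± 4 s⁻¹ for R2\* and 2.0 ± 0.3 /
1.8 ± 0.3 (10⁻³ mm²/s) for the diffusion covariates. The cortical R2\*
scale is given the larger relative eGFR effect so that the derived
per-subject MCR = RM/RC comes out lower in the DN group, as observed
clinically; the exact group MCR means are a consequence, not a target —
hitting the four correlation targets takes precedence. Serum creatinine
is back-solved from each subject's eGFR, age and sex, so
`egfr_ckd_epi(scr, …)` reproduces the drawn eGFR to numerical precision.
The binary outcome is drawn with probability logistic in −z (worse
outcomes at lower eGFR); it emulates only a prognosis label's
association structure, not survival time.

## Numerical conventions

- Convergence is declared on membership change, not objective change;
  both the trace and the iteration count are returned.
- Objective traces are evaluated after both half-updates of an
  iteration; coordinate descent guarantees they are nonincreasing, and
  tests allow 1e-10 absolute slack for floating-point summation.
- NIfTI affines are passed through untouched; voxel indices are
  0-based. All CLI writers are atomic (write to a temp sibling, then
  rename), so failed runs leave no partial outputs.
- Test problem sizes (128² phantoms, 500-pixel relaxometry fixtures,
  n = 500 cohorts) were chosen as the smallest sizes at which sampling
  error is comfortably below the tolerances being asserted.

## Known limitations

- No bias-field *estimation*: BCFCM here regularizes spatially but does
  not model a separate multiplicative field.
- Rician noise is generated but the relaxometry fit is not
  Rician-bias-corrected; at very low SNR the fitted R2\* is biased.
- Cross-engine Vpc/Vpe comparisons favor Euclidean-geometry engines by
  construction (see the validity section).
- The cohort generator reproduces first-order correlation structure
  only; it makes no claim about multivariate regression coefficients.
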