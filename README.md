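# renalbold

Fuzzy C-means family segmentation and R2\* quantification for renal
BOLD-MRI, with seeded synthetic phantoms and cohort simulation.

Blood-oxygen-level-dependent (BOLD) MRI assesses kidney oxygenation
non-invasively: deoxyhemoglobin is paramagnetic, so tissue hypoxia raises
the apparent transverse relaxation rate R2\* = 1/T2\*. Tracking cortical
and medullary R2\* is of growing interest in diabetic nephropathy, where
chronic medullary hypoxia drives disease progression. This package is
aimed at imaging researchers who want a tested, scriptable implementation
of the full quantitative chain — segmentation of the kidney image into
background / cortex / medulla, per-pixel relaxometry, regional averaging,
and the clinical metrics the imaging is correlated against.

## What it implements

**Segmentation.** Four fuzzy clustering engines sharing one alternating
minimization loop over an n × c membership matrix U (rows on the
1-simplex) and centers y_k, with fuzzifier s (default 2):

- `fit_fcm` — classical fuzzy C-means,
  J = Σ_k Σ_i u_ik^s (p_i − y_k)², with the closed-form updates
  u_ik = [Σ_z (h_ik/h_iz)^{1/(s−1)}]^{−1} and
  y_k = Σ_i u_ik^s p_i / Σ_i u_ik^s;
- `fit_kfcm` — kernelized FCM with a Gaussian RBF
  K(x,y) = exp(−(x−y)²/σ²) and kernel-induced distance 2(1 − K),
  robust to outlying intensities;
- `fit_bcfcm` — bias-corrected FCM with the neighborhood regularizer
  (α/N_R) Σ_{r∈N_i} (p_r − y_k)², robust to noise and coil
  inhomogeneity;
- `fit_enfcm` — efficiency-enhanced FCM, clustering the gray-level
  histogram of a linearly filtered image instead of individual pixels.

Partitions are scored with the Bezdek partition coefficient
Vpc = (1/n) ΣΣ u² and the partition entropy
Vpe = −(1/n) ΣΣ u log₂ u, and segmentations are compared against ground
truth with per-class Dice after optimal (Hungarian) label matching.

**Relaxometry.** Mono-exponential multi-echo fitting
S(TE) = S0·exp(−TE·R2\*) by S²-weighted log-linear least squares; the
cortex/medulla protocol averages nine per-ROI means per compartment per
kidney and forms the medulla-to-cortex ratio MCR = RM-R2\*/RC-R2\*.

**Clinical metrics.** The CKD-EPI creatinine equation
eGFR = 141·min(Scr/κ,1)^γ·max(Scr/κ,1)^{−1.209}·0.993^Age·1.018[female]·1.159[black]
(κ = 0.7/0.9, γ = −0.329/−0.411 for women/men) and the Pearson
product-moment correlation.

**Synthetic data.** Seeded generators for nested-ellipse kidney phantoms
(piecewise-constant classes, Gaussian/Rician noise, smooth multiplicative
bias field), multi-gradient-echo series with known R2\* maps, and a
two-group clinical cohort whose imaging covariates carry prescribed
correlations with eGFR (serum creatinine is back-solved through the
CKD-EPI equation). See `docs/methods.md` for the modeling details.

## Worked example

```python
import numpy as np
from renalbold import (ClusteringConfig, PhantomSpec, fit, make_phantom,
                       make_echo_series, fit_t2star, mcr, egfr_ckd_epi,
                       partition_coefficient, partition_entropy)
from renalbold.validity import mean_dice

img, truth = make_phantom(PhantomSpec(
    shape=(128, 128), noise_model="gaussian", snr=10.0, bias_field=0.2, seed=0))
print("engine   dice    Vpc     Vpe")
for engine in ("fcm", "kfcm", "bcfcm", "enfcm"):
    res = fit(img, ClusteringConfig(n_clusters=3), engine)
    print(f"{engine:<8} {mean_dice(res.labels, truth):.4f}  "
          f"{partition_coefficient(res.membership):.4f}  "
          f"{partition_entropy(res.membership):.4f}")

r2 = np.full((64, 64), 20.0); r2[20:44, 20:44] = 23.8
pm = fit_t2star(make_echo_series(np.full((64, 64), 1000.0), r2))
rc = pm.r2star[r2 == 20.0].mean(); rm = pm.r2star[r2 == 23.8].mean()
print(f"RC-R2* = {rc:.2f} 1/s, RM-R2* = {rm:.2f} 1/s, MCR = {mcr(rm, rc):.2f}")
print(f"eGFR(male, Scr 2.11 mg/dL, 57 y) = {egfr_ckd_epi(2.11, 57, 'male'):.1f} mL/min/1.73m2")
```

prints

```
engine   dice    Vpc     Vpe
fcm      0.9832  0.9031  0.2843
kfcm     0.9838  0.8444  0.4450
bcfcm    0.9893  0.8713  0.3842
enfcm    0.9900  0.9415  0.1820
RC-R2* = 20.00 1/s, RM-R2* = 23.80 1/s, MCR = 1.19
eGFR(male, Scr 2.11 mg/dL, 57 y) = 33.7 mL/min/1.73m2
```

On a noisy, bias-corrupted phantom every engine recovers the three
tissue classes with Dice ≈ 0.98–0.99, and the spatially regularized
variants beat plain FCM; the relaxometry chain recovers the simulated
cortical (20 s⁻¹) and medullary (23.8 s⁻¹) relaxation rates exactly,
giving a whole-kidney MCR of 1.19; the eGFR line shows the advanced
renal impairment implied by a creatinine of 2.11 mg/dL (187 µmol/L) in a
57-year-old man.

## Command line

The same pipeline is exposed as `renalbold` with subcommands
`segment`, `compare`, `relaxometry`, `egfr`, `phantom` and `cohort`
(NIfTI/PNG in, NIfTI/CSV/JSON out; every run writes a JSON report with
the config echo and seed needed to reproduce it):

```sh
renalbold phantom --shape 128 128 --noise gaussian --snr 10 --out-prefix ph
renalbold segment ph_image.nii --engine kfcm --clusters 3 --out-prefix seg
renalbold egfr --scr 186.3 --units umol --age 57 --sex male
```

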