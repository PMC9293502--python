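"""Seeded synthetic data: kidney-like phantoms, echo series and cohorts.

These generators are the test bed for the whole pipeline.  They emulate

* a coronal kidney slice as nested ellipses — an outer cortical ring
  around an inner medullary ellipse on a dark background — with optional
  Gaussian/Rician noise and a smooth multiplicative bias field of the
  kind produced by surface-coil sensitivity;
* the multi-gradient-echo acquisition as a mono-exponential forward
  model ``S(TE) = S0 exp(-TE R2*/1000)`` plus noise, so fitted R2* maps
  have a known ground truth;
* a two-group (diabetic nephropathy vs diabetes-only) clinical cohort
  whose imaging covariates carry a prescribed Pearson correlation with
  eGFR (R2* covariates negative, diffusion covariates positive), with
  serum creatinine back-solved from eGFR through the CKD-EPI equation.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .clinical import egfr_ckd_epi
from .clustering import IntensityImage, InvalidInputError
from .relaxometry import EchoSeries


class InvalidSpecError(ValueError):
    """Raised for phantom/cohort specs that cannot be realized."""


# ---------------------------------------------------------------------------
# Intensity phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Nested-ellipse kidney phantom: background / cortex / medulla.

    ``class_means`` are the noiseless intensities of the three classes.
    ``outer_axes`` / ``inner_axes`` are ellipse semi-axes as fractions of
    the image half-extent.  ``snr`` scales the noise: sigma =
    (max mean - min mean) / snr.  ``bias_field`` is the peak fractional
    amplitude of a smooth multiplicative inhomogeneity.
    """

    shape: Tuple[int, int] = (128, 128)
    class_means: Tuple[float, float, float] = (0.0, 140.0, 70.0)  # bg, cortex, medulla
    outer_axes: Tuple[float, float] = (0.92, 0.78)
    inner_axes: Tuple[float, float] = (0.52, 0.40)
    noise_model: str = "none"  # "none" | "gaussian" | "rician"
    snr: float = 10.0
    bias_field: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(set(self.class_means)) != 3:
            raise InvalidSpecError("class means must be distinct")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise InvalidSpecError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise InvalidSpecError("snr must be > 0 when noise is enabled")
        if not (0 < self.inner_axes[0] < self.outer_axes[0] <= 1
                and 0 < self.inner_axes[1] < self.outer_axes[1] <= 1):
            raise InvalidSpecError("need 0 < inner axes < outer axes <= 1")


def _ellipse_mask(shape, axes_frac) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = axes_frac[0] * h / 2.0, axes_frac[1] * w / 2.0
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _smooth_bias(shape, amplitude, rng) -> np.ndarray:
    """Multiplicative field 1 + amplitude * g with g smooth in [-1, 1]."""
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma=min(shape) / 4.0)
    peak = np.max(np.abs(g))
    if peak > 0:
        g /= peak
    return 1.0 + amplitude * g


def make_phantom(spec: PhantomSpec) -> Tuple[IntensityImage, np.ndarray]:
    """Render the phantom; returns (image, ground-truth label grid).

    Labels: 0 background, 1 cortex, 2 medulla.  Bias field (if any) is
    applied multiplicatively before the noise.
    """
    if len(spec.shape) != 2:
        raise InvalidSpecError("phantom is 2D")
    outer = _ellipse_mask(spec.shape, spec.outer_axes)
    inner = _ellipse_mask(spec.shape, spec.inner_axes)
    labels = np.zeros(spec.shape, dtype=int)
    labels[outer & ~inner] = 1  # cortex ring
    labels[inner] = 2  # medulla
    if min(np.bincount(labels.ravel(), minlength=3)) == 0:
        raise InvalidSpecError("a phantom class has zero area")
    img = np.asarray(spec.class_means, dtype=float)[labels]

    rng = np.random.default_rng(spec.seed)
    if spec.bias_field:
        img = img * _smooth_bias(spec.shape, spec.bias_field, rng)
    if spec.noise_model != "none":
        sigma = (max(spec.class_means) - min(spec.class_means)) / spec.snr
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, sigma, spec.shape)
        else:  # rician: magnitude of a complex signal with iid Gaussian parts
            img = np.hypot(
                img + rng.normal(0.0, sigma, spec.shape),
                rng.normal(0.0, sigma, spec.shape),
            )
    return IntensityImage(values=img), labels


# ---------------------------------------------------------------------------
# Multi-echo forward model
# ---------------------------------------------------------------------------

# 12 gradient echoes: first TE 3.8 ms, spacing 4.86 ms (the 8.66 ms second
# echo is the one conventionally used for ROI drawing) — a typical renal
# BOLD multi-gradient-echo protocol at 3 T.
DEFAULT_ECHO_TIMES = tuple(round(3.8 + 4.86 * k, 2) for k in range(12))


def make_echo_series(
    s0_map: np.ndarray,
    r2star_map: np.ndarray,
    echo_times: Sequence[float] = DEFAULT_ECHO_TIMES,
    noise_model: str = "none",
    snr: float = 20.0,
    seed: int = 0,
    tr: Optional[float] = 100.0,
) -> EchoSeries:
    """Simulate a multi-gradient-echo series from known parameter maps.

    ``S(TE) = S0 exp(-TE * R2* / 1000)`` with TE in ms, R2* in 1/s.
    Noise sigma = mean(S0) / snr.
    """
    s0 = np.asarray(s0_map, dtype=float)
    r2 = np.asarray(r2star_map, dtype=float)
    if s0.shape != r2.shape:
        raise InvalidInputError(
            f"S0 shape {s0.shape} != R2* shape {r2.shape}"
        )
    te = np.asarray(echo_times, dtype=float)
    vols = s0[None] * np.exp(-te.reshape((-1,) + (1,) * s0.ndim) * r2[None] / 1000.0)
    if noise_model != "none":
        if noise_model not in ("gaussian", "rician"):
            raise InvalidSpecError(f"unknown noise model {noise_model!r}")
        if snr <= 0:
            raise InvalidSpecError("snr must be > 0 when noise is enabled")
        rng = np.random.default_rng(seed)
        sigma = float(np.mean(s0)) / snr
        if noise_model == "gaussian":
            vols = vols + rng.normal(0.0, sigma, vols.shape)
        else:
            vols = np.hypot(
                vols + rng.normal(0.0, sigma, vols.shape),
                rng.normal(0.0, sigma, vols.shape),
            )
    return EchoSeries(volumes=vols, echo_times=te, tr=tr)


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

# Group-level conditions emulated by default: DN (diabetic nephropathy)
# vs DM (diabetes without nephropathy).
DEFAULT_GROUPS = {
    "DN": {"n_frac": 57 / 121, "egfr_mean": 54.65, "egfr_sd": 15.0,
           "hb_mean": 108.65, "hb_sd": 12.0},
    "DM": {"n_frac": 64 / 121, "egfr_mean": 92.03, "egfr_sd": 12.0,
           "hb_mean": 119.8, "hb_sd": 12.0},
}

# Target Pearson correlations of each imaging covariate with eGFR, plus the
# marginal scale on which the covariate is generated.
DEFAULT_COVARIATES = {
    "rc_r2star": {"r": -0.57, "mean": 19.0, "sd": 4.0},  # 1/s
    "rm_r2star": {"r": -0.62, "mean": 25.0, "sd": 4.0},  # 1/s
    "rc_d": {"r": 0.49, "mean": 2.0, "sd": 0.3},  # 1e-3 mm^2/s
    "rm_d": {"r": 0.38, "mean": 1.8, "sd": 0.3},
}


@dataclass
class CohortSpec:
    """Two-group cohort with prescribed covariate–eGFR correlations."""

    n: int = 121
    dn_fraction: float = 57 / 121
    egfr_means: Tuple[float, float] = (54.65, 92.03)  # (DN, DM)
    egfr_sds: Tuple[float, float] = (15.0, 12.0)
    target_correlations: dict = field(
        default_factory=lambda: {k: v["r"] for k, v in DEFAULT_COVARIATES.items()}
    )
    male_fraction: float = 72 / 121
    age_mean: float = 57.0
    age_sd: float = 6.7
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise InvalidSpecError("cohort needs n >= 10")
        if not 0 < self.dn_fraction < 1:
            raise InvalidSpecError("dn_fraction must be in (0, 1)")
        for name, r in self.target_correlations.items():
            if not abs(r) < 1:
                raise InvalidSpecError(
                    f"target correlation for {name} must satisfy |r| < 1"
                )


def invert_egfr_for_scr(egfr: float, age: float, sex: str, black: bool = False) -> float:
    """Serum creatinine (mg/dL) producing the given eGFR for this subject.

    The CKD-EPI equation is strictly decreasing in Scr, so the root on
    [0.1, 20] mg/dL is unique; solved by Brent's method.
    """
    lo, hi = 0.1, 20.0
    f = lambda s: egfr_ckd_epi(s, age, sex, black) - egfr
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0 or f_hi > 0:
        raise InvalidSpecError(
            f"eGFR {egfr:.2f} not attainable for age {age:.0f} {sex} "
            f"within Scr in [{lo}, {hi}] mg/dL"
        )
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per subject.

    eGFR is drawn per group (clipped to the CKD-EPI-attainable range),
    each imaging covariate is a linear function of the pooled eGFR
    z-score plus independent Gaussian noise so its population correlation
    with eGFR equals the target, Scr is back-solved from eGFR, and a
    binary outcome is drawn with probability decreasing in eGFR.
    """
    rng = np.random.default_rng(spec.seed)
    n_dn = int(round(spec.n * spec.dn_fraction))
    groups = np.array(["DN"] * n_dn + ["DM"] * (spec.n - n_dn))

    egfr = np.empty(spec.n)
    hb = np.empty(spec.n)
    for g, mu, sd in zip(("DN", "DM"), spec.egfr_means, spec.egfr_sds):
        sel = groups == g
        egfr[sel] = rng.normal(mu, sd, sel.sum())
        hb[sel] = rng.normal(DEFAULT_GROUPS[g]["hb_mean"],
                             DEFAULT_GROUPS[g]["hb_sd"], sel.sum())
    egfr = np.clip(egfr, 8.0, 140.0)

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, spec.n), 30.0, 80.0)
    sex = np.where(rng.random(spec.n) < spec.male_fraction, "male", "female")

    z = (egfr - egfr.mean()) / egfr.std()
    covs = {}
    for name, params in DEFAULT_COVARIATES.items():
        r = spec.target_correlations.get(name, params["r"])
        eps = rng.standard_normal(spec.n)
        covs[name] = params["mean"] + params["sd"] * (
            r * z + np.sqrt(1.0 - r * r) * eps
        )

    scr = np.array([
        invert_egfr_for_scr(e, a, s) for e, a, s in zip(egfr, age, sex)
    ])
    outcome = (rng.random(spec.n) < 1.0 / (1.0 + np.exp(1.5 * z))).astype(int)

    return pd.DataFrame({
        "subject": np.arange(spec.n),
        "group": groups,
        "age": age,
        "sex": sex,
        "black": False,
        "scr": scr,  # mg/dL
        "egfr": egfr,  # mL/min/1.73 m^2
        "hb": hb,  # g/L
        **covs,
        "mcr": covs["rm_r2star"] / covs["rc_r2star"],
        "outcome": outcome,
    })
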