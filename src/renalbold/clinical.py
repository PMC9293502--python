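"""Clinical renal-function metrics: CKD-EPI eGFR and Pearson association.

The 2009 CKD-EPI creatinine equation estimates glomerular filtration rate
(mL/min/1.73 m^2) from serum creatinine (mg/dL), age, sex and an ancestry
adjustment:

    eGFR = 141 * min(Scr/kappa, 1)^gamma * max(Scr/kappa, 1)^-1.209
               * 0.993^Age * 1.018[female] * 1.159[black]

with kappa = 0.7, gamma = -0.329 for women and kappa = 0.9,
gamma = -0.411 for men.  Creatinine reported in umol/L divides by 88.4
to obtain mg/dL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .clustering import InvalidInputError

UMOL_PER_MGDL = 88.4


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input vector)."""


@dataclass
class PatientRecord:
    """One subject: labs, demographics and optional imaging covariates."""

    scr: float  # serum creatinine, mg/dL
    age: float  # years
    sex: str  # "female" | "male"
    black: bool = False
    hb: Optional[float] = None  # g/L
    rc_r2star: Optional[float] = None  # 1/s
    rm_r2star: Optional[float] = None  # 1/s
    rc_d: Optional[float] = None  # diffusion covariate, arbitrary units
    rm_d: Optional[float] = None
    outcome: Optional[int] = None  # binary prognosis label

    def __post_init__(self):
        if self.scr <= 0:
            raise InvalidInputError("scr must be > 0")
        if not 0 < self.age < 130:
            raise InvalidInputError("age must be in (0, 130)")
        if self.sex not in ("female", "male"):
            raise InvalidInputError("sex must be 'female' or 'male'")

    @property
    def egfr(self) -> float:
        return egfr_ckd_epi(self.scr, self.age, self.sex, self.black)


def egfr_ckd_epi(scr, age, sex, black=False):
    """CKD-EPI creatinine eGFR in mL/min/1.73 m^2.

    ``scr`` in mg/dL; ``sex`` is "female"/"male" (scalar, applied to the
    whole array if the other inputs are arrays).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise InvalidInputError("scr and age must be > 0")
    if sex == "female":
        kappa, gamma, sex_factor = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, gamma, sex_factor = 0.9, -0.411, 1.0
    else:
        raise InvalidInputError("sex must be 'female' or 'male'")
    ratio = scr / kappa
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** gamma
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * sex_factor
        * (1.159 if black else 1.0)
    )
    return float(out) if out.ndim == 0 else out


def scr_mgdl_from_umol(scr_umol):
    """Convert serum creatinine from umol/L to mg/dL (divide by 88.4)."""
    return np.asarray(scr_umol, dtype=float) / UMOL_PER_MGDL


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length vectors.

    Requires length >= 3 and nonconstant inputs (otherwise the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError("vectors must have equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float(stats.pearsonr(x, y).statistic)
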