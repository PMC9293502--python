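"""Multi-echo T2*/R2* relaxometry and the cortex/medulla ROI protocol.

The signal of a multi-gradient-echo BOLD acquisition is modeled as a
mono-exponential decay ``S(TE) = S0 exp(-TE * R2*)``; a per-pixel
log-linear least-squares fit of ln S against TE yields S0 and R2*
(TE in ms internally, R2* reported in 1/s, hence the factor 1000).

Regional quantification follows the manual workflow used for renal
BOLD-MRI: several small ROIs are drawn per kidney on the upper, middle
and lower poles of each compartment (nominally 9 per compartment per
side); the compartment value is the unweighted mean of the per-ROI mean
values, and the medulla-to-cortex ratio MCR = RM-R2* / RC-R2* summarizes
whole-kidney oxygenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .clustering import InvalidInputError


@dataclass
class EchoSeries:
    """A stack of >= 2 echo volumes sharing one grid, with TE metadata (ms)."""

    volumes: np.ndarray  # (n_echoes, *grid)
    echo_times: np.ndarray  # ms, strictly increasing
    tr: Optional[float] = None  # ms, metadata only

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float).ravel()
        if self.volumes.ndim < 2:
            raise InvalidInputError("volumes must be a stack of image grids")
        if self.volumes.shape[0] != self.echo_times.size:
            raise InvalidInputError(
                f"{self.volumes.shape[0]} volumes but "
                f"{self.echo_times.size} echo times"
            )
        if self.echo_times.size < 2:
            raise InvalidInputError("need at least 2 echoes")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise InvalidInputError("echo times must be positive and strictly increasing")

    @property
    def grid_shape(self) -> tuple:
        return self.volumes.shape[1:]


@dataclass
class ParametricMap:
    """Fitted S0 / T2* / R2* maps with a mask of successfully fitted pixels.

    Wherever ``fit_mask`` is set: t2star > 0 (ms) and r2star = 1000 / t2star
    (1/s).
    """

    s0: np.ndarray
    t2star: np.ndarray  # ms
    r2star: np.ndarray  # 1/s
    fit_mask: np.ndarray


@dataclass
class ROI:
    """One region of interest tagged with its anatomical placement."""

    mask: np.ndarray
    compartment: str  # "cortex" | "medulla"
    side: str  # "left" | "right"
    pole: str = "middle"  # "upper" | "middle" | "lower"
    label: Optional[int] = None


@dataclass
class ROISet:
    """The ROI collection for one subject (nominally 9 per compartment/side)."""

    regions: List[ROI] = field(default_factory=list)

    def select(self, compartment: str, side: str) -> List[ROI]:
        return [
            r for r in self.regions
            if r.compartment == compartment and r.side == side
        ]


def fit_t2star(series: EchoSeries, mask: Optional[np.ndarray] = None) -> ParametricMap:
    """Per-pixel mono-exponential fit of a multi-echo series.

    ln S = ln S0 - TE * R2* is fit by weighted least squares over the
    echoes with weights S^2 (the standard linearization weights: the
    log-transform inflates noise where the signal is small, and the
    delta-method variance of ln S is sigma^2 / S^2).  Pixels with any
    non-positive signal, or with a non-positive estimated decay rate
    (non-decaying signal), are excluded from ``fit_mask`` and carry NaN
    in the parameter maps.
    """
    shape = series.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise InvalidInputError(
                f"mask shape {mask.shape} != series grid {shape}"
            )
    sig = series.volumes.reshape(series.volumes.shape[0], -1)
    te = series.echo_times
    positive = np.all(sig > 0, axis=0) & mask.ravel()

    s0 = np.full(sig.shape[1], np.nan)
    t2 = np.full(sig.shape[1], np.nan)
    r2 = np.full(sig.shape[1], np.nan)
    fitted = np.zeros(sig.shape[1], dtype=bool)

    if positive.any():
        s = sig[:, positive]
        y = np.log(s)
        w = s * s
        # closed-form weighted simple regression of ln S on TE per pixel;
        # slope = -R2* (per ms)
        wsum = w.sum(axis=0)
        te_col = te[:, None]
        te_bar = (w * te_col).sum(axis=0) / wsum
        y_bar = (w * y).sum(axis=0) / wsum
        dte = te_col - te_bar
        cov = (w * dte * (y - y_bar)).sum(axis=0)
        var = (w * dte * dte).sum(axis=0)
        slope = cov / var
        intercept = y_bar - slope * te_bar
        rate_ms = -slope  # R2* in 1/ms
        ok = rate_ms > 0
        idx = np.where(positive)[0][ok]
        s0[idx] = np.exp(intercept[ok])
        t2[idx] = 1.0 / rate_ms[ok]
        r2[idx] = 1000.0 * rate_ms[ok]
        fitted[idx] = True

    return ParametricMap(
        s0=s0.reshape(shape),
        t2star=t2.reshape(shape),
        r2star=r2.reshape(shape),
        fit_mask=fitted.reshape(shape),
    )


def r2star_from_t2star(t2star_ms):
    """R2* (1/s) from T2* (ms): 1000 / T2*."""
    t2 = np.asarray(t2star_ms, dtype=float)
    if np.any(t2 <= 0):
        raise InvalidInputError("t2star must be > 0")
    out = 1000.0 / t2
    return float(out) if out.ndim == 0 else out


def roi_mean(
    pmap: ParametricMap,
    rois: ROISet,
    compartment: str,
    side: str,
    quantity: str = "r2star",
) -> float:
    """Compartment value for one kidney: mean of the per-ROI mean values.

    Each ROI contributes its mean pixel value over fitted pixels; the ROIs
    are then averaged with equal weight regardless of size.  A count other
    than the nominal 9 ROIs warns but does not fail; an ROI with no fitted
    pixel is skipped with a warning.
    """
    selected = rois.select(compartment, side)
    if not selected:
        raise InvalidInputError(f"no ROI for ({compartment}, {side})")
    if len(selected) != 9:
        warnings.warn(
            f"expected 9 ROIs for ({compartment}, {side}), got {len(selected)}",
            stacklevel=2,
        )
    values = getattr(pmap, quantity)
    means = []
    for roi in selected:
        m = np.asarray(roi.mask, dtype=bool) & pmap.fit_mask
        if not m.any():
            warnings.warn(
                f"ROI {roi.label} ({compartment}, {side}, {roi.pole}) has no "
                "fitted pixel; skipped",
                stacklevel=2,
            )
            continue
        means.append(float(values[m].mean()))
    if not means:
        raise InvalidInputError(
            f"all ROIs for ({compartment}, {side}) fall outside the fit mask"
        )
    return float(np.mean(means))


def mcr(rm_r2star: float, rc_r2star: float) -> float:
    """Medulla-to-cortex R2* ratio (dimensionless)."""
    if rc_r2star <= 0:
        raise InvalidInputError("cortical R2* must be > 0")
    return float(rm_r2star) / float(rc_r2star)
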