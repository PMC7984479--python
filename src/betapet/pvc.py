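"""Recovery-coefficient regression partial-volume correction.

For each beta in the sweep, the six phantom spheres give six (diameter, RC)
points; an ordinary least-squares line RC = slope * d + intercept is fitted
per beta. A lesion's RC is then predicted from its CT-measured diameter
with the model of the matching beta, and its SUVmean/SUVmax/SUVpeak are
divided by the predicted RC (as a fraction). This is a regional correction:
it corrects the reported uptake value, not the image.

The model is fitted at a single 4:1 contrast, the contrast assumed for all
nodules; predictions outside the fitted diameter range (notably below the
smallest 10 mm sphere) are flagged as extrapolated, and predicted RC is
clamped to (0.05, 1.0] with the clamp recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import SUVRecord

__all__ = [
    "RCRegression",
    "RCPrediction",
    "fit_rc_regression",
    "fit_rc_models",
    "predict_rc",
    "apply_pvc",
]

RC_CLAMP_LOW = 0.05
RC_CLAMP_HIGH = 1.0


@dataclass(frozen=True)
class RCRegression:
    """Per-beta straight line RC(%) = slope * diameter(mm) + intercept."""

    beta: float
    slope: float
    intercept: float
    r_squared: float
    diameter_range: tuple[float, float]
    contrast: float = 4.0

    def predict_percent(self, diameter: float) -> float:
        return self.slope * diameter + self.intercept


@dataclass(frozen=True)
class RCPrediction:
    """Predicted RC as a fraction, with extrapolation/clamp provenance."""

    rc: float
    extrapolated: bool
    clamped: bool
    diameter: float
    beta: float


def fit_rc_regression(points, beta: float, contrast: float = 4.0) -> RCRegression:
    """OLS fit of RC (%) against sphere diameter (mm) for one beta.

    ``points`` is an iterable of (diameter_mm, rc_percent) pairs; at least
    two distinct diameters are required.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (diameter, RC) points")
    d, rc = pts[:, 0], pts[:, 1]
    if np.unique(d).size < 2:
        raise ValueError("all diameters identical: regression undefined")
    res = stats.linregress(d, rc)
    return RCRegression(
        beta=float(beta),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        diameter_range=(float(d.min()), float(d.max())),
        contrast=contrast,
    )


def fit_rc_models(nema_metrics: pd.DataFrame, contrast: float = 4.0) -> dict[float, RCRegression]:
    """Fit one RC-vs-diameter model per beta from a phantom sweep table.

    Expects columns ``beta``, ``diameter_mm``, ``rc_pct``; replicates at
    the same (beta, diameter) are averaged before fitting, mirroring how
    repeated phantom scans are reported as means.
    """
    needed = {"beta", "diameter_mm", "rc_pct"}
    if not needed.issubset(nema_metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(needed)}")
    models = {}
    for beta, g in nema_metrics.groupby("beta"):
        pts = g.groupby("diameter_mm")["rc_pct"].mean().reset_index().to_numpy()
        models[float(beta)] = fit_rc_regression(pts, beta=float(beta), contrast=contrast)
    return models


def predict_rc(model: RCRegression, diameter: float) -> RCPrediction:
    """Predicted RC fraction for a lesion diameter, clamped to (0.05, 1.0].

    The extrapolation flag is set when the diameter lies outside the
    fitted range — in particular below 10 mm, where the phantom provides
    no spheres and the model is an acknowledged extrapolation.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    raw = model.predict_percent(diameter) / 100.0
    lo, hi = model.diameter_range
    extrapolated = not (lo <= diameter <= hi)
    rc = min(max(raw, RC_CLAMP_LOW), RC_CLAMP_HIGH)
    return RCPrediction(
        rc=rc,
        extrapolated=extrapolated,
        clamped=(rc != raw),
        diameter=float(diameter),
        beta=model.beta,
    )


def apply_pvc(record: SUVRecord, rc: float) -> SUVRecord:
    """Divide each SUV by the estimated RC fraction; flag the record."""
    if not (0 < rc <= 1.0):
        raise ValueError(f"RC must lie in (0, 1], got {rc}")
    return replace(
        record,
        suv_mean=record.suv_mean / rc,
        suv_max=record.suv_max / rc,
        suv_peak=record.suv_peak / rc,
        pvc_applied=True,
        rc_used=rc,
    )
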