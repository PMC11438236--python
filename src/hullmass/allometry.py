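"""Log-log scaling fits, mass prediction, and percent-prediction-error (PPE)
accuracy/precision machinery.

Two predictive equations are central.  The volumetric (minimum convex hull)
equation,

    log10(mass kg) = 0.968 * log10(hull volume m^3 * density kg/m^3) + 0.215,

and the stylopodial-scaling equation,

    log10(mass kg) = 2.716 * log10(humerus + femur circumference mm) - 4.078.

Both are ordinary least squares fits in log10-log10 space with t-based 95%
confidence intervals (n-2 df).  PPE quantifies per-specimen prediction
error; group mean absolute PPE with a t-interval measures precision.
Allometry is called by comparing a slope CI against a null slope (1 for
circumference~length, 0 for robustness~mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .published import (
    DEFAULT_DENSITY,
    MCH_INTERCEPT,
    MCH_N,
    MCH_SLOPE,
    SS_INTERCEPT,
    SS_N,
    SS_SLOPE,
)

__all__ = [
    "ScalingFit",
    "PPEReport",
    "AllometryCall",
    "MCH_EQUATION",
    "SS_EQUATION",
    "fit_loglog",
    "fit_through_origin",
    "predict_mass_mch",
    "predict_mass_ss",
    "ppe",
    "logged_ppe",
    "mean_ppe_ci",
    "subsample_mean_ppe",
    "classify_allometry",
    "robustness",
    "residual_diagnostics",
]


@dataclass(frozen=True)
class ScalingFit:
    """An OLS scaling model, either log10-log10 or raw through-origin.

    For through-origin fits the intercept is identically 0 and its CI is
    undefined (None); the slope is then read as a volume "expansion factor".
    """

    slope: float
    intercept: float
    slope_ci95: tuple[float, float] | None
    intercept_ci95: tuple[float, float] | None
    r_squared: float
    p_value: float
    n: int
    transform: str = "log10-log10"  # or "raw-through-origin"

    def predict_log10(self, log10_x: float | np.ndarray):
        """Fitted value in log10 space (log10-log10 fits only)."""
        if self.transform != "log10-log10":
            raise ValueError("predict_log10 applies to log10-log10 fits")
        return self.slope * np.asarray(log10_x) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci95) if self.slope_ci95 else None,
            "intercept_ci95": list(self.intercept_ci95) if self.intercept_ci95 else None,
            "r2": self.r_squared,
            "p": self.p_value,
            "n": self.n,
            "transform": self.transform,
        }


#: The published volumetric predictive equation (33 extant specimens).
MCH_EQUATION = ScalingFit(
    slope=MCH_SLOPE, intercept=MCH_INTERCEPT, slope_ci95=None, intercept_ci95=None,
    r_squared=0.993, p_value=0.001, n=MCH_N,
)

#: The published stylopodial-scaling equation (266 extant amniotes).
SS_EQUATION = ScalingFit(
    slope=SS_SLOPE, intercept=SS_INTERCEPT, slope_ci95=None, intercept_ci95=None,
    r_squared=float("nan"), p_value=0.001, n=SS_N,
)


@dataclass(frozen=True)
class PPEReport:
    """Per-specimen PPE values for one method x group, with summary stats."""

    ppe_values: np.ndarray  # absolute PPE, %
    signed_values: np.ndarray  # signed PPE, % (negative = underestimate)
    mean_abs_ppe: float
    ci95_halfwidth: float
    group: str


@dataclass(frozen=True)
class AllometryCall:
    """Slope-CI-versus-null trichotomy: positive / negative / isometry."""

    verdict: str
    null_slope: float
    slope_ci95: tuple[float, float]


def _positive_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and > 0")
    return arr


def fit_loglog(x, y) -> ScalingFit:
    """OLS of log10(y) on log10(x) with t-based 95% CIs (n-2 df).

    Both variables must be strictly positive; p is the two-sided slope test.
    """
    lx = np.log10(_positive_array(x, "x"))
    ly = np.log10(_positive_array(y, "y"))
    n = len(lx)
    if n < 3 or len(ly) != n:
        raise ValueError(f"need n >= 3 paired positive observations, got {n}")
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = res.conf_int(alpha=0.05)  # rows: const, slope
    return ScalingFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci95=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=n,
        transform="log10-log10",
    )


def fit_through_origin(x, y) -> ScalingFit:
    """Raw-scale no-intercept OLS: slope = sum(xy)/sum(x^2).

    The slope of mass on hull-volume-times-density through the origin is
    interpreted as a whole-body volume expansion factor.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(xa)
    if n < 2 or len(ya) != n:
        raise ValueError(f"need n >= 2 paired observations, got {n}")
    sxx = float(np.dot(xa, xa))
    if sxx == 0:
        raise ValueError("all x are 0; through-origin slope undefined")
    res = sm.OLS(ya, xa[:, None]).fit()
    ci = res.conf_int(alpha=0.05)
    with np.errstate(invalid="ignore"):
        r2 = float(res.rsquared)  # uncentered; NaN when y is identically 0
    return ScalingFit(
        slope=float(res.params[0]),
        intercept=0.0,
        slope_ci95=(float(ci[0, 0]), float(ci[0, 1])) if n > 2 else None,
        intercept_ci95=None,
        r_squared=min(max(r2, 0.0), 1.0) if np.isfinite(r2) else 0.0,
        p_value=float(res.pvalues[0]),
        n=n,
        transform="raw-through-origin",
    )


def predict_mass_mch(
    volume_m3, density: float = DEFAULT_DENSITY, fit: ScalingFit = MCH_EQUATION
):
    """Body mass (kg) from whole-body hull volume via the volumetric equation.

    mass = 10^(slope * log10(V * rho) + intercept); strictly increasing in
    volume, and scaling density by k scales mass by k^slope.
    """
    v = np.asarray(volume_m3, dtype=float)
    if np.any(v <= 0) or density <= 0:
        raise ValueError("volume and density must be > 0")
    out = 10.0 ** (fit.slope * np.log10(v * density) + fit.intercept)
    return float(out) if np.isscalar(volume_m3) else out


def predict_mass_ss(
    humerus_circ_mm, femur_circ_mm, fit: ScalingFit = SS_EQUATION
):
    """Body mass (kg) from combined stylopod midshaft circumference (mm).

    mass = 10^(slope * log10(C_h + C_f) + intercept).
    """
    ch = np.asarray(humerus_circ_mm, dtype=float)
    cf = np.asarray(femur_circ_mm, dtype=float)
    if np.any(ch <= 0) or np.any(cf <= 0):
        raise ValueError("circumferences must be > 0 (millimetres)")
    out = 10.0 ** (fit.slope * np.log10(ch + cf) + fit.intercept)
    return float(out) if np.isscalar(humerus_circ_mm) else out


def ppe(observed_kg, predicted_kg) -> tuple:
    """Percent prediction error of a mass estimate.

    Returns ``(absolute, signed)`` where

    * absolute PPE = 100 * |observed - predicted| / predicted,
    * signed PPE  = 100 * (predicted - observed) / observed,

    so an underestimated specimen has negative signed PPE.  Both are
    invariant to rescaling observed and predicted by a common constant.
    """
    obs = np.asarray(observed_kg, dtype=float)
    pred = np.asarray(predicted_kg, dtype=float)
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("masses must be > 0")
    absolute = 100.0 * np.abs(obs - pred) / pred
    signed = 100.0 * (pred - obs) / obs
    if np.isscalar(observed_kg) and np.isscalar(predicted_kg):
        return float(absolute), float(signed)
    return absolute, signed


def logged_ppe(signed_ppe):
    """Sign-preserving pseudo-log of signed PPE: sign(s) * log10(1 + |s|).

    Zero maps exactly to zero, so under/over-estimates sit left/right of the
    origin in density plots.
    """
    s = np.asarray(signed_ppe, dtype=float)
    out = np.sign(s) * np.log10(1.0 + np.abs(s))
    return float(out) if np.isscalar(signed_ppe) else out


def mean_ppe_ci(ppe_values) -> tuple[float, float]:
    """Mean absolute PPE with a t-based 95% CI halfwidth (n-1 df)."""
    vals = np.asarray(ppe_values, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError(f"need n >= 2 PPE values, got {n}")
    mean = float(vals.mean())
    halfwidth = float(stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n))
    return mean, halfwidth


def subsample_mean_ppe(
    ppe_values, subsample_n: int, iterations: int = 1000, seed: int | np.random.Generator = 0
) -> list[tuple[float, float]]:
    """Repeatedly subsample (without replacement) and summarise mean PPE.

    Used to put the large stylopodial sample on the same footing as the
    33-specimen volumetric sample: each iteration draws ``subsample_n``
    values and records (mean, CI95 halfwidth).
    """
    vals = np.asarray(ppe_values, dtype=float)
    if subsample_n > len(vals):
        raise ValueError(f"subsample_n={subsample_n} exceeds sample size {len(vals)}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(iterations):
        sub = rng.choice(vals, size=subsample_n, replace=False)
        out.append(mean_ppe_ci(sub))
    return out


def classify_allometry(fit: ScalingFit, null_slope: float) -> AllometryCall:
    """Call positive/negative allometry or isometry from a slope CI.

    Positive iff the whole CI lies above the null slope, negative iff the
    whole CI lies below; otherwise isometry (null not excluded).
    """
    if fit.slope_ci95 is None:
        raise ValueError("fit has no slope confidence interval")
    lo, hi = fit.slope_ci95
    if lo > null_slope:
        verdict = "positive"
    elif hi < null_slope:
        verdict = "negative"
    else:
        verdict = "isometry"
    return AllometryCall(verdict=verdict, null_slope=null_slope, slope_ci95=(lo, hi))


def robustness(circumference, length):
    """Stylopod robustness: minimum midshaft circumference / length.

    Dimensionless; both inputs must be positive and share a unit.  Higher
    values mean stouter bones.
    """
    c = np.asarray(circumference, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(c <= 0) or np.any(ln <= 0):
        raise ValueError("circumference and length must be > 0")
    out = c / ln
    return float(out) if np.isscalar(circumference) else out


def residual_diagnostics(fit: ScalingFit, x, y) -> tuple[np.ndarray, np.ndarray, float]:
    """Q-Q data and skewness for a fit's residuals.

    Returns ``(theoretical, ordered_residuals, skewness)`` where the
    theoretical values are standard-normal quantiles at Blom plotting
    positions ((i - 3/8)/(n + 1/4)) and skewness is the adjusted
    Fisher-Pearson coefficient (0 by convention for an exact fit).
    Residuals are taken on the fit's own scale (log10 for log-log fits,
    raw for through-origin fits).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(xa)
    if n < 4:
        raise ValueError(f"need n >= 4 observations for diagnostics, got {n}")
    if fit.transform == "log10-log10":
        resid = np.log10(ya) - fit.predict_log10(np.log10(xa))
    else:
        resid = ya - fit.slope * xa
    order = np.sort(resid)
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theoretical = stats.norm.ppf(positions)
    if np.allclose(resid, 0) or resid.std(ddof=1) == 0:
        skew = 0.0
    else:
        skew = float(stats.skew(resid, bias=False))
    return theoretical, order, skew
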