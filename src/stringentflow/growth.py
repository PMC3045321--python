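"""Specific growth rate, Monod kinetics and the growth-retardation law.

The specific growth rate of a batch culture is mu(t) = (1/N) dN/dt =
d(ln N)/dt, estimated here by differentiating a smoothing spline fitted to
log optical density.  Nutrient-limited growth follows the Monod form
mu = mu_max * s / (k + s); when synthesising a stress protein at concentration
x imposes a metabolic burden epsilon = lambda * x on the nutrient supply, a
first-order expansion of the Monod law yields the growth-retardation
(reciprocal) law

    mu(x) = phi / (1 + theta * x),
    phi = mu_max * s / (s + k),   theta = k * lambda / (s + k).

The same reciprocal form is fitted directly to (GFP intensity, mu) pairs,
with GFP fluorescence acting as the proxy for stress-protein level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.optimize import curve_fit

__all__ = [
    "OD_TO_CELLS",
    "GrowthCurve",
    "MonodParams",
    "RetardationFit",
    "specific_growth_rate",
    "monod_mu",
    "monod_burdened_mu",
    "retarded_mu",
    "phi_theta_from_monod",
    "fit_growth_retardation",
]

#: calibration constant: cells per unit OD600
OD_TO_CELLS = 1e8


@dataclass(frozen=True)
class GrowthCurve:
    """Times (hours) and OD600 readings; cell counts via 1 OD600 = 1e8 cells."""

    time_h: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("time and OD must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD600 must be nonnegative")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "od600", od)

    @property
    def cells(self) -> np.ndarray:
        return self.od600 * OD_TO_CELLS


@dataclass(frozen=True)
class MonodParams:
    """Monod growth with a linear protein burden on the nutrient supply."""

    mu_max: float  # 1/h
    s: float  # nutrient concentration, arbitrary units
    k: float  # half-saturation constant, same units as s
    lam: float = 0.0  # burden per protein unit; epsilon = lam * x

    def __post_init__(self) -> None:
        if not (self.mu_max > 0 and self.k > 0):
            raise ValueError("mu_max and k must be positive")
        if self.s < 0:
            raise ValueError("nutrient concentration s must be nonnegative")


@dataclass(frozen=True)
class RetardationFit:
    """Parameters of the reciprocal growth-retardation law mu = phi/(1+theta x)."""

    phi: float  # maximal specific growth rate at x = 0, 1/h
    theta: float  # retardation per protein (or GFP intensity) unit
    residual_ss: float = 0.0
    fitted: bool = False

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


def specific_growth_rate(
    curve: GrowthCurve, smoothing: float | None = 0.0
) -> pd.DataFrame:
    """Estimate mu(t) = d(ln N)/dt along a growth curve.

    A cubic smoothing spline is fitted to ln(OD) and differentiated
    analytically; ``smoothing`` is the spline's residual bound (0 =
    interpolating, None = scipy's default heuristic for noisy data).  Curves
    with five or fewer points fall back to central finite differences.
    Because mu depends on N only through ln N, the estimate is exactly
    invariant to rescaling OD into cell counts.
    """
    t, od = curve.time_h, curve.od600
    if t.size < 4:
        raise ValueError(f"need >= 4 points to differentiate, got {t.size}")
    if np.any(od <= 0):
        raise ValueError("OD must be positive wherever the rate is evaluated")
    logn = np.log(od)
    if t.size <= 5:
        mu = np.gradient(logn, t)
    else:
        spline = UnivariateSpline(t, logn, k=3, s=smoothing)
        mu = spline.derivative()(t)
    return pd.DataFrame({"time_h": t, "mu_per_h": mu})


def monod_mu(s, k: float, mu_max: float):
    """Monod specific growth rate mu = mu_max * s / (k + s)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("nutrient concentration must be nonnegative")
    if k <= 0:
        raise ValueError("half-saturation constant k must be positive")
    return mu_max * s / (k + s)


def retarded_mu(x, fit: RetardationFit):
    """Growth rate under protein burden: mu = phi / (1 + theta x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("protein level x must be nonnegative")
    return fit.phi / (1.0 + fit.theta * x)


def monod_burdened_mu(x, params: MonodParams):
    """Monod growth with the protein burden epsilon = lam*x on the nutrient.

    The burden scales the available nutrient down to s(1 - epsilon), so
    mu = mu_max / (1 + (k/s) / (1 - epsilon)); requires epsilon < 1.
    First-order expansion in epsilon gives the reciprocal law of
    :func:`phi_theta_from_monod`.
    """
    x = np.asarray(x, dtype=float)
    eps = params.lam * x
    if np.any(eps >= 1):
        raise ValueError("burden epsilon = lam*x must stay below 1")
    if params.s <= 0:
        raise ValueError("burdened Monod growth needs s > 0")
    return params.mu_max / (1.0 + (params.k / params.s) / (1.0 - eps))


def phi_theta_from_monod(params: MonodParams) -> RetardationFit:
    """Reduce burdened Monod growth to the reciprocal law.

    First-order expansion of mu = mu_max / (1 + (k/s)(1 - epsilon)) in the
    small burden epsilon = lam * x gives phi = mu_max s/(s+k) and
    theta = k lam/(s+k).
    """
    denom = params.s + params.k
    if denom <= 0:
        raise ValueError("s + k must be positive")
    phi = params.mu_max * params.s / denom
    theta = params.k * params.lam / denom
    return RetardationFit(phi=phi, theta=theta)


def fit_growth_retardation(
    x, mu, p0: tuple[float, float] | None = None
) -> RetardationFit:
    """Nonlinear least-squares fit of mu = phi/(1 + theta x) to (x, mu) pairs.

    The loss is unweighted least squares on mu.  The default start is
    (max mu, small positive theta); theta is constrained nonnegative.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.size != mu.size or x.size < 3:
        raise ValueError("need >= 3 (x, mu) pairs of equal length")
    if np.any(x < 0) or np.any(mu <= 0):
        raise ValueError("require x >= 0 and mu > 0")
    if p0 is None:
        p0 = (float(mu.max()), 0.01)

    def law(xv, phi, theta):
        return phi / (1.0 + theta * xv)

    try:
        popt, _ = curve_fit(
            law, x, mu, p0=p0, bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"retardation fit did not converge: {err}") from err
    resid = mu - law(x, *popt)
    return RetardationFit(
        phi=float(popt[0]),
        theta=float(popt[1]),
        residual_ss=float(resid @ resid),
        fitted=True,
    )
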