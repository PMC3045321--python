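"""Synthetic inputs with the statistical structure the analysis assumes.

The flow-cytometry generator draws, at each acquisition time, N events
(default 20,000, the standard acquisition size) from the two-component
mixture: each event belongs to the H subpopulation with probability
``omega_2(t)`` and its intensity is drawn from the corresponding invariant
component.  The default truth components are the fitted *mprA* reporter
parameters (Gaussian center 97.3366 / width 103.0731; lognormal log-mean
5.95526 / log-sd 0.17618) and the default weight schedule is a logistic rise
of the H fraction (midpoint 20 h, scale 2 h), matching the gradual L-to-H
transition seen over a starvation time course.

Also generated here: logistic OD600 growth curves under nutrient depletion
and (protein level, specific growth rate) pairs obeying the reciprocal
growth-retardation law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distributions import (
    GaussianComponent,
    LognormalComponent,
    MixtureModel,
    sample_component,
)
from .growth import GrowthCurve, RetardationFit, retarded_mu

__all__ = [
    "DEFAULT_EVENTS_PER_TIMEPOINT",
    "MPRA_COMPONENTS",
    "SIGE_COMPONENTS",
    "default_weight_schedule",
    "SyntheticScenario",
    "generate_flow_timecourse",
    "generate_growth_curve",
    "generate_mu_x_pairs",
]

#: events per acquisition, the standard flow-cytometry acquisition size
DEFAULT_EVENTS_PER_TIMEPOINT = 20_000

#: fitted invariant components for the mprA reporter (truth set for synthesis)
MPRA_COMPONENTS = MixtureModel(
    gaussian=GaussianComponent(center=97.3366, width=103.0731),
    lognormal=LognormalComponent(log_mean=5.95526, log_sd=0.17618),
)

#: fitted invariant components for the sigE reporter
SIGE_COMPONENTS = MixtureModel(
    gaussian=GaussianComponent(center=145.86181, width=154.67381),
    lognormal=LognormalComponent(log_mean=6.1171, log_sd=0.2509),
)


def default_weight_schedule(
    times_h=(12, 15, 18, 21, 24, 27, 30),
    midpoint_h: float = 20.0,
    scale_h: float = 2.0,
) -> dict[str, float]:
    """Logistic H-fraction schedule omega_2(t) = 1/(1+exp(-(t-t0)/s))."""
    return {
        f"{t:g}h": float(1.0 / (1.0 + np.exp(-(t - midpoint_h) / scale_h)))
        for t in times_h
    }


@dataclass
class SyntheticScenario:
    """Complete recipe for a synthetic flow-cytometry time course.

    ``cv_burst_factor``/``cv_burst_window`` inflate the Gaussian (L) width by
    a constant factor over a time window (hours, inclusive), a constructed
    scenario in which expression noise in the L subpopulation peaks
    mid-course while cells transition to H.
    """

    model: MixtureModel = field(default_factory=lambda: MPRA_COMPONENTS)
    schedule: dict[str, float] = field(default_factory=default_weight_schedule)
    events_per_timepoint: int = DEFAULT_EVENTS_PER_TIMEPOINT
    seed: int = 0
    cv_burst_factor: float = 1.0
    cv_burst_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for t, w2 in self.schedule.items():
            if not 0.0 <= w2 <= 1.0:
                raise ValueError(f"omega_2 at {t!r} must be in [0, 1], got {w2}")
        if self.events_per_timepoint <= 0:
            raise ValueError("events_per_timepoint must be positive")
        if self.cv_burst_factor < 1.0:
            raise ValueError("cv_burst_factor must be >= 1")


def _burst_active(scenario: SyntheticScenario, hours: float) -> bool:
    if scenario.cv_burst_window is None or scenario.cv_burst_factor == 1.0:
        return False
    lo, hi = scenario.cv_burst_window
    return lo <= hours <= hi


def generate_flow_timecourse(
    scenario: SyntheticScenario,
) -> tuple[list[tuple[str, np.ndarray]], dict]:
    """Draw the event tables for every time point in the scenario.

    Returns ``(dataset, truth)`` where ``dataset`` is a list of
    ``(time_label, intensities)`` in schedule order and ``truth`` records the
    generating components, schedule and realised per-time H counts.  Output
    is fully determined by the scenario (components, schedule, seed).
    """
    from .subpopulations import parse_time_label  # local: avoids cycle

    rng = np.random.default_rng(scenario.seed)
    n = scenario.events_per_timepoint
    dataset = []
    realized = {}
    for label, w2 in scenario.schedule.items():
        gauss = scenario.model.gaussian
        if _burst_active(scenario, parse_time_label(label)):
            gauss = replace(gauss, width=gauss.width * scenario.cv_burst_factor)
        is_high = rng.random(n) < w2
        x = np.empty(n)
        n_high = int(is_high.sum())
        if n_high < n:
            x[~is_high] = sample_component(gauss, n - n_high, rng)
        if n_high:
            x[is_high] = sample_component(scenario.model.lognormal, n_high, rng)
        dataset.append((label, x))
        realized[label] = n_high
    truth = {
        "gaussian": {
            "center": scenario.model.gaussian.center,
            "width": scenario.model.gaussian.width,
        },
        "lognormal": {
            "log_mean": scenario.model.lognormal.log_mean,
            "log_sd": scenario.model.lognormal.log_sd,
        },
        "schedule": dict(scenario.schedule),
        "events_per_timepoint": n,
        "seed": scenario.seed,
        "n_high_realized": realized,
        "cv_burst_factor": scenario.cv_burst_factor,
        "cv_burst_window": scenario.cv_burst_window,
    }
    return dataset, truth


def generate_growth_curve(
    mu0: float = 0.35,
    capacity: float = 2.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    od0: float = 0.02,
    times_h=None,
) -> GrowthCurve:
    """Logistic OD600 trajectory under nutrient depletion.

    OD(t) = capacity / (1 + (capacity/od0 - 1) exp(-mu0 t)); optional
    multiplicative lognormal noise of relative magnitude ``noise_sd``.
    Defaults give an early-exponential rate mu0 and saturation at the
    carrying capacity, on an hourly grid over 36 h.
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be positive")
    t = (
        np.arange(0.0, 36.5, 1.0)
        if times_h is None
        else np.asarray(times_h, dtype=float)
    )
    od = capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-mu0 * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_sd, size=t.size))
    return GrowthCurve(time_h=t, od600=od)


def generate_mu_x_pairs(
    phi: float = 0.94,
    theta: float = 0.317,
    x_grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(x, mu) pairs on the reciprocal growth-retardation law.

    Defaults are the fitted GFP-proxy parameters (phi = 0.94 /h,
    theta = 0.317 per intensity unit).  ``noise_sd`` adds zero-mean Gaussian
    noise to mu.
    """
    fit = RetardationFit(phi=phi, theta=theta)
    x = (
        np.linspace(0.0, 3.0, 20)
        if x_grid is None
        else np.atleast_1d(np.asarray(x_grid, dtype=float))
    )
    mu = np.asarray(retarded_mu(x, fit), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mu = mu + rng.normal(0.0, noise_sd, size=x.size)
    return pd.DataFrame({"x": x, "mu": mu})
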