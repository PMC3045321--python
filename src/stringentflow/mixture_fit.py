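"""Joint mixture fitting with invariant components shared across time points.

The central statistical claim encoded here is that the population density at
every acquisition time is ``C1(t) P1(x) + C2(t) P2(x)`` with *one* Gaussian
``P1`` and *one* lognormal ``P2`` shared by all time points and only the
weights time-dependent.  The joint fit is an expectation-maximisation (EM)
scheme on raw events: the E-step computes per-event responsibilities with each
time point's own weights; the M-step re-estimates the per-time weights locally
and the shared component parameters by pooling weighted sufficient statistics
across all time points.

Single-family maximum-likelihood fits (Gaussian / lognormal / gamma) and the
lognormal-versus-gamma model comparison for the H subpopulation live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import (
    GammaComponent,
    GaussianComponent,
    LognormalComponent,
    MixtureModel,
    gamma_pdf,
    gaussian_pdf,
    lognormal_pdf,
)

__all__ = [
    "ComponentFit",
    "JointFitResult",
    "FamilyComparison",
    "ConvergenceError",
    "fit_component_mle",
    "fit_joint_timecourse",
    "compare_families",
]

_FAMILIES = ("gaussian", "lognormal", "gamma")
_N_PARAMS = {"gaussian": 2, "lognormal": 2, "gamma": 2}

# numerical floor for responsibilities / weights to keep the EM iteration
# defined when one component momentarily captures everything
_EPS = 1e-300


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the last iterate in ``last_result``."""

    def __init__(self, message: str, last_result: "JointFitResult"):
        super().__init__(message)
        self.last_result = last_result


@dataclass(frozen=True)
class ComponentFit:
    """Single-family MLE: fitted component, log-likelihood, degeneracy flag."""

    component: object
    loglik: float
    degenerate: bool = False


@dataclass
class JointFitResult:
    """Shared-component EM fit over a time course."""

    model: MixtureModel
    per_time_loglik: dict[str, float]
    n_iter: int
    final_rel_change: float
    converged: bool
    loglik_trace: list[float] | None = None

    @property
    def total_loglik(self) -> float:
        return float(sum(self.per_time_loglik.values()))


@dataclass
class FamilyComparison:
    """Per-family log-likelihood / AIC table with the AIC-best family."""

    table: pd.DataFrame
    best_family: str


def fit_component_mle(events, family: str) -> ComponentFit:
    """Maximum-likelihood fit of a single distribution family to events.

    Gaussian and lognormal use the closed-form MLEs (with the Gaussian width
    reported in the ``w01 = 2 sigma`` convention); gamma uses numerical MLE
    with the location fixed at 0.  Zero-variance samples are returned with a
    tiny positive width and ``degenerate=True``.
    """
    x = np.asarray(events, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError(f"need >= 10 events in a 1-d array, got shape {x.shape}")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {_FAMILIES}")
    if family in ("lognormal", "gamma") and np.any(x <= 0):
        raise ValueError(
            f"{family} fit requires strictly positive events; "
            f"min observed = {x.min()}"
        )

    if family == "gaussian":
        mu = float(x.mean())
        sigma = float(x.std(ddof=0))
        if sigma <= 0:
            comp = GaussianComponent(center=mu, width=1e-12)
            return ComponentFit(comp, loglik=np.inf, degenerate=True)
        comp = GaussianComponent(center=mu, width=2.0 * sigma)
        ll = float(stats.norm.logpdf(x, mu, sigma).sum())
        return ComponentFit(comp, ll)

    if family == "lognormal":
        logx = np.log(x)
        m = float(logx.mean())
        s = float(logx.std(ddof=0))
        if s <= 0:
            comp = LognormalComponent(log_mean=m, log_sd=1e-12)
            return ComponentFit(comp, loglik=np.inf, degenerate=True)
        comp = LognormalComponent(log_mean=m, log_sd=s)
        ll = float(stats.lognorm.logpdf(x, s, scale=np.exp(m)).sum())
        return ComponentFit(comp, ll)

    # gamma: numerical MLE, location pinned to the origin
    shape, _, scale = stats.gamma.fit(x, floc=0)
    comp = GammaComponent(shape=float(shape), scale=float(scale))
    ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    return ComponentFit(comp, ll)


def _initial_model(pooled: np.ndarray, labels: list[str]) -> MixtureModel:
    """Deterministic start: median split, moment-matched components."""
    med = np.median(pooled)
    low = pooled[pooled <= med]
    high = pooled[pooled > med]
    high = high[high > 0]
    if high.size < 2:  # essentially unimodal at the origin; fall back
        high = pooled[pooled > 0]
    mu = float(low.mean())
    sigma = max(float(low.std(ddof=0)), 1e-6 * max(abs(mu), 1.0))
    logh = np.log(high)
    lm = float(logh.mean())
    ls = max(float(logh.std(ddof=0)), 1e-3)
    return MixtureModel(
        gaussian=GaussianComponent(center=mu, width=2.0 * sigma),
        lognormal=LognormalComponent(log_mean=lm, log_sd=ls),
        weights={t: (0.5, 0.5) for t in labels},
    )


def fit_joint_timecourse(
    dataset,
    max_iter: int = 2000,
    tol: float = 1e-8,
    min_events: int = 100,
) -> JointFitResult:
    """EM fit of one Gaussian + one lognormal shared across all time points.

    Parameters
    ----------
    dataset
        Sequence of ``(time_label, events)`` pairs, one per acquisition.
    max_iter, tol
        Iteration cap and relative joint log-likelihood convergence tolerance.
    min_events
        Minimum events required per time point.

    Returns
    -------
    JointFitResult
        Fitted model with per-time weights ``(C1, C2)`` summing to 1, and the
        per-time log-likelihoods at the optimum.  The component labelled
        Gaussian/L is the one with the smaller raw-scale mean.

    Raises
    ------
    ConvergenceError
        If the relative log-likelihood change has not fallen below ``tol``
        within ``max_iter`` iterations; the exception carries the last iterate.
    """
    items = [(str(t), np.asarray(x, dtype=float)) for t, x in dataset]
    if len(items) < 2:
        raise ValueError(f"need >= 2 time points, got {len(items)}")
    for t, x in items:
        if x.size < min_events:
            raise ValueError(
                f"time point {t!r} has {x.size} events; need >= {min_events}"
            )
    labels = [t for t, _ in items]
    pooled = np.concatenate([x for _, x in items])

    model = _initial_model(pooled, labels)
    gauss, logn = model.gaussian, model.lognormal
    weights = dict(model.weights)

    prev_total = -np.inf
    rel_change = np.inf
    n_iter = 0
    per_time_ll: dict[str, float] = {}
    trace: list[float] = []

    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities per time point with that point's weights
        sum_r1 = sum_r1x = sum_r1xx = 0.0
        sum_r2 = sum_r2l = sum_r2ll = 0.0
        total_ll = 0.0
        resp_cache = []
        per_time_ll = {}
        for t, x in items:
            c1, c2 = weights[t]
            d1 = c1 * gaussian_pdf(x, gauss)
            d2 = c2 * lognormal_pdf(x, logn)
            tot = d1 + d2
            ll_t = float(np.log(np.maximum(tot, _EPS)).sum())
            per_time_ll[t] = ll_t
            total_ll += ll_t
            r1 = d1 / np.maximum(tot, _EPS)
            resp_cache.append((t, x, r1))

        # M-step: local weights, pooled shared-component statistics
        for t, x, r1 in resp_cache:
            w1 = float(r1.mean())
            weights[t] = (w1, 1.0 - w1)
            r2 = 1.0 - r1
            sum_r1 += float(r1.sum())
            sum_r1x += float((r1 * x).sum())
            sum_r1xx += float((r1 * x * x).sum())
            pos = x > 0
            logx = np.log(x[pos])
            r2p = r2[pos]
            sum_r2 += float(r2p.sum())
            sum_r2l += float((r2p * logx).sum())
            sum_r2ll += float((r2p * logx * logx).sum())

        if sum_r1 > _EPS:
            m1 = sum_r1x / sum_r1
            v1 = max(sum_r1xx / sum_r1 - m1 * m1, 1e-12)
            gauss = GaussianComponent(center=m1, width=2.0 * np.sqrt(v1))
        if sum_r2 > _EPS:
            m2 = sum_r2l / sum_r2
            v2 = max(sum_r2ll / sum_r2 - m2 * m2, 1e-12)
            logn = LognormalComponent(log_mean=m2, log_sd=np.sqrt(v2))

        trace.append(total_ll)
        rel_change = abs(total_ll - prev_total) / max(abs(total_ll), 1.0)
        prev_total = total_ll
        if rel_change < tol:
            break

    model = MixtureModel(gaussian=gauss, lognormal=logn, weights=dict(weights))
    result = JointFitResult(
        model=model,
        per_time_loglik=per_time_ll,
        n_iter=n_iter,
        final_rel_change=float(rel_change),
        converged=rel_change < tol,
        loglik_trace=trace,
    )
    if not result.converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(relative change {rel_change:.3e} > {tol:g})",
            result,
        )
    return result


def compare_families(events, families=("lognormal", "gamma")) -> FamilyComparison:
    """Fit each family to the events and rank by AIC (``2k - 2 loglik``)."""
    if not families:
        raise ValueError("at least one family must be requested")
    x = np.asarray(events, dtype=float)
    if np.any(x <= 0):
        raise ValueError("family comparison requires strictly positive events")
    rows = []
    for fam in families:
        fit = fit_component_mle(x, fam)
        k = _N_PARAMS[fam]
        aic = 2 * k - 2 * fit.loglik
        params = {
            f: getattr(fit.component, f)
            for f in fit.component.__dataclass_fields__
        }
        rows.append(
            {"family": fam, "loglik": fit.loglik, "aic": aic, "params": params}
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["aic"].idxmin(), "family"]
    return FamilyComparison(table=table, best_family=str(best))
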