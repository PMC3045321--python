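"""Stochastic binning into L/H subpopulations and time-course statistics.

With the fitted invariant components in hand, each cell ``j`` with intensity
``x_j`` is assigned a membership ratio

    g1(x_j) = P1(x_j) / (P1(x_j) + P2(x_j)),     g2 = 1 - g1,

computed from the *unweighted* component densities, and is placed in the L
subpopulation if a fresh uniform draw ``r`` satisfies ``0 <= r < g1(x_j)``,
in H otherwise.  Because the two densities overlap, the partition is
stochastic: the same intensity can end up in either subpopulation.  Per time
point the module reports subpopulation counts ``N_i``, fractions ``omega_i``,
means ``mu_i``, variances ``sigma_i^2`` (``N_i - 1`` denominator) and the
coefficient of variation ``CV_i = sd_i / mu_i``, plus the L-to-H transition
rate between consecutive acquisitions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import MixtureModel, gaussian_pdf, lognormal_pdf

__all__ = [
    "UndefinedMembershipError",
    "membership_ratios",
    "stochastic_binning",
    "subpopulation_summary",
    "transition_rate_series",
    "analyze_timecourse",
    "parse_time_label",
]

L, H = "L", "H"


class UndefinedMembershipError(ValueError):
    """Both component densities vanish at an event's intensity."""


def parse_time_label(label: str) -> float:
    """Hours from a time label like ``"18h"``, ``"18"`` or ``"18.5 h"``."""
    m = re.fullmatch(r"\s*([0-9]+(?:\.[0-9]+)?)\s*h?\s*", str(label))
    if m is None:
        raise ValueError(f"cannot parse time label {label!r} as hours")
    return float(m.group(1))


def membership_ratios(x, model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """Membership ratios ``(g1, g2)`` from the unweighted component densities.

    The weighted-posterior variant ``C1 P1 / (C1 P1 + C2 P2)`` needs a time
    label to pick the weights, so it is exposed on :func:`stochastic_binning`
    (``weighted=True``) rather than here.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    p1 = gaussian_pdf(x, model.gaussian)
    p2 = lognormal_pdf(x, model.lognormal)
    tot = p1 + p2
    bad = ~(tot > 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise UndefinedMembershipError(
            f"both component densities are zero at event {idx} (x={x[idx]})"
        )
    g1 = p1 / tot
    return g1, 1.0 - g1


def stochastic_binning(
    events,
    model: MixtureModel,
    seed: int | np.random.Generator,
    t: str | None = None,
    weighted: bool = False,
) -> np.ndarray:
    """Assign each event to L or H by one uniform draw against ``g1(x_j)``.

    ``weighted=True`` uses the posterior ratios ``C1 P1 / (C1 P1 + C2 P2)``
    with the weights stored for time label ``t``; the default follows the
    unweighted ratio.  One seeded generator drives the whole call; event order
    is the input order, so a fixed seed reproduces the labeling exactly.
    """
    x = np.asarray(events, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bin an empty event table")
    if weighted:
        if t is None:
            raise ValueError("weighted binning needs the time label t")
        c1, c2 = model.weight_at(t)
        p1 = c1 * gaussian_pdf(x, model.gaussian)
        p2 = c2 * lognormal_pdf(x, model.lognormal)
        tot = p1 + p2
        bad = ~(tot > 0)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise UndefinedMembershipError(
                f"both weighted densities are zero at event {idx} (x={x[idx]})"
            )
        g1 = p1 / tot
    else:
        g1, _ = membership_ratios(x, model)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r = rng.random(x.size)
    return np.where(r < g1, L, H)


def subpopulation_summary(events, labels, time: str | None = None) -> pd.DataFrame:
    """Per-subpopulation count, fraction, mean, variance and CV.

    Returns a tidy frame with one row per subpopulation (L then H).  The
    variance uses the ``N_i - 1`` denominator and is NaN when a subpopulation
    has fewer than two members; the fraction ``omega_i = N_i / N``.
    """
    x = np.asarray(events, dtype=float)
    lab = np.asarray(labels)
    if lab.shape != x.shape:
        raise ValueError(
            f"labels shape {lab.shape} does not match events shape {x.shape}"
        )
    n_total = x.size
    rows = []
    for i, sub in enumerate((L, H), start=1):
        xs = x[lab == sub]
        n = xs.size
        mean = float(xs.mean()) if n else np.nan
        var = float(xs.var(ddof=1)) if n >= 2 else np.nan
        cv = float(np.sqrt(var) / mean) if n >= 2 and mean != 0 else np.nan
        rows.append(
            {
                "time": time,
                "subpopulation": sub,
                "n": n,
                "omega": n / n_total,
                "mean": mean,
                "variance": var,
                "cv": cv,
            }
        )
    return pd.DataFrame(rows)


def transition_rate_series(stats: pd.DataFrame) -> pd.DataFrame:
    """L-to-H transition rate between consecutive time points.

    ``stats`` is the tidy output of repeated :func:`subpopulation_summary`
    calls (columns ``time``, ``subpopulation``, ``omega``).  Over an interval
    ``[t_a, t_b]`` the rate is the per-capita one-way flux

        (omega_2(t_b) - omega_2(t_a)) / ((t_b - t_a) * omega_1(t_a)),

    reported at the interval midpoint; it is NaN where ``omega_1(t_a) = 0``.
    """
    wide = stats.pivot(index="time", columns="subpopulation", values="omega")
    hours = np.array([parse_time_label(t) for t in wide.index])
    order = np.argsort(hours)
    hours = hours[order]
    if len(hours) < 2:
        raise ValueError("need >= 2 time points for transition rates")
    if np.any(np.diff(hours) <= 0):
        raise ValueError("time points must be strictly increasing")
    w1 = wide[L].to_numpy()[order]
    w2 = wide[H].to_numpy()[order]
    dt = np.diff(hours)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.diff(w2) / (dt * w1[:-1])
    rate = np.where(w1[:-1] > 0, rate, np.nan)
    return pd.DataFrame(
        {"t_mid": (hours[:-1] + hours[1:]) / 2.0, "rate_per_h": rate}
    )


@dataclass
class TimeCourseReport:
    """Per-time subpopulation statistics plus derived series."""

    stats: pd.DataFrame
    transition_rates: pd.DataFrame | None
    cv_low: pd.DataFrame  # L-subpopulation CV versus time (hours)


def analyze_timecourse(
    dataset, model: MixtureModel, seed: int
) -> TimeCourseReport:
    """Bin every acquisition and assemble the full time-course report.

    ``dataset`` is a sequence of ``(time_label, events)`` pairs.  Each time
    point gets an independent child generator spawned from ``seed``, so the
    report is reproducible while time points stay statistically independent.
    Transition rates are omitted (None) for a single time point.
    """
    items = [(str(t), np.asarray(x, dtype=float)) for t, x in dataset]
    for t, x in items:
        if x.size == 0:
            raise ValueError(f"time point {t!r} has no events")
    root = np.random.default_rng(seed)
    frames = []
    for (t, x), child in zip(items, root.spawn(len(items))):
        labels = stochastic_binning(x, model, child)
        frames.append(subpopulation_summary(x, labels, time=t))
    stats = pd.concat(frames, ignore_index=True)
    rates = transition_rate_series(stats) if len(items) >= 2 else None
    low = stats[stats["subpopulation"] == L]
    cv_low = pd.DataFrame(
        {
            "time_h": [parse_time_label(t) for t in low["time"]],
            "cv": low["cv"].to_numpy(),
        }
    ).sort_values("time_h", ignore_index=True)
    return TimeCourseReport(stats=stats, transition_rates=rates, cv_low=cv_low)
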