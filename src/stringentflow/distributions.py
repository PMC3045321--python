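"""Component densities and the time-indexed two-component mixture.

Single-cell GFP fluorescence distributions in nutrient-starved *M. smegmatis*
are bimodal: a low-expression (L) subpopulation described by a Gaussian and a
high-expression (H) subpopulation described by a lognormal.  At every
acquisition time the population density is a convex combination of the two
*time-invariant* component densities,

    P(x, t) = C1(t) * P1(x) + C2(t) * P2(x),

with only the weights ``(C1, C2)`` depending on time.  A gamma component is
provided as well, as the classical alternative to the lognormal for skewed
single-cell protein abundance data.

Gaussian width convention
-------------------------
The L-component is parameterised by a center ``x01`` and a width ``w01``.
The default ("half") convention uses the peak-normalised form

    P1(x) = exp(-2 ((x - x01) / w01)^2) / (w01 * sqrt(pi / 2)),

a proper density with standard deviation ``sigma = w01 / 2``.  The plain-sigma
alternative ("root2", ``sigma = w01 / sqrt(2)``,
``P1(x) = exp(-((x - x01)/w01)^2) / (w01 * sqrt(pi))``) is available through
the ``convention`` argument everywhere a Gaussian is evaluated or sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GaussianComponent",
    "LognormalComponent",
    "GammaComponent",
    "MixtureModel",
    "GAUSSIAN_CONVENTIONS",
    "gaussian_pdf",
    "lognormal_pdf",
    "gamma_pdf",
    "mixture_pdf",
    "sample_component",
]

#: supported Gaussian width conventions, mapping to sigma = width / divisor
GAUSSIAN_CONVENTIONS = {"half": 2.0, "root2": np.sqrt(2.0)}


def _check_convention(convention: str) -> float:
    try:
        return GAUSSIAN_CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown Gaussian convention {convention!r}; "
            f"expected one of {sorted(GAUSSIAN_CONVENTIONS)}"
        ) from None


@dataclass(frozen=True)
class GaussianComponent:
    """L-subpopulation component: center ``x01`` and width ``w01`` (a.u.)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"Gaussian width must be > 0, got {self.width}")

    def sigma(self, convention: str = "half") -> float:
        """Standard deviation implied by ``width`` under ``convention``."""
        return self.width / _check_convention(convention)


@dataclass(frozen=True)
class LognormalComponent:
    """H-subpopulation component: log-mean ``x02`` and log-sd ``w02``.

    Both parameters are on the natural-log scale of intensity; the median of
    the distribution is ``exp(x02)`` and the mode ``exp(x02 - w02**2)``.
    """

    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError(f"lognormal log-sd must be > 0, got {self.log_sd}")

    @property
    def median(self) -> float:
        return float(np.exp(self.log_mean))

    @property
    def mode(self) -> float:
        return float(np.exp(self.log_mean - self.log_sd**2))

    @property
    def mean(self) -> float:
        return float(np.exp(self.log_mean + self.log_sd**2 / 2))


@dataclass(frozen=True)
class GammaComponent:
    """Gamma alternative for the H subpopulation (shape, scale)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"gamma shape and scale must be > 0, got "
                f"({self.shape}, {self.scale})"
            )

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class MixtureModel:
    """Two invariant components with per-time-point weights.

    ``weights`` maps a time label (e.g. ``"18h"``) to ``(C1, C2)``.  In
    density mode the weights at each time point are fractions summing to 1;
    :meth:`count_scaled_weights` gives the count-scaled view ``C_i * N`` used
    for histogram overlays.
    """

    gaussian: GaussianComponent
    lognormal: LognormalComponent
    weights: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, (c1, c2) in self.weights.items():
            if c1 < 0 or c2 < 0:
                raise ValueError(f"negative mixture weight at t={t!r}: ({c1}, {c2})")

    def weight_at(self, t: str) -> tuple[float, float]:
        try:
            return self.weights[t]
        except KeyError:
            raise KeyError(
                f"unknown time label {t!r}; known labels: {sorted(self.weights)}"
            ) from None

    def count_scaled_weights(self, t: str, n_events: int) -> tuple[float, float]:
        """Weights scaled by the event count, for overlay on count histograms."""
        c1, c2 = self.weight_at(t)
        return c1 * n_events, c2 * n_events


def gaussian_pdf(
    x, comp: GaussianComponent, convention: str = "half"
) -> np.ndarray | float:
    """Gaussian L-component density at ``x`` (units 1/a.u.)."""
    sigma = comp.sigma(convention)
    return stats.norm.pdf(np.asarray(x, dtype=float), loc=comp.center, scale=sigma)


def lognormal_pdf(x, comp: LognormalComponent) -> np.ndarray | float:
    """Lognormal H-component density at ``x``; zero for x <= 0."""
    return stats.lognorm.pdf(
        np.asarray(x, dtype=float), s=comp.log_sd, scale=np.exp(comp.log_mean)
    )


def gamma_pdf(x, comp: GammaComponent) -> np.ndarray | float:
    """Gamma density at ``x``; zero for x < 0."""
    return stats.gamma.pdf(np.asarray(x, dtype=float), a=comp.shape, scale=comp.scale)


def component_pdf(x, comp, convention: str = "half"):
    """Dispatch to the density of whichever component type ``comp`` is."""
    if isinstance(comp, GaussianComponent):
        return gaussian_pdf(x, comp, convention=convention)
    if isinstance(comp, LognormalComponent):
        return lognormal_pdf(x, comp)
    if isinstance(comp, GammaComponent):
        return gamma_pdf(x, comp)
    raise TypeError(f"unsupported component type: {type(comp).__name__}")


def mixture_pdf(
    x, model: MixtureModel, t: str, convention: str = "half"
) -> np.ndarray | float:
    """Population density ``C1(t) P1(x) + C2(t) P2(x)`` at time label ``t``."""
    c1, c2 = model.weight_at(t)
    return c1 * gaussian_pdf(x, model.gaussian, convention=convention) + (
        c2 * lognormal_pdf(x, model.lognormal)
    )


def sample_component(
    comp,
    n: int,
    seed: int | np.random.Generator,
    convention: str = "half",
    clip_negative: bool = False,
) -> np.ndarray:
    """Draw ``n`` i.i.d. intensities from a component's law.

    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`.
    ``clip_negative`` clips Gaussian draws at 0 for synthetic realism
    (measured intensities are nonnegative); off by default to match the
    untruncated analytic form.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(comp, GaussianComponent):
        draws = rng.normal(comp.center, comp.sigma(convention), size=n)
        if clip_negative:
            draws = np.clip(draws, 0.0, None)
        return draws
    if isinstance(comp, LognormalComponent):
        return np.exp(rng.normal(comp.log_mean, comp.log_sd, size=n))
    if isinstance(comp, GammaComponent):
        return rng.gamma(comp.shape, comp.scale, size=n)
    raise TypeError(f"unsupported component type: {type(comp).__name__}")
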