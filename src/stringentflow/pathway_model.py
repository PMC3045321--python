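"""Deterministic MprAB-SigE-Rel pathway model with growth-retardation dilution.

The stringent-response circuit is modelled with seven species: the response
regulator MprA and sensor kinase MprB (products of the positively
autoregulated *mprAB* operon), their phosphorylated forms MprA-P and MprB-P,
the sigma factor SigE (transcribed under MprA-P control), and Rel and GFP
(both transcribed under SigE control; GFP is the reporter of the *rel*
promoter).  Reactions:

* operon transcription: basal rate plus an MprA-P-activated Hill term with
  coefficient ``n`` (default 1, noncooperative), feeding both MprA and MprB;
* MprB autophosphorylation at rate ``k_auto`` (poly-P is the implicit
  phosphate donor; ``k_auto`` lumps its availability and is the swept
  bifurcation parameter);
* phosphotransfer MprB-P + MprA -> MprB + MprA-P (mass action);
* MprB acting as an MprA-P phosphatase: MprA-P + MprB -> MprA + MprB;
* SigE synthesis activated by MprA-P; Rel and GFP synthesis activated by
  SigE (Michaelis-Menten-type saturating activation);
* every species is lost at the effective decay rate
  ``gamma_eff(x) = gamma + phi / (1 + theta * x)``, the sum of intrinsic
  degradation and growth dilution under the growth-retardation law, with
  ``x`` the summed stress-protein concentration (a per-species option
  exists).

With ``theta = 0`` and ``n = 1`` neither feedback loop is ultrasensitive and
the model is monostable for every ``k_auto``; growth retardation
(``theta > 0``) restores bistability and hysteresis without cooperativity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SPECIES",
    "PathwayParams",
    "REFERENCE_PARAMS",
    "REFERENCE_K_RANGE",
    "SteadyState",
    "Branch",
    "BistableWindow",
    "pathway_rhs",
    "simulate_pathway",
    "find_steady_states",
    "hysteresis_scan",
    "bistable_window",
    "inflection_metrics",
]

#: state vector ordering
SPECIES = ("MprA", "MprB", "MprA_P", "MprB_P", "SigE", "Rel", "GFP")
_IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class PathwayParams:
    """Rate constants of the pathway model (concentrations in arbitrary units)."""

    a0: float  # basal mprAB transcription, conc/h
    a1: float  # maximal activated mprAB transcription, conc/h
    K_a: float  # MprA-P activation constant at the mprAB promoter, conc
    n: float  # Hill coefficient of operon activation (1 = noncooperative)
    k_auto: float  # MprB autophosphorylation rate, 1/h (bifurcation parameter)
    k_t: float  # phosphotransfer MprB-P -> MprA, 1/(conc h)
    k_p: float  # MprB phosphatase activity on MprA-P, 1/(conc h)
    e0: float  # basal sigE transcription, conc/h
    e1: float  # maximal MprA-P-activated sigE transcription, conc/h
    K_e: float  # MprA-P activation constant at the sigE promoter, conc
    r1: float  # maximal SigE-activated rel/gfp transcription, conc/h
    K_r: float  # SigE activation constant at the rel promoter, conc
    gamma: float  # intrinsic protein decay, 1/h
    phi: float  # maximal dilution (specific growth) rate, 1/h
    theta: float  # growth retardation per unit stress protein, 1/conc
    per_species_dilution: bool = False  # gamma_eff from each species alone

    def __post_init__(self) -> None:
        for name in (
            "a0", "a1", "K_a", "k_auto", "k_t", "k_p",
            "e0", "e1", "K_e", "r1", "K_r", "gamma", "phi", "theta",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    def gamma_eff(self, x_tot):
        """Effective decay gamma + phi/(1 + theta x); in [gamma, gamma+phi]."""
        return self.gamma + self.phi / (1.0 + self.theta * np.asarray(x_tot))


#: reference parameter set; committed implementation constants chosen so the
#: bistable window sits within one decade of the k_auto sweep
REFERENCE_PARAMS = PathwayParams(
    a0=0.05,
    a1=3.0,
    K_a=2.0,
    n=1.0,
    k_auto=0.2,
    k_t=4.0,
    k_p=10.0,
    e0=0.01,
    e1=3.0,
    K_e=1.0,
    r1=3.0,
    K_r=1.0,
    gamma=0.05,
    phi=1.0,
    theta=1.0,
)

#: k_auto sweep that brackets the reference set's bistable window
REFERENCE_K_RANGE = np.linspace(0.02, 1.0, 25)


def pathway_rhs(state, params: PathwayParams) -> np.ndarray:
    """Time derivatives of all seven species at ``state``.

    Phosphorylation reactions interconvert (they neither create nor destroy
    protein), so summed MprA + MprA-P changes only through synthesis and
    decay; the same holds for MprB.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(SPECIES),):
        raise ValueError(f"state must have shape ({len(SPECIES)},), got {y.shape}")
    if np.any(y < 0):
        raise ValueError(f"negative concentration in state: {y}")
    A, B, Ap, Bp, E, R, G = y

    p = params
    # operon transcription: basal + Hill activation by MprA-P
    hill = Ap**p.n / (p.K_a**p.n + Ap**p.n) if Ap > 0 else 0.0
    tx_operon = p.a0 + p.a1 * hill
    transfer = p.k_t * Bp * A  # MprB-P + MprA -> MprB + MprA-P
    dephos = p.k_p * B * Ap  # MprB dephosphorylates MprA-P
    auto = p.k_auto * B

    if p.per_species_dilution:
        g = p.gamma_eff(y)
    else:
        g = np.full(len(SPECIES), p.gamma_eff(y.sum()))

    dA = tx_operon - transfer + dephos - g[_IDX["MprA"]] * A
    dB = tx_operon - auto + transfer - g[_IDX["MprB"]] * B
    dAp = transfer - dephos - g[_IDX["MprA_P"]] * Ap
    dBp = auto - transfer - g[_IDX["MprB_P"]] * Bp
    dE = p.e0 + p.e1 * Ap / (p.K_e + Ap) - g[_IDX["SigE"]] * E
    dR = p.r1 * E / (p.K_r + E) - g[_IDX["Rel"]] * R
    dG = p.r1 * E / (p.K_r + E) - g[_IDX["GFP"]] * G
    return np.array([dA, dB, dAp, dBp, dE, dR, dG])


def simulate_pathway(
    params: PathwayParams,
    init,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the pathway ODEs on ``t_grid`` (hours).

    Returns an array of shape ``(len(t_grid), 7)`` in :data:`SPECIES` order.
    Uses a stiff-capable integrator (LSODA); tiny negative excursions from
    roundoff are clipped to zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-d and strictly increasing")
    y0 = np.asarray(init, dtype=float)

    def rhs(_t, y):
        return pathway_rhs(np.clip(y, 0.0, None), params)

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"pathway integration failed: {sol.message}")
    return np.clip(sol.y.T, 0.0, None)


def _settle(params: PathwayParams, y0, horizon: float = 2000.0) -> np.ndarray:
    """Integrate to a long horizon and polish the endpoint to a root."""
    traj = simulate_pathway(
        params, y0, np.array([0.0, horizon]), rtol=1e-9, atol=1e-11
    )
    y_end = traj[-1]
    sol = root(lambda y: pathway_rhs(np.clip(y, 0.0, None), params), y_end,
               method="hybr", tol=1e-12)
    y_star = np.clip(sol.x, 0.0, None) if sol.success else y_end
    return y_star


def _jacobian(params: PathwayParams, y, h: float = 1e-6) -> np.ndarray:
    n = len(SPECIES)
    J = np.empty((n, n))
    f0 = pathway_rhs(y, params)
    for j in range(n):
        step = h * max(abs(y[j]), 1.0)
        yp = y.copy()
        yp[j] += step
        J[:, j] = (pathway_rhs(np.clip(yp, 0.0, None), params) - f0) / step
    return J


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    stable: bool
    residual: float


def _saddle_between(
    params: PathwayParams, y_a: np.ndarray, y_b: np.ndarray, tol: float
) -> np.ndarray | None:
    """Root on the basin boundary between two stable states, if one exists."""

    def basin(alpha: float) -> bool:
        y = _settle(params, (1 - alpha) * y_a + alpha * y_b, horizon=500.0)
        return np.linalg.norm(y - y_a) < np.linalg.norm(y - y_b)

    lo, hi = 0.0, 1.0
    if basin(lo) == basin(hi):  # same basin; no separatrix on this segment
        return None
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if basin(mid) == basin(lo):
            lo = mid
        else:
            hi = mid
    y0 = (1 - 0.5 * (lo + hi)) * y_a + 0.5 * (lo + hi) * y_b
    sol = root(
        lambda y: pathway_rhs(np.clip(y, 0.0, None), params),
        y0, method="hybr", tol=1e-12,
    )
    if not sol.success:
        return None
    y_sad = np.clip(sol.x, 0.0, None)
    if float(np.max(np.abs(pathway_rhs(y_sad, params)))) > tol:
        return None
    return y_sad


def inflection_metrics(t, g) -> tuple[float, float]:
    """Shape of an induction curve: inflection time and rise fraction there.

    Returns ``(t_inflect, rise_fraction)`` where ``t_inflect`` is the time of
    the maximal slope of ``g(t)`` and ``rise_fraction`` the fraction of the
    total rise already completed at that time.  A sigmoidal (S-shaped)
    induction has an interior inflection after an appreciable part of the
    rise (fraction well above 0); a saturating (concave) rise puts the
    maximal slope at or near the start.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    dg = np.gradient(g, t)
    i = int(np.argmax(dg))
    total = g[-1] - g[0]
    frac = float((g[i] - g[0]) / total) if total > 0 else 0.0
    return float(t[i]), frac


def find_steady_states(
    params: PathwayParams,
    n_starts: int = 20,
    seed: int = 0,
    scale: float = 50.0,
    tol: float = 1e-8,
) -> list[SteadyState]:
    """Multi-start search for steady states with linear stability flags.

    Random log-uniform initial states are integrated to a long horizon and
    polished with a damped Newton (hybrid) root solve; converged roots are
    de-duplicated with a relative tolerance and classified by the sign of the
    leading Jacobian eigenvalue.  Returns an empty list if nothing converges.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts = [np.zeros(len(SPECIES))]
    starts += [
        np.exp(rng.uniform(np.log(1e-3), np.log(scale), size=len(SPECIES)))
        for _ in range(n_starts - 1)
    ]
    found: list[np.ndarray] = []
    for y0 in starts:
        y_star = _settle(params, y0)
        res = float(np.max(np.abs(pathway_rhs(y_star, params))))
        if res > tol:
            continue
        if any(
            np.allclose(y_star, y, rtol=1e-4, atol=1e-6) for y in found
        ):
            continue
        found.append(y_star)
    # an unstable state between two stable ones is never reached by forward
    # integration; locate the basin boundary by bisection along the line
    # between each stable pair and root-polish from there
    if len(found) >= 2:
        for i in range(len(found)):
            for j in range(i + 1, len(found)):
                y_sad = _saddle_between(params, found[i], found[j], tol)
                if y_sad is not None and not any(
                    np.allclose(y_sad, y, rtol=1e-4, atol=1e-6) for y in found
                ):
                    found.append(y_sad)
    out = []
    for y in found:
        eigs = np.linalg.eigvals(_jacobian(params, y))
        res = float(np.max(np.abs(pathway_rhs(y, params))))
        out.append(SteadyState(state=y, stable=bool(np.max(eigs.real) < 0),
                               residual=res))
    return out


@dataclass
class Branch:
    """One hysteresis branch: steady-state values along a k_auto sweep."""

    k_values: np.ndarray
    states: np.ndarray  # shape (len(k_values), 7)
    direction: str  # "up" or "down"
    species: str = "GFP"

    @property
    def values(self) -> np.ndarray:
        return self.states[:, _IDX[self.species]]


@dataclass(frozen=True)
class BistableWindow:
    k_lo: float
    k_hi: float

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.k_lo)

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.k_hi - self.k_lo


def hysteresis_scan(
    params: PathwayParams,
    k_range,
    direction: str = "up",
    species: str = "GFP",
) -> Branch:
    """Continuation sweep of ``k_auto``: follow the steady state branch.

    ``k_range`` must be ordered increasing for ``direction="up"`` and
    decreasing for ``"down"``.  The first point settles from a low (zero)
    state on the up sweep or from a long integration at the highest ``k``
    on the down sweep; each subsequent point settles from the previous
    steady state, which is what makes the sweep history-dependent.
    """
    k = np.asarray(k_range, dtype=float)
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if direction == "up" and np.any(np.diff(k) <= 0):
        raise ValueError("up sweep needs strictly increasing k_range")
    if direction == "down" and np.any(np.diff(k) >= 0):
        raise ValueError("down sweep needs strictly decreasing k_range")
    if species not in _IDX:
        raise ValueError(f"unknown species {species!r}")

    y = np.zeros(len(SPECIES))
    states = np.empty((k.size, len(SPECIES)))
    for i, kv in enumerate(k):
        p = replace(params, k_auto=float(kv))
        y = _settle(p, y)
        states[i] = y
    return Branch(k_values=k, states=states, direction=direction,
                  species=species)


def bistable_window(
    params: PathwayParams,
    k_range,
    species: str = "GFP",
    rel_tol: float = 0.05,
) -> BistableWindow:
    """Interval of ``k_auto`` where up- and down-sweep branches separate.

    Branches are compared pointwise on the sweep grid; a point is inside the
    window when the branch values differ by more than ``rel_tol`` of the
    larger branch value.  Empty windows are reported with NaN bounds.
    """
    k = np.sort(np.asarray(k_range, dtype=float))
    up = hysteresis_scan(params, k, "up", species=species)
    down = hysteresis_scan(params, k[::-1], "down", species=species)
    v_up = up.values
    v_down = down.values[::-1]
    scale = np.maximum(np.maximum(v_up, v_down), 1e-12)
    separated = np.abs(v_down - v_up) / scale > rel_tol
    if not np.any(separated):
        return BistableWindow(k_lo=np.nan, k_hi=np.nan)
    inside = k[separated]
    return BistableWindow(k_lo=float(inside.min()), k_hi=float(inside.max()))
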