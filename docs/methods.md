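# Methods

## Scope and model

`stringentflow` quantifies phenotypic heterogeneity in a nutrient-starved
mycobacterial population carrying a GFP transcriptional reporter of the
stringent-response pathway (*mprA*, *sigE* or *rel* promoter fusions). The
statistical core is the claim that the single-cell fluorescence distribution
at every acquisition time t is a superposition of two *time-invariant*
component densities,

    P(x, t) = C1(t) P1(x) + C2(t) P2(x),

with P1 Gaussian (the low-expression L subpopulation), P2 lognormal (the
high-expression H subpopulation), and only the weights C1, C2 changing as
cells switch from L to H. Around that sit: stochastic binning of cells into
the two overlapping subpopulations, per-subpopulation time-course statistics,
the growth-retardation law linking protein burden to specific growth rate,
and a deterministic ODE model of the MprAB–SigE–Rel circuit whose
growth-retardation feedback produces bistability and hysteresis without
cooperative transcription.

## Gaussian width convention

The L component is parameterised by a center `x01` and width `w01`. The
default density is the peak-normalised form

    P1(x) = exp(-2 ((x - x01)/w01)^2) / (w01 sqrt(pi/2)),

a proper density with standard deviation `sigma = w01/2`. This is the unique
normalisation consistent with a `w01 sqrt(pi/2)` prefactor. The plain-sigma
alternative (`sigma = w01/sqrt(2)`, prefactor `w01 sqrt(pi)`) is kept behind
the `convention="root2"` switch; all fitted widths are reported in the
default convention. The Gaussian support formally extends below zero while
measured intensities do not; no truncation is applied in density mode, and
samplers only clip at zero when asked (`clip_negative=True`, off by default).

## Joint mixture fit

`fit_joint_timecourse` is an expectation–maximisation scheme on raw events
(not histograms, avoiding bin-width sensitivity):

* E-step: per-event responsibilities using each time point's own weights
  `(C1(t), C2(t))`.
* M-step: weights re-estimated per time point; the shared Gaussian and
  lognormal parameters from sufficient statistics pooled across *all* time
  points — this is what enforces time-invariant components.
* Initialisation: deterministic median split of the pooled events; the
  Gaussian is moment-matched below the median, the lognormal above. The
  split also fixes label identity (the Gaussian is the low-mean component).
* Convergence: relative change of the joint log-likelihood below 1e-8, cap
  2000 iterations (EM is near-degenerate and slow when one weight approaches
  the boundary — effectively unimodal data needs 1000+ iterations); failure
  raises a `ConvergenceError` carrying the last iterate. The log-likelihood
  trace is retained so monotonicity is checkable.

On data with no H subpopulation at all, the exact MLE does not drive C2 to
zero at finite n: the lognormal absorbs finite-sample skew worth a few nats,
leaving C2 of order 0.01–0.05 at n = 20,000 and shrinking with n. This is a
property of the likelihood surface, not a defect of the optimiser.

Lognormal-versus-gamma comparison for the H subpopulation
(`compare_families`) uses per-family maximum likelihood and AIC
(`2k − 2 log L`, k = 2 for each family); skewed data separate the families
clearly while high-shape gamma draws produce nearly tied AICs, matching the
known near-interchangeability of the two laws for mildly skewed data.

## Stochastic binning and statistics

Membership ratios follow the unweighted form
`g1(x) = P1(x) / (P1(x) + P2(x))`; a weighted-posterior variant
(`C1 P1 / (C1 P1 + C2 P2)`) is available behind `weighted=True` but is not
the default. Each cell is assigned L if a fresh uniform draw r satisfies
`r < g1(x_j)`; one seeded generator per binning call, events processed in
input order, so labelings are exactly reproducible. Variances use the
`N_i − 1` denominator and are undefined (NaN) for subpopulations with fewer
than two members; `CV = sd/mean`.

The L→H transition rate over `[t_a, t_b]` is the per-capita one-way flux

    (omega_2(t_b) − omega_2(t_a)) / ((t_b − t_a) * omega_1(t_a)),

reported at interval midpoints and undefined where the L pool is empty. This
estimator is an interpretive choice: it is the minimal kinetic reading of a
gradual one-way L→H conversion, and other definitions (fitted kinetic
models) would differ mainly once `omega_1` is small.

## Growth kinetics

Specific growth rate is `mu(t) = d(ln N)/dt`, estimated by differentiating a
cubic smoothing spline fitted to log-OD (interpolating by default; a
`smoothing` parameter admits noisy curves; ≤ 5 points fall back to central
finite differences). Working on the log scale makes the estimate exactly
invariant to the OD-to-cell-count calibration (1 OD600 = 1e8 cells is kept
only as a constant for count conversion).

Monod growth `mu = mu_max s/(k + s)` with a protein burden
`epsilon = lambda x` rescaling the available nutrient to `s(1 − epsilon)`
reduces, to first order in epsilon, to the reciprocal growth-retardation law

    mu(x) = phi / (1 + theta x),  phi = mu_max s/(s+k),  theta = k lambda/(s+k).

`fit_growth_retardation` fits (phi, theta) by unweighted nonlinear least
squares on mu (start: max mu, theta = 0.01; theta bounded at 0). The default
GFP-proxy parameters used by the synthetic generator are phi = 0.94 /h and
theta = 0.317 per intensity unit.

## Pathway model

Seven species (MprA, MprB, MprA-P, MprB-P, SigE, Rel, GFP), mass-action
phospho-reactions and saturating transcription:

* operon synthesis `a0 + a1 Ap^n/(K_a^n + Ap^n)` feeding MprA and MprB
  (n = 1 by default: no cooperativity);
* MprB autophosphorylation at `k_auto` (lumping poly-P availability; the
  swept bifurcation parameter), phosphotransfer `k_t Bp A`, MprB phosphatase
  action on MprA-P `k_p B Ap`;
* SigE synthesis activated by MprA-P, Rel and GFP synthesis activated by
  SigE (Michaelis–Menten forms);
* every species decays at `gamma_eff = gamma + phi/(1 + theta x_tot)` with
  `x_tot` the summed concentration of all seven species (a per-species
  option exists behind `per_species_dilution`).

The functional forms (mass action for the phosphorelay, Hill/MM for
transcription, a shared dilution term) are this package's own modelling
choices for the circuit architecture; the quantities the package stands
behind are the qualitative dynamical signatures — bistability over a window
of `k_auto`, hysteresis between up and down sweeps, no bistability at
`theta = 0` with `n = 1`, and sigmoidal induction only with the nonlinear
decay term — not any particular numeric steady-state curve.

The committed reference parameter set (`REFERENCE_PARAMS`: a0=0.05, a1=3,
K_a=2, k_t=4, k_p=10, e0=0.01, e1=3, K_e=1, r1=3, K_r=1, gamma=0.05, phi=1,
theta=1) was chosen so the bistable window (k_auto ≈ 0.11–0.42) sits within
one decade of the default sweep `REFERENCE_K_RANGE = linspace(0.02, 1, 25)`.
Window width versus theta is non-monotone globally (larger theta shifts the
window to smaller k_auto); over the tested grid theta ∈ {0, 0.5, 1} the
width is non-decreasing, which is the comparison that matters: retardation
creates the window.

Numerics: LSODA integration (rtol 1e-8, atol 1e-10, tiny negative excursions
clipped); steady states by long-horizon integration (2000 h) plus a hybrid
Newton polish, de-duplicated at 1e-4 relative tolerance; stability from the
sign of the leading eigenvalue of a finite-difference Jacobian. Saddle
points, unreachable by forward integration, are located by bisecting the
basin boundary on the segment joining each stable pair and polishing from
there. Hysteresis sweeps are continuations: each step settles from the
previous step's steady state. Branch separation beyond 5% (relative) marks
the bistable window.

## Synthetic data

The generator *defines* the study conditions rather than adapting to them:

* 20,000 events per acquisition (the standard cytometer acquisition size);
* truth components fixed to the fitted mprA reporter values (Gaussian
  97.3366 / 103.0731; lognormal 5.95526 / 0.17618; a sigE set is also
  shipped);
* H-fraction schedule logistic in time, midpoint 20 h, scale 2 h, sampled
  every 3 h over 12–30 h — a sigmoidal L→H conversion over a starvation
  course;
* logistic OD600 growth curves (mu0 = 0.35 /h, capacity 2.5 OD, inoculum
  0.02 OD, hourly over 36 h) with optional multiplicative lognormal noise;
* (x, mu) pairs on the reciprocal law with optional additive noise.

Each event's subpopulation is drawn Bernoulli(omega_2(t)), then its
intensity from the corresponding component; everything is determined by the
scenario seed (bit-reproducible). The "CV burst" scenario inflates the L
width by a constant factor over a chosen time window to emulate the
noise-driven transition narrative (CV_1 and transition rate peaking
together); it is a constructed scenario, not a fitted one. The generator
does not emulate cytometer artifacts (gating, compensation, doublets,
log-amplifier binning), so passing recovery tests demonstrates correctness
of the estimators under the model's own assumptions, not robustness to
instrument effects.

## Problem sizes in the test suite

Unit suites run at 2,000–8,000 events per time point; recovery studies at
the full 20,000-event acquisition size (20 seeded replicates for the EM and
retardation-fit studies); binning convergence checks at 1e5 events;
hysteresis properties on 12–15-point sweeps; the theta=0 uniqueness check
samples 30 random initial states at three sweep points. These sizes make the
statistical assertions sharp (3-sigma or median-error bounds) while keeping
the whole suite a few minutes on one core.

## Known limitations

* The ODE model's rate constants are illustrative; no kinetic parameters for
  this circuit are fitted from data.
* The transition-rate estimator degrades as omega_1 → 0 (per-capita flux on
  a vanishing pool); compare the absolute flux there.
* Mixture weights near the 0/1 boundary slow EM markedly and leave the
  boundary-component parameters weakly identified.
* FCS ingestion covers plain list-mode files (float or unsigned-integer
  events, one data segment) — enough for standard cytometer exports, not
  the full breadth of the format.
* Modelling the time evolution of the subpopulation weights themselves
  (a kinetic model for omega_i(t)) is out of scope.
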