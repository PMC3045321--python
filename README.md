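# stringentflow

Quantitative analysis of bistable stringent-response activation in
mycobacteria from single-cell reporter fluorescence.

Nutrient-starved *Mycobacterium smegmatis* populations carrying GFP
transcriptional reporters of the stringent-response pathway (*mprA*, *sigE*,
*rel* promoter fusions) split into two phenotypes: a low-expression (L)
subpopulation of normally growing cells and a high-expression (H)
subpopulation of slow-growing, stress-adapted (persister-like) cells. This
package implements the quantitative machinery for analysing that
heterogeneity from flow-cytometry event data:

* **Mixture decomposition** — the fluorescence distribution at every
  acquisition time t is modelled as
  `P(x, t) = C1(t) P1(x) + C2(t) P2(x)` with a *time-invariant* Gaussian
  `P1` (L) and lognormal `P2` (H) and only the weights time-dependent;
  fitted jointly across all time points by EM on raw events
  (`fit_joint_timecourse`), with a lognormal-vs-gamma AIC comparison for the
  H component (`compare_families`).
* **Stochastic binning** — each cell j is assigned to L with probability
  `g1(x_j) = P1(x_j)/(P1(x_j) + P2(x_j))` against a uniform draw, then the
  per-subpopulation fractions `omega_i(t)`, means, variances (`N−1`
  denominator), CV and the L→H transition-rate series are computed
  (`analyze_timecourse`).
* **Growth retardation** — specific growth rate `mu = d(ln N)/dt` from OD600
  curves via a smoothing spline; the reciprocal burden law
  `mu(x) = phi/(1 + theta x)` (the first-order reduction of Monod growth
  with a protein burden on the nutrient supply) fitted to
  (GFP intensity, mu) pairs.
* **Pathway model** — a deterministic ODE model of the MprAB–SigE–Rel
  circuit (phosphorelay, noncooperative positive feedback, growth-retardation
  dilution `gamma_eff = gamma + phi/(1 + theta x_tot)`) with steady-state
  search, bistable-window detection and hysteresis sweeps versus the MprB
  autophosphorylation rate.
* **Synthetic data** — generators for mixture time courses (20,000 events
  per acquisition), logistic growth curves, and (x, mu) pairs, with recorded
  ground truth for recovery studies.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
from stringentflow import (
    SyntheticScenario, generate_flow_timecourse,
    fit_joint_timecourse, analyze_timecourse,
    generate_mu_x_pairs, fit_growth_retardation,
)

scenario = SyntheticScenario(seed=1)          # 7 time points x 20,000 events
dataset, truth = generate_flow_timecourse(scenario)

fit = fit_joint_timecourse(dataset)           # shared components + weights
m = fit.model
print(m.gaussian, m.lognormal)

report = analyze_timecourse(dataset, m, seed=1)
print(report.stats.head(4))
print(report.transition_rates.head(3))

pairs = generate_mu_x_pairs(phi=0.94, theta=0.317)
r = fit_growth_retardation(pairs["x"], pairs["mu"])
print(f"mu_max={r.phi:.4f} /h, theta={r.theta:.4f}")
```

prints (abridged):

```
Gaussian L : center=97.315  width=103.211
Lognormal H: log_mean=5.95476  log_sd=0.17590
time subpopulation     n   omega       mean    variance       cv
 12h             L 19561 0.97805  96.139819 2525.771035 0.522750
 12h             H   439 0.02195 360.745810 7854.648949 0.245676
 15h             L 18373 0.91865  97.315611 2588.070689 0.522764
 15h             H  1627 0.08135 382.053155 6021.562412 0.203110
 t_mid  rate_per_h
  13.5    0.020244
  16.5    0.069395
  19.5    0.162015
mu_max=0.9400 /h, theta=0.3170
```

The joint fit recovers the generating invariant components (Gaussian center
97.34, width 103.07; lognormal log-mean 5.95526, log-sd 0.17618) to a
fraction of a percent, the per-time weights track the scheduled H fraction,
and the binned report shows the H fraction rising while the L-subpopulation
statistics stay put — the signature of two invariant overlapping
subpopulations exchanging members. The retardation fit returns the
generating (0.94, 0.317) exactly on noiseless pairs.

A command-line interface covers the same stages:

```sh
stringentflow simulate-data --out-dir out --seed 1
stringentflow fit-mixture   --events out/events.csv --out-dir out
stringentflow stats         --events out/events.csv --model out/mixture_fit.yaml --seed 1 --out-dir out
stringentflow growth        --curve out/growth_curve.csv --out-dir out
stringentflow pathway-scan  --k-range 0.02,1.0,25 --direction up --out-dir out
```

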