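import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from stringentflow import (
    GaussianComponent,
    LognormalComponent,
    MixtureModel,
    analyze_timecourse,
    gaussian_pdf,
    lognormal_pdf,
    membership_ratios,
    stochastic_binning,
    subpopulation_summary,
    transition_rate_series,
)
from stringentflow.subpopulations import (
    UndefinedMembershipError,
    parse_time_label,
)
from stringentflow.synthetic_data import SyntheticScenario, generate_flow_timecourse


class TestMembership:
    def test_one_sided_support_far_left(self, mpra_model):
        # well below the lognormal's mass the Gaussian dominates entirely
        g1, g2 = membership_ratios(np.array([-50.0, 0.0, 10.0]), mpra_model)
        assert np.all(g1 > 0.999999)
        assert np.allclose(g1 + g2, 1.0)

    def test_half_membership_where_densities_cross(self, mpra_model):
        x_eq = brentq(
            lambda x: gaussian_pdf(x, mpra_model.gaussian)
            - lognormal_pdf(x, mpra_model.lognormal),
            150.0,
            400.0,
        )
        g1, g2 = membership_ratios(x_eq, mpra_model)
        assert g1[0] == pytest.approx(0.5, abs=1e-9)
        assert g2[0] == pytest.approx(0.5, abs=1e-9)

    def test_direct_substitution_at_x150(self, mpra_model):
        p1 = float(gaussian_pdf(150.0, mpra_model.gaussian))
        p2 = float(lognormal_pdf(150.0, mpra_model.lognormal))
        g1, _ = membership_ratios(150.0, mpra_model)
        assert g1[0] == pytest.approx(p1 / (p1 + p2), rel=1e-12)

    def test_undefined_membership_raises_with_event_index(self, mpra_model):
        # intensities absurdly far away underflow both densities
        with pytest.raises(UndefinedMembershipError, match="event 1"):
            membership_ratios(np.array([100.0, 1e9]), mpra_model)


class TestBinning:
    def test_certain_membership_labels_all_low(self):
        model = MixtureModel(
            gaussian=GaussianComponent(10.0, 4.0),
            lognormal=LognormalComponent(10.0, 0.1),  # mass near e^10
        )
        labels = stochastic_binning(np.full(200, 10.0), model, seed=0)
        assert np.all(labels == "L")

    def test_binomial_fraction_at_fixed_intensity(self, mpra_model):
        x0 = 250.0
        g1, _ = membership_ratios(x0, mpra_model)
        p = float(g1[0])
        assert 0.05 < p < 0.95  # genuinely stochastic assignment point
        n = 10**5
        labels = stochastic_binning(np.full(n, x0), mpra_model, seed=21)
        frac = np.mean(labels == "L")
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_seed_reproducibility(self, mpra_model):
        x = np.linspace(10.0, 600.0, 1000)
        a = stochastic_binning(x, mpra_model, seed=5)
        b = stochastic_binning(x, mpra_model, seed=5)
        np.testing.assert_array_equal(a, b)
        assert np.any(a != stochastic_binning(x, mpra_model, seed=6))

    def test_empty_events_rejected(self, mpra_model):
        with pytest.raises(ValueError):
            stochastic_binning(np.array([]), mpra_model, seed=0)

    def test_weighted_posterior_option_shifts_membership(self, mpra_model):
        # heavily H-weighted time point pushes borderline events toward H
        model = MixtureModel(
            gaussian=mpra_model.gaussian,
            lognormal=mpra_model.lognormal,
            weights={"30h": (0.05, 0.95)},
        )
        x = np.full(20_000, 300.0)
        plain = np.mean(stochastic_binning(x, model, seed=1) == "L")
        weighted = np.mean(
            stochastic_binning(x, model, seed=1, t="30h", weighted=True) == "L"
        )
        assert weighted < plain


class TestSummary:
    def test_textbook_mean_and_variance(self):
        events = np.array([1.0, 2.0, 3.0, 100.0])
        labels = np.array(["L", "L", "L", "H"])
        rep = subpopulation_summary(events, labels).set_index("subpopulation")
        assert rep.loc["L", "mean"] == pytest.approx(2.0)
        assert rep.loc["L", "variance"] == pytest.approx(1.0)  # N-1 = 2
        assert rep.loc["L", "cv"] == pytest.approx(0.5)

    def test_degenerate_partition_and_undefined_variance(self):
        events = np.array([5.0, 6.0, 7.0])
        rep = subpopulation_summary(events, ["H", "H", "H"]).set_index(
            "subpopulation"
        )
        assert rep.loc["H", "omega"] == 1.0
        assert rep.loc["L", "omega"] == 0.0
        assert np.isnan(rep.loc["L", "variance"])

    def test_fractions_sum_to_one_and_marginal_preservation(self, mpra_model):
        rng = np.random.default_rng(2)
        events = rng.uniform(5.0, 700.0, size=5000)
        labels = stochastic_binning(events, mpra_model, seed=3)
        rep = subpopulation_summary(events, labels)
        assert rep["omega"].sum() == pytest.approx(1.0, abs=1e-15)
        assert rep["n"].sum() == events.size
        pooled = (rep["n"] * rep["mean"]).sum() / events.size
        assert pooled == pytest.approx(events.mean(), rel=1e-12)

    def test_recovered_fraction_tracks_schedule(self):
        scenario = SyntheticScenario(
            schedule={"12h": 0.1, "20h": 0.5, "28h": 0.9}, seed=13
        )
        dataset, _ = generate_flow_timecourse(scenario)
        model = scenario.model
        for (t, x), w2 in zip(dataset, scenario.schedule.values()):
            labels = stochastic_binning(x, model, seed=31)
            rep = subpopulation_summary(x, labels).set_index("subpopulation")
            assert rep.loc["H", "omega"] == pytest.approx(w2, abs=0.02)

    def test_binned_means_match_quadrature_posterior_means(self, mpra_model):
        # analytic oracle: E[x | assigned L] under the mixture law
        c1, c2 = 0.6, 0.4
        gauss, logn = mpra_model.gaussian, mpra_model.lognormal

        def f(x):
            return c1 * gaussian_pdf(x, gauss) + c2 * lognormal_pdf(x, logn)

        def g1f(x):
            p1 = gaussian_pdf(x, gauss)
            p2 = lognormal_pdf(x, logn)
            return p1 / (p1 + p2) * f(x)

        lo, hi = -500.0, 3000.0
        mass_l, _ = quad(g1f, lo, hi, limit=400)
        mean_l, _ = quad(lambda x: x * g1f(x), lo, hi, limit=400)
        mean_l /= mass_l

        n = 10**5
        rng = np.random.default_rng(17)
        from stringentflow import sample_component

        n2 = rng.binomial(n, c2)
        events = np.concatenate(
            [
                sample_component(gauss, n - n2, rng),
                sample_component(logn, n2, rng),
            ]
        )
        labels = stochastic_binning(events, mpra_model, seed=55)
        xs = events[labels == "L"]
        se = xs.std(ddof=1) / np.sqrt(xs.size)
        assert abs(xs.mean() - mean_l) < 3 * se


class TestTransitionRates:
    @staticmethod
    def _stats_from_omega(times, omega2):
        rows = []
        for t, w2 in zip(times, omega2):
            rows.append({"time": t, "subpopulation": "L", "omega": 1 - w2})
            rows.append({"time": t, "subpopulation": "H", "omega": w2})
        return pd.DataFrame(rows)

    def test_constant_fraction_gives_zero_rates(self):
        stats = self._stats_from_omega(["1h", "2h", "3h"], [0.3, 0.3, 0.3])
        rates = transition_rate_series(stats)
        assert np.allclose(rates["rate_per_h"], 0.0)

    def test_direct_evaluation_of_the_flux_formula(self):
        stats = self._stats_from_omega(["10h", "12h"], [0.2, 0.4])
        rates = transition_rate_series(stats)
        # (0.4 - 0.2) / (2 h * 0.8)
        assert rates["rate_per_h"].iloc[0] == pytest.approx(0.125)
        assert rates["t_mid"].iloc[0] == pytest.approx(11.0)

    def test_logistic_schedule_peaks_near_inflection(self):
        times = np.arange(10, 31, 2)
        omega2 = 1 / (1 + np.exp(-(times - 20) / 2.0))
        stats = self._stats_from_omega([f"{t}h" for t in times], omega2)
        rates = transition_rate_series(stats)
        # per-capita flux d(omega2)/dt / omega1 for a logistic is
        # omega2(t)/(2 h); maximal where omega2 is largest before
        # omega1 -> 0 blows the estimator up; the *absolute* flux
        # d(omega2)/dt peaks at the inflection (t = 20)
        flux = np.gradient(omega2, times)
        assert times[np.argmax(flux)] == 20

    def test_undefined_rate_when_low_pool_empty(self):
        stats = self._stats_from_omega(["1h", "2h"], [1.0, 1.0])
        rates = transition_rate_series(stats)
        assert np.isnan(rates["rate_per_h"].iloc[0])

    def test_time_labels_parse_and_validate(self):
        assert parse_time_label("18h") == 18.0
        assert parse_time_label(" 18.5 h ") == 18.5
        with pytest.raises(ValueError):
            parse_time_label("eighteen")


class TestAnalyzeTimecourse:
    def test_empty_time_point_error_names_label(self, mpra_model):
        with pytest.raises(ValueError, match="20h"):
            analyze_timecourse(
                [("10h", np.array([1.0, 2.0])), ("20h", np.array([]))],
                mpra_model,
                seed=0,
            )

    def test_single_time_point_has_no_rates(self, mpra_model):
        rng = np.random.default_rng(1)
        report = analyze_timecourse(
            [("10h", rng.uniform(10, 500, 500))], mpra_model, seed=0
        )
        assert report.transition_rates is None
        assert len(report.cv_low) == 1

    def test_cv_peak_coincides_with_transition_peak(self):
        # mid-course noise burst in the L component while cells transition:
        # CV_1 and the transition rate should peak within one interval
        times = (12, 15, 18, 21, 24, 27, 30)
        scenario = SyntheticScenario(
            schedule={f"{t}h": 1 / (1 + np.exp(-(t - 21) / 2.0)) for t in times},
            events_per_timepoint=20_000,
            seed=23,
            cv_burst_factor=1.8,
            cv_burst_window=(19.0, 23.0),
        )
        dataset, _ = generate_flow_timecourse(scenario)
        report = analyze_timecourse(dataset, scenario.model, seed=29)
        cv = report.cv_low
        t_cv = cv["time_h"].iloc[int(np.nanargmax(cv["cv"].to_numpy()))]
        rates = report.transition_rates
        # compare against the absolute L->H flux to avoid the 1/omega_1
        # blow-up once the L pool has nearly emptied
        stats = report.stats
        w2 = (
            stats[stats["subpopulation"] == "H"]
            .assign(t=lambda d: d["time"].map(parse_time_label))
            .sort_values("t")
        )
        flux = np.diff(w2["omega"]) / np.diff(w2["t"])
        t_flux = rates["t_mid"].iloc[int(np.argmax(flux))]
        assert abs(t_cv - t_flux) <= 3.0  # one sampling interval
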