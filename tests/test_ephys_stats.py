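"""Peak extraction, Hill fitting, normalization, ratios, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peptidegate.ephys_stats import (
    ApplicationWindow,
    CurrentTrace,
    DoseResponseSet,
    classify_mutants,
    concentration_to_ph,
    dunnett_critical,
    enhancement_ratio,
    fit_dose_response_set,
    fit_hill,
    hill,
    measure_peak,
    normalize_to_reference,
    ph_to_concentration,
    potency_ratio,
)
from peptidegate.synthetic_data import (
    TraceSimConfig,
    simulate_dose_response,
    simulate_trace,
)


class TestMeasurePeak:
    def _flat(self, value=0.0):
        t = np.arange(0, 10, 0.01)
        return CurrentTrace(t, np.full_like(t, value), [ApplicationWindow(2.0, 7.0)])

    def test_flat_zero_trace(self):
        assert measure_peak(self._flat(), ApplicationWindow(2.0, 7.0)) == 0.0

    def test_baseline_offset_invariance(self):
        cfg = TraceSimConfig(noise_sd=0.0, peak_amplitude=-4.0)
        trace, truth = simulate_trace(cfg)
        w = trace.application_windows[0]
        p0 = measure_peak(trace, w)
        shifted = CurrentTrace(trace.time, trace.current + 0.5, [w])
        assert measure_peak(shifted, w) == pytest.approx(p0, abs=1e-12)

    def test_recovers_analytic_peak_of_noiseless_pulse(self):
        cfg = TraceSimConfig(
            noise_sd=0.0, peak_amplitude=-4.0, tau_desensitization=1.0
        )
        trace, truth = simulate_trace(cfg)
        p = measure_peak(trace, trace.application_windows[0])
        assert p == pytest.approx(truth.true_peak, rel=1e-3)

    def test_sign_preserved_for_inward_currents(self):
        cfg = TraceSimConfig(noise_sd=0.0, peak_amplitude=-4.0)
        trace, _ = simulate_trace(cfg)
        assert measure_peak(trace, trace.application_windows[0]) < 0

    def test_missing_baseline_is_an_error(self):
        t = np.arange(0, 5, 0.01)
        tr = CurrentTrace(t, np.zeros_like(t), [ApplicationWindow(0.5, 2.0)])
        with pytest.raises(ValueError):
            measure_peak(tr, tr.application_windows[0])


class TestHillFit:
    def test_exact_recovery_of_noiseless_curve(self):
        c = np.array([1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5])
        y = hill(c, 1e-6, 1.0, 1.0)
        fit = fit_hill(c, y)
        assert fit.converged
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-4)
        assert fit.hill_n == pytest.approx(1.0, rel=1e-3)
        assert fit.imax == pytest.approx(1.0, rel=1e-3)

    def test_half_max_identity(self):
        assert hill(np.array([2e-6]), 2e-6, 1.7, 3.0)[0] == pytest.approx(1.5)

    def test_sign_of_peaks_is_immaterial(self):
        c = np.array([1e-7, 1e-6, 1e-5, 1e-4])
        y = hill(c, 1e-6, 1.0, 2.0)
        assert fit_hill(c, -y).ec50 == pytest.approx(fit_hill(c, y).ec50)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(np.array([1e-6, 1e-5]), np.array([0.3, 0.8]))

    def test_median_recovery_under_multiplicative_noise(self):
        ds, truth = simulate_dose_response(
            3.4e-6, n_recordings=50, noise_sd_fraction=0.05, seed=2
        )
        res = fit_dose_response_set(ds)
        med = res["summary"]["ec50_median"]
        assert abs(np.log10(med) - np.log10(truth.true_ec50)) < 0.05

    def test_scale_equivariance(self):
        ds, _ = simulate_dose_response(1e-6, n_recordings=3, noise_sd_fraction=0.05, seed=5)
        scaled = DoseResponseSet(ds.table.assign(peak_uA=ds.table["peak_uA"] * 7.0))
        a = fit_dose_response_set(ds)["summary"]
        b = fit_dose_response_set(scaled)["summary"]
        assert b["ec50_mean"] == pytest.approx(a["ec50_mean"], rel=1e-6)


class TestNormalization:
    def _table(self):
        rows = []
        for batch, scale in (("b1", 10.0), ("b2", 20.0)):
            rows.append(("wt1" + batch, batch, 1e-4, -scale, "WT"))
            rows.append(("mut1" + batch, batch, 1e-4, -scale / 2, "M1"))
        return DoseResponseSet(
            pd.DataFrame(
                rows,
                columns=["recording_id", "batch_id", "concentration_M", "peak_uA", "construct"],
            )
        )

    def test_reference_maps_to_one_and_batches_are_independent(self):
        df = normalize_to_reference(self._table(), "WT")
        assert set(df.loc[df["construct"] == "WT", "peak_norm"]) == {1.0}
        assert set(df.loc[df["construct"] == "M1", "peak_norm"]) == {0.5}

    def test_batch_without_reference_is_an_error(self):
        ds = self._table()
        bad = DoseResponseSet(
            pd.concat(
                [
                    ds.table,
                    pd.DataFrame(
                        [("x", "b3", 1e-4, -1.0, "M1")], columns=ds.table.columns
                    ),
                ]
            )
        )
        with pytest.raises(ValueError, match="b3"):
            normalize_to_reference(bad, "WT")


class TestPotencyRatio:
    def test_identical_pairs_give_unity(self):
        r = potency_ratio(np.full(5, -2.0), np.full(5, -2.0))
        assert r.ratio == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        r = potency_ratio(np.array([-3.2]), np.array([-5.0]))
        assert r.ratio == pytest.approx(0.64)

    def test_noise_floor_exclusion_is_counted(self):
        r = potency_ratio(
            np.array([1.0, 1.0]), np.array([5.0, 0.01]), noise_floor=0.1
        )
        assert r.n == 1 and r.n_excluded == 1


class TestEnhancement:
    def test_identical_pulses_give_unity(self):
        r = enhancement_ratio(np.full(4, -0.5), np.full(4, -0.5))
        assert r.fold == pytest.approx(1.0)

    def test_hand_computed_fold(self):
        r = enhancement_ratio(np.array([-0.1]), np.array([-1.0]))
        assert r.fold == pytest.approx(10.0)

    def test_subfloor_control_is_flagged_and_floored(self):
        r = enhancement_ratio(
            np.array([0.01, 0.5]), np.array([1.0, 1.0]), noise_floor=0.05
        )
        assert r.n_flagged == 1
        assert r.per_recording[0] == pytest.approx(1.0 / 0.05)


class TestClassification:
    def test_silent_construct_labeled_no_response(self, rng):
        groups = {
            "WT": rng.normal(0.64, 0.03, 6),
            "dead": rng.normal(0.5, 0.3, 5),
        }
        amps = {"dead": rng.normal(0.0, 0.05, 5)}
        classes = classify_mutants(groups, amplitudes=amps, seed=1)
        assert classes["dead"].label == "no_response"

    def test_strong_loss_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        detected = 0
        for _ in range(100):
            groups = {
                "WT": rng.normal(0.64, 0.64 * 0.05, 5),
                "loss": rng.normal(0.10, 0.10 * 0.05, 5),
            }
            if classify_mutants(groups, seed=0)["loss"].label == "reduced":
                detected += 1
        assert detected >= 95

    def test_missing_wt_is_an_error(self):
        with pytest.raises(ValueError):
            classify_mutants({"m1": np.ones(4)})

    def test_monte_carlo_critical_matches_scipy_dunnett(self):
        """Compare against the closed-form multivariate-t implementation."""
        rng = np.random.default_rng(8)
        sizes = (6, 6, 6, 6)
        df = sum(sizes) - len(sizes)
        crit = dunnett_critical(sizes, df, 0.05, "less", n_draws=400_000, seed=5)
        # scipy gives p-values; check that a t-statistic at the critical
        # value produces p close to alpha for the same design
        control = rng.normal(0.0, 1.0, sizes[0])
        control = (control - control.mean()) / control.std(ddof=1)  # mean 0, sd 1
        samples = []
        for n in sizes[1:]:
            g = rng.normal(0.0, 1.0, n)
            samples.append((g - g.mean()) / g.std(ddof=1))
        # place one group's mean exactly at the critical difference
        pooled = 1.0  # all groups standardized
        delta = crit * pooled * np.sqrt(1 / sizes[1] + 1 / sizes[0])
        samples[0] = samples[0] - delta
        res = stats.dunnett(*samples, control=control, alternative="less")
        assert res.pvalue[0] == pytest.approx(0.05, abs=0.006)


def test_ph_adapter_round_trips():
    assert ph_to_concentration(7.0) == pytest.approx(1e-7)
    assert ph_to_concentration(5.3) == pytest.approx(10**-5.3)
    for ph in (4.0, 5.3, 7.4):
        assert concentration_to_ph(ph_to_concentration(ph)) == pytest.approx(ph)
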