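"""Simulator state dynamics, scenario summaries and model invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import axonbrake as ab
from axonbrake import defaults
from axonbrake.traces import RateTrace


def tonic(rate, duration=2000.0, dt=1.0):
    return ab.make_tonic_rate(rate, duration, dt)


class TestSuppressionTrace:
    def test_tonic_firing_holds_background_level(self, dls):
        # Tonic ChI firing leaves only the beta term: S = 0.5 * 0.872.
        cfg = ab.SimConfig(beta=0.5, duration=2000.0)
        s, a = ab.compute_suppression_trace(tonic(5.0), dls, cfg)
        assert np.all(s.values == pytest.approx(0.436, abs=1e-12))
        assert np.all(a.values == 1.0)

    def test_sustained_silence_discharges_background(self, dls):
        # Delta-u = -1 drives S to clamp at 0 within one kernel support.
        cfg = ab.SimConfig(beta=0.5, duration=2000.0)
        s, _ = ab.compute_suppression_trace(tonic(0.0), dls, cfg)
        support_bins = int(np.ceil(dls.depression_support))
        assert np.all(s.values[support_bins:] == 0.0)

    def test_no_background_no_deviation_is_inert(self, dls):
        cfg = ab.SimConfig(beta=0.0, duration=1000.0)
        s, a = ab.compute_suppression_trace(tonic(5.0), dls, cfg)
        assert np.all(s.values == 0.0)
        assert np.all(a.values == 1.0)

    def test_suppression_bounded_by_depression_max(self, both_regions):
        # Even a strong sustained excitation cannot exceed D_max.
        for params in both_regions.values():
            cfg = ab.SimConfig(beta=1.0, duration=2000.0)
            chi = tonic(params.tonic_chi_rate * 4)
            s, a = ab.compute_suppression_trace(chi, params, cfg)
            assert np.all(s.values <= params.depression_max + 1e-12)
            assert np.all((a.values >= 0) & (a.values <= 1))

    def test_steady_state_matches_closed_form(self, dls):
        # Constant supra-tonic input: after burn-in S converges to
        # clamp(D_max * (beta + du * a_ss), 0, D_max), with a_ss from the
        # converged desensitization load (hand closed form).
        gamma = 0.8
        cfg = ab.SimConfig(beta=0.25, duration=3000.0, desensitization_gain=gamma)
        du = 0.5
        chi = tonic(5.0 * (1 + du), duration=3000.0)
        s, a = ab.compute_suppression_trace(chi, dls, cfg)
        a_ss = 1.0 - np.clip(gamma * du, 0.0, 1.0)  # unit-area kernel fully loaded
        expected = np.clip(dls.depression_max * (0.25 + du * a_ss), 0, dls.depression_max)
        assert a.values[-1] == pytest.approx(a_ss, abs=1e-9)
        assert s.values[-1] == pytest.approx(expected, abs=1e-9)

    def test_mismatched_dt_rejected(self, dls):
        cfg = ab.SimConfig(dt=1.0)
        with pytest.raises(ValueError, match="dt"):
            ab.compute_suppression_trace(ab.make_tonic_rate(5.0, 100.0, dt=0.5), dls, cfg)


class TestSimulateDao:
    def test_impulse_with_inert_chi_reproduces_kernel(self, dls):
        cfg = ab.SimConfig(beta=0.0, duration=3000.0)
        da = ab.resolve_da_pattern("impulse", 3000.0, 1.0)
        result = ab.simulate_dao(da, tonic(5.0, 3000.0), dls, cfg)
        kernel = cfg.release_kernel().samples
        onset = int(defaults.PATTERN_ONSET_MS)
        seg = result.dao.values[onset : onset + 500]
        np.testing.assert_allclose(seg, kernel[:500], atol=1e-12)

    def test_linearity_in_da_drive(self, dls):
        cfg = ab.SimConfig(beta=0.5, duration=1500.0)
        chi = ab.resolve_chi_pattern("multiphasic_with_excitation", 1500.0, 1.0)
        da = ab.resolve_da_pattern("burst", 1500.0, 1.0)
        base = ab.simulate_dao(da, chi, dls, cfg)
        doubled = ab.simulate_dao(da.with_values(2 * da.values), chi, dls, cfg)
        np.testing.assert_allclose(doubled.dao.values, 2 * base.dao.values, rtol=1e-12)

    def test_multiplier_and_summary_consistency(self, dls):
        cfg = ab.SimConfig(beta=0.5, duration=1500.0)
        chi = ab.resolve_chi_pattern("multiphasic_with_excitation", 1500.0, 1.0)
        da = ab.resolve_da_pattern("burst", 1500.0, 1.0)
        result = ab.simulate_dao(da, chi, dls, cfg)
        np.testing.assert_allclose(
            result.multiplier.values, 1.0 - result.suppression.values, atol=0
        )
        assert np.all(result.dao.values >= 0)
        assert result.peak == pytest.approx(result.dao.values.max())
        assert result.auc == pytest.approx(result.dao.values.sum() * result.dao.dt)

    def test_pause_raises_and_excitation_lowers_dao(self, dls):
        # Against tonic DA drive at half background, a brief ChI pause
        # transiently raises [DA]_o and a rate doubling transiently lowers it.
        duration, dt = 3500.0, 1.0
        onset = 2100  # past the full release-kernel rise, so baseline is steady
        cfg = ab.SimConfig(beta=0.5, duration=duration)
        da = tonic(4.0, duration)
        base = ab.make_tonic_rate(5.0, duration).values
        for factor, comparator in ((0.0, np.greater), (2.0, np.less)):
            chi_values = base.copy()
            chi_values[onset : onset + 100] = 5.0 * factor
            result = ab.simulate_dao(da, RateTrace(dt, chi_values), dls, cfg)
            baseline = result.dao.values[onset - 1]
            window = result.dao.values[onset : onset + 600]
            extremum = window.max() if comparator is np.greater else window.min()
            assert comparator(extremum, baseline)

    def test_grid_mismatch_rejected(self, dls):
        cfg = ab.SimConfig(duration=1000.0)
        with pytest.raises(ValueError):
            ab.simulate_dao(tonic(4.0, 1000.0), tonic(5.0, 500.0), dls, cfg)

    @given(seed=st.integers(0, 500))
    def test_raising_chi_never_raises_dao(self, dls, seed):
        # Bin-wise monotonicity: more ChI activity, less dopamine
        # (desensitization disabled so gating cannot mask added drive).
        rng = np.random.default_rng(seed)
        n = 400
        cfg = ab.SimConfig(
            beta=0.5, duration=float(n), desensitization_enabled=False,
            kernel=ab.make_parametric_kernel(dt=1.0, t_max=300.0),
        )
        da = RateTrace(1.0, rng.uniform(0, 10, n))
        chi = RateTrace(1.0, rng.uniform(0, 15, n))
        bump = rng.uniform(0, 5, n) * (rng.random(n) < 0.3)
        low = ab.simulate_dao(da, chi, dls, cfg)
        high = ab.simulate_dao(da, chi.with_values(chi.values + bump), dls, cfg)
        assert np.all(high.dao.values <= low.dao.values + 1e-12)


class TestScenarioSweep:
    def test_peak_strictly_decreasing_in_beta(self, dls):
        cfg = ab.SimConfig(duration=1500.0, da_tonic_rate=4.0)
        scenarios = [("burst", "tonic", b) for b in (0.0, 0.5, 1.0)]
        table = ab.scenario_sweep(scenarios, dls, cfg)
        peaks = table.sort_values("beta")["peak"].to_numpy()
        assert np.all(np.diff(peaks) < 0)

    def test_regions_crossed_with_scenarios(self, dls, nacc):
        cfg = ab.SimConfig(duration=1500.0)
        table = ab.scenario_sweep([("burst", "tonic", 0.5)], [dls, nacc], cfg)
        assert sorted(table["region"]) == ["DLS", "NAcc"]

    def test_unknown_pattern_label_rejected(self, dls):
        cfg = ab.SimConfig(duration=1500.0)
        with pytest.raises(ValueError, match="unknown ChI pattern"):
            ab.scenario_sweep([("burst", "bursty", 0.5)], dls, cfg)
        with pytest.raises(ValueError, match="unknown DA pattern"):
            ab.scenario_sweep([("ramp", "tonic", 0.5)], dls, cfg)


class TestExcitationRatio:
    def test_identity_and_reciprocal(self, dls, scenario_runner):
        no_exc = scenario_runner(dls, 0.0, "multiphasic_no_excitation")
        with_exc = scenario_runner(dls, 0.0, "multiphasic_with_excitation")
        ratio_peak, ratio_auc = ab.excitation_ratio(no_exc, with_exc)
        same = ab.excitation_ratio(no_exc, no_exc)
        assert same == (1.0, 1.0)
        swapped = ab.excitation_ratio(with_exc, no_exc)
        assert swapped[0] == pytest.approx(1.0 / ratio_peak, abs=1e-12)
        assert swapped[1] == pytest.approx(1.0 / ratio_auc, abs=1e-12)

    def test_excitation_lowers_release_on_minimal_background(self, dls, scenario_runner):
        no_exc = scenario_runner(dls, 0.0, "multiphasic_no_excitation")
        with_exc = scenario_runner(dls, 0.0, "multiphasic_with_excitation")
        ratio_peak, ratio_auc = ab.excitation_ratio(no_exc, with_exc)
        assert ratio_peak > 1.0 and ratio_auc > 1.0

    def test_zero_denominator_diagnosed(self, dls, scenario_runner):
        result = scenario_runner(dls, 0.0, "tonic")
        zero = ab.SimResult(
            dao=result.dao.with_values(np.zeros(len(result.dao))),
            suppression=result.suppression,
            availability=result.availability,
            multiplier=result.multiplier,
            peak=0.0,
            auc=0.0,
            time_to_peak=0.0,
            analysis_window=result.analysis_window,
        )
        with pytest.raises(ZeroDivisionError, match="zero peak"):
            ab.excitation_ratio(result, zero)


class TestKineticsReport:
    def test_result_against_itself_is_null(self, dls, scenario_runner):
        result = scenario_runner(dls, 0.5, "tonic")
        report = ab.kinetics_report(result, result)
        assert report.time_to_peak_diff == 0.0
        assert report.max_shape_diff == 0.0

    def test_constant_suppression_is_pure_rescaling(self, dls):
        # Background suppression scales the impulse response without
        # changing its time course.
        duration = 3000.0
        da = ab.resolve_da_pattern("impulse", duration, 1.0)
        chi = tonic(5.0, duration)
        runs = [
            ab.simulate_dao(da, chi, dls, ab.SimConfig(beta=b, duration=duration))
            for b in (0.0, 0.5)
        ]
        report = ab.kinetics_report(runs[1], runs[0])
        assert report.time_to_peak_diff == 0.0
        assert report.max_shape_diff < 1e-10

    def test_time_varying_suppression_changes_shape(self, dls):
        # A pause overlapping the release tail rescales bins unevenly.
        duration = 3000.0
        da = ab.resolve_da_pattern("burst", duration, 1.0)
        reference = ab.simulate_dao(
            da, tonic(5.0, duration), dls, ab.SimConfig(beta=0.5, duration=duration)
        )
        chi = ab.resolve_chi_pattern("pause", duration, 1.0)
        paused = ab.simulate_dao(da, chi, dls, ab.SimConfig(beta=0.5, duration=duration))
        report = ab.kinetics_report(paused, reference)
        assert report.max_shape_diff > 1e-3


class TestAblation:
    def test_noop_without_supratonic_excursions(self, both_regions, scenario_runner):
        for params in both_regions.values():
            for label in ("tonic", "pause"):
                on = scenario_runner(params, 0.5, label, desensitization=True)
                off = scenario_runner(params, 0.5, label, desensitization=False)
                np.testing.assert_array_equal(on.dao.values, off.dao.values)

    def test_gain_calibration_halves_availability_at_rebound(self, both_regions):
        # The default gamma leaves availability ~0.5 at rebound onset after
        # the default excitation, by construction.
        for params in both_regions.values():
            cfg = ab.SimConfig(beta=0.0, duration=1500.0)
            chi = ab.resolve_chi_pattern("multiphasic_with_excitation", 1500.0, 1.0)
            _, a = ab.compute_suppression_trace(chi, params, cfg)
            rebound_onset = int(defaults.PATTERN_ONSET_MS + defaults.REBOUND[1])
            assert a.values[rebound_onset] == pytest.approx(
                defaults.REBOUND_AVAILABILITY_TARGET, abs=0.02
            )
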