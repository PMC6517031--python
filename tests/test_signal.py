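"""Preprocessing, QC flagging, feature extraction, kinetics and onsets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divnorm.biophys import synaptic_waveform, waveform_peak_time_ms
from divnorm.datatypes import QCFlag, SynapticKinetics, Trace
from divnorm.signal import (
    detect_onset,
    extract_features,
    fit_kinetics,
    flag_trial,
    preprocess,
    qc_cell,
)
from tests.conftest import make_trace


def doe_trace(g_bar=2.0, tau_r=2.0, tau_d=10.0, onset_delay=5.0,
              stim_onset=30.0, dt=0.05, duration=130.0, noise_sd=0.0, seed=0):
    t = np.arange(0, duration + dt / 2, dt)
    kin = SynapticKinetics(g_bar, tau_r, tau_d, stim_onset + onset_delay)
    y = synaptic_waveform(t, kin)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
    return Trace(dt_ms=dt, samples=y, units="mV", stim_onset_ms=stim_onset,
                 baseline_window_ms=(0, stim_onset),
                 interest_window_ms=(stim_onset, duration))


class TestPreprocess:
    def test_constant_trace_becomes_zero(self):
        tr = make_trace(np.full(4001, 3.7))
        out = preprocess(tr)
        assert np.allclose(out.samples, 0.0, atol=1e-9)
        assert tr.samples[0] == 3.7  # original untouched

    def test_tone_above_cutoff_attenuated(self):
        dt = 0.05
        t = np.arange(0, 200 + dt / 2, dt)
        tone = 0.5 * np.sin(2 * np.pi * 5.0 * t)  # 5 kHz, above 2 kHz cutoff
        tr = make_trace(5.0 + tone, stim_onset_ms=100.0)
        out = preprocess(tr, 2000.0)
        # >= 20 dB: residual tone amplitude below 10% of input
        assert np.std(out.samples[1000:-1000]) < 0.1 * np.std(tone)

    def test_cutoff_above_nyquist_rejected(self):
        tr = make_trace(np.zeros(1001))
        with pytest.raises(ValueError):
            preprocess(tr, 11_000.0)

    def test_degenerate_baseline_window_rejected(self):
        with pytest.raises(ValueError):
            make_trace(np.zeros(1001), baseline=(10.0, 10.0))


class TestFlagTrial:
    def test_null_calibration_flags_no_response(self):
        # identical Gaussian in both windows: response-absent flag expected
        rng = np.random.default_rng(0)
        n_flagged = 0
        trials = 400
        for _ in range(trials):
            tr = make_trace(rng.normal(0, 1, 801), dt_ms=0.05,
                            stim_onset_ms=20.0)
            if QCFlag.NOISY in flag_trial(tr, alpha=0.05).trial_flags:
                n_flagged += 1
        assert n_flagged / trials >= 0.90

    def test_clear_response_not_flagged(self):
        rng = np.random.default_rng(1)
        misses = 0
        trials = 200
        for _ in range(trials):
            y = rng.normal(0, 1, 801)
            y[400:] += 10.0  # shift by 10x noise sd
            tr = make_trace(y, dt_ms=0.05, stim_onset_ms=20.0)
            if QCFlag.NOISY in flag_trial(tr).trial_flags:
                misses += 1
        assert misses / trials <= 0.01

    def test_spike_flagged_in_current_clamp(self):
        y = np.full(801, -65.0)
        y[450] = 0.0
        tr = make_trace(y, stim_onset_ms=20.0)
        assert QCFlag.SPIKE in flag_trial(tr).trial_flags

    def test_overlapping_windows_rejected(self):
        tr = make_trace(np.zeros(801), stim_onset_ms=20.0,
                        baseline=(0.0, 25.0), interest=(20.0, 40.0))
        with pytest.raises(ValueError):
            flag_trial(tr)


class TestFeatures:
    def test_zero_trace_gives_zero_features(self):
        f = extract_features(make_trace(np.zeros(2001), stim_onset_ms=50.0))
        assert (f.peak_amp, f.auc, f.mean_v, f.auc_to_peak) == (0, 0, 0, 0)

    def test_rectangular_pulse_geometry(self):
        dt = 0.05
        y = np.zeros(4001)  # 200 ms
        # pulse amplitude 2 from 120 ms to 140 ms
        y[2400:2801] = 2.0
        tr = make_trace(y, stim_onset_ms=100.0)
        f = extract_features(tr)
        assert f.peak_amp == pytest.approx(2.0)
        assert f.auc == pytest.approx(2.0 * 20.0, rel=0.01)
        assert f.mean_v == pytest.approx(2.0 * 20.0 / 100.0, rel=0.01)
        assert f.auc_to_peak <= f.auc

    def test_waveform_peak_reported_as_g_bar(self):
        tr = doe_trace(g_bar=1.0, dt=0.01)
        f = extract_features(tr)
        assert f.peak_amp == pytest.approx(1.0, rel=1e-5)

    def test_baseline_offset_invariance(self):
        tr = doe_trace(g_bar=1.5, noise_sd=0.01)
        shifted = Trace(dt_ms=tr.dt_ms, samples=tr.samples + 12.0, units="mV",
                        stim_onset_ms=tr.stim_onset_ms,
                        baseline_window_ms=tr.baseline_window_ms,
                        interest_window_ms=tr.interest_window_ms)
        f0 = extract_features(preprocess(tr))
        f1 = extract_features(preprocess(shifted))
        assert f0.peak_amp == pytest.approx(f1.peak_amp, rel=1e-9)
        assert f0.auc == pytest.approx(f1.auc, rel=1e-6, abs=1e-9)


class TestKinetics:
    def test_noiseless_recovery_within_one_percent(self):
        tr = doe_trace(g_bar=2.0, tau_r=2.0, tau_d=10.0, onset_delay=5.0)
        fit = fit_kinetics(tr)
        assert fit.g_bar == pytest.approx(2.0, rel=0.01)
        assert fit.tau_rise_ms == pytest.approx(2.0, rel=0.01)
        assert fit.tau_decay_ms == pytest.approx(10.0, rel=0.01)
        assert fit.delta_onset_ms == pytest.approx(5.0, rel=0.01)

    def test_noiseless_fit_is_a_fixed_point(self):
        tr = doe_trace(g_bar=2.0)
        fit = fit_kinetics(tr)
        assert fit.fit_rss < 1e-12 * float(np.sum(tr.samples ** 2))

    def test_monte_carlo_recovery_under_noise(self):
        # 5% of peak Gaussian noise; parameters within 10% in >= 95% of seeds
        ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            tr = doe_trace(g_bar=2.0, noise_sd=0.1, seed=seed)
            fit = fit_kinetics(tr)
            good = (abs(fit.g_bar - 2.0) / 2.0 < 0.1
                    and abs(fit.tau_rise_ms - 2.0) / 2.0 < 0.1
                    and abs(fit.tau_decay_ms - 10.0) / 10.0 < 0.1
                    and abs(fit.delta_onset_ms - 5.0) / 5.0 < 0.1)
            ok += good
        assert ok / n_seeds >= 0.95

    def test_decay_exceeds_rise_by_construction(self):
        for seed in range(5):
            tr = doe_trace(noise_sd=0.2, seed=seed)
            fit = fit_kinetics(tr)
            assert fit.tau_decay_ms > fit.tau_rise_ms > 0

    def test_invalid_init_rejected_by_type(self):
        with pytest.raises(ValueError):
            SynapticKinetics(g_bar=1.0, tau_rise_ms=10.0, tau_decay_ms=2.0)


class TestOnset:
    def test_step_onset_found_by_all_methods(self):
        dt = 0.05
        y = np.zeros(2001)  # 100 ms
        y[600:] = 4.0  # step at 30 ms
        tr = make_trace(y, stim_onset_ms=20.0)
        for method in ("THRESHOLD", "SLOPE", "KS_WINDOW"):
            onset = detect_onset(tr, method=method)
            assert onset == pytest.approx(30.0, abs=0.6), method

    def test_methods_agree_on_smooth_waveform(self):
        tr = doe_trace(g_bar=2.0, onset_delay=8.0)
        onsets = [detect_onset(tr, method=m)
                  for m in ("THRESHOLD", "SLOPE", "KS_WINDOW")]
        assert all(o is not None for o in onsets)
        assert max(onsets) - min(onsets) <= 1.0

    def test_flat_noise_yields_no_onset(self):
        rng = np.random.default_rng(2)
        trials = 60
        for method in ("THRESHOLD", "SLOPE", "KS_WINDOW"):
            false_hits = sum(
                detect_onset(make_trace(rng.normal(0, 1, 2001),
                                        stim_onset_ms=20.0),
                             method=method) is not None
                for _ in range(trials))
            assert false_hits / trials <= 0.05, method

    def test_onset_estimates_track_generating_delay(self):
        estimates = [detect_onset(doe_trace(onset_delay=d), method="THRESHOLD")
                     for d in (2.0, 5.0, 10.0, 20.0)]
        assert estimates == sorted(estimates)


class TestCellQC:
    def test_input_resistance_change_excludes(self):
        verdict = qc_cell({"mode": "CC", "input_resistance_mohm": [100, 130],
                           "vm_mv": [-65, -65]})
        assert not verdict.passed and "RIN_CHANGE" in verdict.cell_flags

    def test_series_resistance_within_limits_passes(self):
        verdict = qc_cell({"mode": "VC",
                           "series_resistance_mohm": [15.0, 18.0]})
        assert verdict.passed

    def test_vm_drift_boundary_is_strict(self):
        verdict = qc_cell({"mode": "CC", "vm_mv": [-65.0, -62.5]})
        assert verdict.passed  # drift exactly 2.5 mV: strict > excludes

    def test_ca3_cells_get_wider_drift_limit(self):
        assert qc_cell({"mode": "CC", "vm_mv": [-65.0, -61.0],
                        "is_ca3": True}).passed
        assert not qc_cell({"mode": "CC", "vm_mv": [-65.0, -61.0]}).passed

    def test_missing_fields_yield_unknown_not_pass(self):
        verdict = qc_cell({"mode": "CC"})
        assert verdict.unknown and not verdict.passed
        verdict = qc_cell({})
        assert verdict.unknown and not verdict.passed


@given(tau_r=st.floats(0.3, 8.0), g_bar=st.floats(0.1, 50.0),
       ratio=st.floats(1.2, 12.0))
@settings(max_examples=60, deadline=None)
def test_waveform_peak_equals_g_bar_property(tau_r, g_bar, ratio):
    """The normalized waveform's maximum equals g_bar for any tau_d > tau_r."""
    tau_d = tau_r * ratio
    kin = SynapticKinetics(g_bar, tau_r, tau_d, 0.0)
    t_peak = waveform_peak_time_ms(kin)
    t = np.linspace(max(t_peak - 1, 0), t_peak + 1, 2001)
    assert np.max(synaptic_waveform(t, kin)) == pytest.approx(g_bar, rel=1e-6)
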