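"""Trace preprocessing, QC, response feature extraction and kinetics fitting.

Sign conventions: EPSCs recorded at the inhibitory reversal (-70 mV) are
inward (negative pA) and IPSCs at the excitatory reversal (0 mV) outward
(positive pA); current-clamp PSPs are depolarizing (positive mV). Feature
extraction rectifies the deflection by condition so reported peak amplitudes
are always non-negative.
"""

from __future__ import annotations

import math
from dataclasses import replace

import lmfit
import numpy as np
from scipy import signal as sps
from scipy.stats import ks_2samp

from .biophys import waveform_norm_factor
from .datatypes import Condition, PSPFeatures, QCFlag, QCVerdict, SynapticKinetics, Trace

__all__ = [
    "condition_sign",
    "preprocess",
    "flag_trial",
    "extract_features",
    "fit_kinetics",
    "detect_onset",
    "qc_cell",
]

SPIKE_THRESHOLD_MV = -20.0  # absolute membrane potential, current clamp only


def condition_sign(condition) -> float:
    """Sign that rectifies the physiological deflection to positive."""
    if condition in (Condition.VC_MINUS70, "VC_MINUS70"):
        return -1.0  # inward EPSC
    return 1.0


def preprocess(trace: Trace, filter_cutoff_hz: float = 2000.0) -> Trace:
    """Low-pass Bessel filter then subtract the baseline-window mean.

    A 4-pole Bessel filter applied forward-backward (zero phase) avoids
    biasing onset times. The input trace is left untouched.
    """
    fs = 1000.0 / trace.dt_ms
    if filter_cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {filter_cutoff_hz} Hz at/above Nyquist ({fs / 2} Hz)")
    base = trace.baseline()
    if base.size == 0:
        raise ValueError("baseline window is empty")
    sos = sps.bessel(4, filter_cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    filtered = filtered - filtered[trace.window_slice(trace.baseline_window_ms)].mean()
    return replace(trace, samples=filtered)


def flag_trial(trace: Trace, alpha: float = 0.05,
               spike_threshold_mv: float = SPIKE_THRESHOLD_MV) -> QCVerdict:
    """Flag response-absent (NOISY) and spiking (SPIKE) trials.

    NOISY: the interest-window sample distribution is statistically
    indistinguishable from baseline (two-sample KS p >= alpha) -- i.e. no
    detectable response above the noise. SPIKE: any current-clamp sample
    crosses the action-potential threshold.
    """
    b0, b1 = trace.baseline_window_ms
    i0, i1 = trace.interest_window_ms
    if max(b0, i0) < min(b1, i1):
        raise ValueError("baseline and interest windows overlap")
    base, interest = trace.baseline(), trace.interest()
    if base.size < 8 or interest.size < 8:
        raise ValueError("windows need at least 8 samples for the KS test")
    verdict = QCVerdict()
    p = ks_2samp(base, interest, method="asymp").pvalue
    if p >= alpha:
        verdict.trial_flags.add(QCFlag.NOISY)
        verdict.reasons.append(f"interest indistinguishable from baseline (KS p={p:.3g})")
    if trace.units == "mV" and np.any(trace.samples >= spike_threshold_mv):
        verdict.trial_flags.add(QCFlag.SPIKE)
        verdict.reasons.append("action potential in trace")
    verdict.passed = not verdict.trial_flags
    return verdict


def extract_features(trace: Trace, sign: float = 1.0) -> PSPFeatures:
    """Peak, AUC, window mean, and area-to-peak of the rectified deflection.

    ``sign`` rectifies the physiological deflection (use
    :func:`condition_sign`). Expects a preprocessed (baseline-subtracted)
    trace. Times are measured from stimulus onset.
    """
    y = sign * trace.samples
    sl = trace.window_slice(trace.interest_window_ms)
    win = y[sl]
    if np.all(np.isnan(win)):
        raise ValueError("interest window is all-NaN")
    t = trace.time_ms()[sl]
    ipk = int(np.argmax(win))
    peak = float(win[ipk])
    peak_time = float(t[ipk] - trace.stim_onset_ms)
    auc = float(np.trapezoid(win, t))
    window_len = t[-1] - t[0]
    mean_v = auc / window_len if window_len > 0 else 0.0
    auc_to_peak = float(np.trapezoid(win[: ipk + 1], t[: ipk + 1]))
    onset = detect_onset(trace, method="THRESHOLD", sign=sign)
    return PSPFeatures(peak_amp=peak, peak_time_ms=peak_time, auc=auc,
                       mean_v=mean_v, auc_to_peak=auc_to_peak,
                       onset_time_ms=math.nan if onset is None
                       else onset - trace.stim_onset_ms)


def _doe_model(t, g_bar, tau_rise, tau_decay, delta_onset):
    tt = np.maximum(t - delta_onset, 0.0)
    norm = waveform_norm_factor(tau_rise, tau_decay)
    return g_bar * (np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise)) / norm


def fit_kinetics(trace: Trace, init: SynapticKinetics = None, sign: float = 1.0,
                 max_restarts: int = 4) -> SynapticKinetics:
    """Fit the normalized difference-of-exponentials to a rectified PSC/PSP.

    The decay constant is parameterized as tau_rise + dtau (dtau > 0) so the
    tau_decay > tau_rise invariant survives optimization. Non-convergence
    after bounded random restarts returns a result with ``converged=False``
    rather than failing silently.
    """
    sl = trace.window_slice(trace.interest_window_ms)
    t = trace.time_ms()[sl] - trace.stim_onset_ms
    y = sign * trace.samples[sl]

    if init is None:
        ipk = int(np.argmax(y))
        init = SynapticKinetics(g_bar=max(float(y[ipk]), 1e-6),
                                tau_rise_ms=2.0, tau_decay_ms=10.0,
                                delta_onset_ms=max(float(t[ipk]) / 3.0, 0.1))

    def residual(params):
        p = params.valuesdict()
        return _doe_model(t, p["g_bar"], p["tau_rise"],
                          p["tau_rise"] + p["dtau"], p["delta_onset"]) - y

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        params = lmfit.Parameters()
        jitter = 1.0 if attempt == 0 else float(rng.uniform(0.5, 2.0))
        params.add("g_bar", value=init.g_bar * jitter, min=0.0)
        params.add("tau_rise", value=init.tau_rise_ms * jitter, min=1e-3)
        params.add("dtau", value=(init.tau_decay_ms - init.tau_rise_ms) * jitter,
                   min=1e-3)
        params.add("delta_onset", value=min(init.delta_onset_ms * jitter, t[-1] / 2),
                   min=0.0, max=float(t[-1]))
        res = lmfit.minimize(residual, params, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and res.chisqr <= 1e-3 * float(np.sum(y ** 2) + 1e-30):
            break
    p = best.params.valuesdict()
    return SynapticKinetics(g_bar=p["g_bar"], tau_rise_ms=p["tau_rise"],
                            tau_decay_ms=p["tau_rise"] + p["dtau"],
                            delta_onset_ms=p["delta_onset"],
                            fit_rss=float(best.chisqr),
                            converged=bool(best.success))


# noise gate for onset detection: a pure-noise interest window of ~2000
# samples has max excursion ~3.5-4 sd, so a 3-sd floor would fire on noise;
# 5 sd keeps the false-onset rate well below 5%
ONSET_NOISE_GATE_SD = 5.0


def detect_onset(trace: Trace, method: str = "THRESHOLD", sign: float = 1.0,
                 threshold: float = None, alpha: float = 0.05,
                 window_ms: float = 0.5):
    """Response onset time (ms, on the trace's own axis), or None.

    THRESHOLD: first crossing of an absolute threshold (default 10% of the
    interest-window extremum with a floor of 5x the baseline sd).
    SLOPE: steepest rise between interest start and the peak (gated on the
    peak clearing the noise floor).
    KS_WINDOW: earliest boundary between consecutive ``window_ms`` windows
    whose sample distributions differ by two-sample KS; ``alpha`` is
    Bonferroni-corrected over the scanned window pairs.
    """
    y = sign * trace.samples
    sl = trace.window_slice(trace.interest_window_ms)
    win = y[sl]
    t = trace.time_ms()[sl]
    base_sd = float(np.std(y[trace.window_slice(trace.baseline_window_ms)]))

    if method == "THRESHOLD":
        if threshold is None:
            threshold = max(0.1 * float(np.max(win)),
                            ONSET_NOISE_GATE_SD * base_sd)
        above = np.nonzero(win >= threshold)[0]
        if above.size == 0 or np.max(win) <= 0:
            return None
        return float(t[above[0]])
    if method == "SLOPE":
        ipk = int(np.argmax(win))
        if ipk < 2 or win[ipk] <= ONSET_NOISE_GATE_SD * base_sd:
            return None
        dv = np.diff(win[: ipk + 1])
        return float(t[int(np.argmax(dv))])
    if method == "KS_WINDOW":
        n = max(int(round(window_ms / trace.dt_ms)), 4)
        n_pairs = max((win.size - n) // n, 1)
        alpha_corr = alpha / n_pairs
        for start in range(0, win.size - 2 * n, n):
            a, b = win[start: start + n], win[start + n: start + 2 * n]
            if ks_2samp(a, b, method="exact").pvalue < alpha_corr:
                return float(t[start + n])
        return None
    raise ValueError(f"unknown onset method {method!r}")


# cell-level exclusion rules; comparisons are strict (> excludes)
RIN_CHANGE_FRAC = 0.25
VM_DRIFT_MV_CA1 = 2.5
VM_DRIFT_MV_CA3 = 5.0
RS_MAX_MOHM = 25.0
RS_CHANGE_FRAC = 0.30


def qc_cell(cell_metadata: dict) -> QCVerdict:
    """Apply the cell-level exclusion rules to a metadata record.

    Expected keys (each a sequence over the recording, first value = initial):
    ``input_resistance_mohm``; ``vm_mv`` with ``mode`` in {'CC','VC'};
    ``series_resistance_mohm`` (VC); optional ``is_ca3`` bool. Missing fields
    yield an explicit 'unknown' verdict, never a silent pass.
    """
    verdict = QCVerdict()
    mode = cell_metadata.get("mode")
    if mode not in ("CC", "VC"):
        verdict.unknown = True
        verdict.passed = False
        verdict.reasons.append("missing or unknown recording mode")
        return verdict

    rin = cell_metadata.get("input_resistance_mohm")
    if rin is not None and len(rin) >= 2:
        change = abs(rin[-1] - rin[0]) / abs(rin[0])
        if change > RIN_CHANGE_FRAC:
            verdict.cell_flags.add("RIN_CHANGE")
            verdict.reasons.append(f"input resistance changed {change:.0%}")

    if mode == "CC":
        vm = cell_metadata.get("vm_mv")
        if vm is None:
            verdict.unknown = True
            verdict.reasons.append("missing Vm series")
        else:
            limit = VM_DRIFT_MV_CA3 if cell_metadata.get("is_ca3") else VM_DRIFT_MV_CA1
            drift = abs(vm[-1] - vm[0])
            if drift > limit:
                verdict.cell_flags.add("VM_DRIFT")
                verdict.reasons.append(f"Vm drifted {drift:.2f} mV (> {limit})")
    else:
        rs = cell_metadata.get("series_resistance_mohm")
        if rs is None:
            verdict.unknown = True
            verdict.reasons.append("missing series resistance series")
        else:
            if max(rs) > RS_MAX_MOHM:
                verdict.cell_flags.add("RS_HIGH")
                verdict.reasons.append(f"series resistance reached {max(rs):.1f} MOhm")
            change = abs(rs[-1] - rs[0]) / abs(rs[0])
            if change > RS_CHANGE_FRAC:
                verdict.cell_flags.add("RS_CHANGE")
                verdict.reasons.append(f"series resistance changed {change:.0%}")

    verdict.passed = not verdict.cell_flags and not verdict.unknown
    return verdict
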