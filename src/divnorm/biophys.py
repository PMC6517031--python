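"""Single-compartment conductance model with difference-of-exponentials synapses.

The membrane obeys

    Cm dVm/dt = -[ g_leak (Vm - E_leak) + g_exc(t) (Vm - E_exc)
                   + g_inh(t) (Vm - E_inh) ]

with synaptic conductances shaped as normalized differences of exponentials
whose peak equals the requested amplitude exactly. Feedforward inhibition
follows excitation after an onset lag that either stays constant (STATIC) or
shrinks exponentially with the excitatory drive (DYNAMIC):

    delta_inh(g_exc) = delta_min + m * exp(-k * g_exc)

The integrator is classic fixed-step RK4, vectorized over batches of drives so
that whole sweeps (and whole permutation ensembles) integrate in one pass.
A Hodgkin-Huxley variant adds Na and delayed-rectifier K channels for spiking.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ConductanceParams,
    DelayModel,
    EOPair,
    SimResult,
    SynapticDrive,
    SynapticKinetics,
    Trace,
)

__all__ = [
    "delay_of",
    "waveform_norm_factor",
    "waveform_peak_time_ms",
    "synaptic_waveform",
    "simulate_psp",
    "simulate_batch",
    "run_sdn_sweep",
    "shuffle_controls",
    "gamma_phase_map",
    "HHChannels",
    "simulate_hh",
    "extract_ei_delay",
]

VM_INSTABILITY_MV = 200.0


# ---------------------------------------------------------------------------
# delay law and synaptic waveform
# ---------------------------------------------------------------------------

def delay_of(g_exc, dm: DelayModel):
    """Inhibitory onset lag (ms) for excitatory drive ``g_exc`` (nS).

    DYNAMIC: delta_min + m * exp(-k * g_exc); STATIC: the configured constant.
    Accepts scalars or arrays.
    """
    g = np.asarray(g_exc, dtype=float)
    if np.any(g < 0):
        raise ValueError("g_exc must be non-negative")
    if dm.mode == "static":
        out = np.full_like(g, dm.static_delay_ms)
    else:
        out = dm.delta_min_ms + dm.m_ms * np.exp(-dm.k_per_ns * g)
    return float(out) if np.isscalar(g_exc) else out


def waveform_norm_factor(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Peak value of exp(-t/tau_d) - exp(-t/tau_r), used to normalize to 1.

    The unnormalized difference peaks at
    t* = tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r), where it equals
    r^(tau_r/(tau_d-tau_r)) - r^(tau_d/(tau_d-tau_r)) with r = tau_r/tau_d.
    """
    if not tau_decay_ms > tau_rise_ms > 0:
        raise ValueError("requires tau_decay > tau_rise > 0")
    r = tau_rise_ms / tau_decay_ms
    span = tau_decay_ms - tau_rise_ms
    return r ** (tau_rise_ms / span) - r ** (tau_decay_ms / span)


def waveform_peak_time_ms(kin: SynapticKinetics) -> float:
    """Time (ms, from trace start) at which the waveform attains g_bar."""
    tr, td = kin.tau_rise_ms, kin.tau_decay_ms
    return kin.delta_onset_ms + tr * td / (td - tr) * np.log(td / tr)


def synaptic_waveform(t, kin: SynapticKinetics):
    """Conductance (nS) at time(s) ``t`` (ms); zero before onset, peak = g_bar."""
    tt = np.maximum(np.asarray(t, dtype=float) - kin.delta_onset_ms, 0.0)
    norm = waveform_norm_factor(kin.tau_rise_ms, kin.tau_decay_ms)
    out = kin.g_bar * (np.exp(-tt / kin.tau_decay_ms) - np.exp(-tt / kin.tau_rise_ms)) / norm
    return float(out) if np.isscalar(t) else out


def _batch_conductance(t, g_bar, tau_r, tau_d, onset, norm):
    """Vectorized waveform for per-unit amplitude/onset arrays at scalar t."""
    tt = np.maximum(t - onset, 0.0)
    return g_bar * (np.exp(-tt / tau_d) - np.exp(-tt / tau_r)) / norm


# ---------------------------------------------------------------------------
# passive integrator
# ---------------------------------------------------------------------------

def simulate_batch(
    params: ConductanceParams,
    g_exc_bar,
    g_inh_bar,
    inh_delay_ms,
    exc_kin: SynapticKinetics,
    inh_kin: SynapticKinetics,
    stim_onset_ms: float = 20.0,
    record: bool = False,
):
    """Integrate the passive membrane for a batch of (g_exc, g_inh, delay).

    All three drive arguments broadcast to a common shape; one RK4 pass
    integrates every unit simultaneously. Returns (v_max, v_max_time, traces)
    where v_max is depolarization above rest (mV) and ``traces`` is the
    (n_steps+1, n_units) voltage array when ``record`` else None.
    """
    ge, gi, dly = np.broadcast_arrays(
        np.asarray(g_exc_bar, float), np.asarray(g_inh_bar, float),
        np.asarray(inh_delay_ms, float))
    shape = ge.shape
    ge, gi, dly = ge.ravel(), gi.ravel(), dly.ravel()

    norm_e = waveform_norm_factor(exc_kin.tau_rise_ms, exc_kin.tau_decay_ms)
    norm_i = waveform_norm_factor(inh_kin.tau_rise_ms, inh_kin.tau_decay_ms)
    onset_e = stim_onset_ms + exc_kin.delta_onset_ms
    onset_i = stim_onset_ms + inh_kin.delta_onset_ms + dly

    dt = params.dt_ms
    n_steps = int(round(params.duration_ms / dt))
    cm, gl, el = params.cm_pf, params.g_leak_ns, params.e_leak_mv
    ee, ei = params.e_exc_mv, params.e_inh_mv
    tre, tde = exc_kin.tau_rise_ms, exc_kin.tau_decay_ms
    tri, tdi = inh_kin.tau_rise_ms, inh_kin.tau_decay_ms

    def dvdt(v, t):
        gexc = _batch_conductance(t, ge, tre, tde, onset_e, norm_e)
        ginh = _batch_conductance(t, gi, tri, tdi, onset_i, norm_i)
        return -(gl * (v - el) + gexc * (v - ee) + ginh * (v - ei)) / cm

    v = np.full(ge.shape, el)
    v_max = np.zeros_like(v)
    v_max_t = np.zeros_like(v)
    traces = np.empty((n_steps + 1, v.size)) if record else None
    if record:
        traces[0] = v
    for step in range(n_steps):
        t = step * dt
        k1 = dvdt(v, t)
        k2 = dvdt(v + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = dvdt(v + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = dvdt(v + dt * k3, t + dt)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if record:
            traces[step + 1] = v
        depol = v - el
        newmax = depol > v_max
        v_max_t = np.where(newmax, t + dt, v_max_t)
        v_max = np.where(newmax, depol, v_max)
    if np.any(np.abs(v) > VM_INSTABILITY_MV) or not np.all(np.isfinite(v)):
        raise FloatingPointError("membrane potential diverged; reduce dt")
    return v_max.reshape(shape), v_max_t.reshape(shape), traces


def steady_state_voltage(params: ConductanceParams, g_exc_ns: float,
                         g_inh_ns: float = 0.0) -> float:
    """Fixed point of the membrane under constant conductances (mV)."""
    num = (params.g_leak_ns * params.e_leak_mv + g_exc_ns * params.e_exc_mv
           + g_inh_ns * params.e_inh_mv)
    return num / (params.g_leak_ns + g_exc_ns + g_inh_ns)


def simulate_constant_conductance(params: ConductanceParams, g_exc_ns: float,
                                  g_inh_ns: float = 0.0, v0_mv: float = None):
    """RK4 integration with time-invariant conductances.

    Returns (time_ms, v_mv). The closed form is exponential relaxation to
    :func:`steady_state_voltage` with tau = Cm / g_total, which makes this the
    segment-wise oracle for piecewise-constant drives.
    """
    dt = params.dt_ms
    n_steps = int(round(params.duration_ms / dt))
    cm, gl, el = params.cm_pf, params.g_leak_ns, params.e_leak_mv
    ee, ei = params.e_exc_mv, params.e_inh_mv
    v = params.e_leak_mv if v0_mv is None else v0_mv
    out = np.empty(n_steps + 1)
    out[0] = v

    def f(vv):
        return -(gl * (vv - el) + g_exc_ns * (vv - ee)
                 + g_inh_ns * (vv - ei)) / cm

    for step in range(n_steps):
        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[step + 1] = v
    return np.arange(n_steps + 1) * dt, out


def simulate_psp(
    params: ConductanceParams,
    drive: SynapticDrive,
    stim_onset_ms: float = 20.0,
) -> SimResult:
    """Integrate one excitatory/inhibitory drive; return trace and peak."""
    if stim_onset_ms >= params.duration_ms:
        raise ValueError("stimulus onset outside simulation window")
    g_exc = drive.exc.g_bar
    if drive.inh is not None:
        g_inh = drive.inh.g_bar
        inh_kin = drive.inh
    elif drive.ie_ratio > 0:
        g_inh = drive.ie_ratio * g_exc
        inh_kin = SynapticKinetics(g_bar=1.0, tau_rise_ms=2.0, tau_decay_ms=15.0)
    else:
        g_inh = 0.0
        inh_kin = SynapticKinetics(g_bar=0.0, tau_rise_ms=2.0, tau_decay_ms=15.0)
    dly = delay_of(g_exc, drive.delay)
    v_max, v_max_t, traces = simulate_batch(
        params, [g_exc], [g_inh], [dly], drive.exc, inh_kin,
        stim_onset_ms=stim_onset_ms, record=True)
    trace = Trace(
        dt_ms=params.dt_ms, samples=traces[:, 0], units="mV",
        stim_onset_ms=stim_onset_ms,
        baseline_window_ms=(0.0, stim_onset_ms),
        interest_window_ms=(stim_onset_ms,
                            min(params.duration_ms, stim_onset_ms + 100.0)))
    return SimResult(trace=trace, v_max=float(v_max[0]), v_max_time_ms=float(v_max_t[0]))


# ---------------------------------------------------------------------------
# sweeps, shuffles, phase maps
# ---------------------------------------------------------------------------

def _default_kinetics():
    exc = SynapticKinetics(g_bar=1.0, tau_rise_ms=2.0, tau_decay_ms=10.0)
    inh = SynapticKinetics(g_bar=1.0, tau_rise_ms=2.0, tau_decay_ms=15.0)
    return exc, inh


def run_sdn_sweep(
    params: ConductanceParams,
    ie_ratio: float,
    dm: DelayModel,
    g_exc_grid,
    exc_kin: SynapticKinetics = None,
    inh_kin: SynapticKinetics = None,
    stim_onset_ms: float = 20.0,
):
    """Observed-vs-expected PSP peaks across an excitatory conductance sweep.

    expected: peak depolarization with excitation alone;
    observed: peak with balanced inhibition (g_inh = ie_ratio * g_exc) arriving
    at the delay the law assigns to that g_exc.
    """
    grid = np.asarray(g_exc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("g_exc_grid must be non-empty")
    dflt = _default_kinetics()
    exc_kin = exc_kin or dflt[0]
    inh_kin = inh_kin or dflt[1]
    delays = delay_of(grid, dm)
    exp_v, _, _ = simulate_batch(params, grid, np.zeros_like(grid),
                                 np.zeros_like(grid), exc_kin, inh_kin,
                                 stim_onset_ms)
    obs_v, _, _ = simulate_batch(params, grid, ie_ratio * grid, delays,
                                 exc_kin, inh_kin, stim_onset_ms)
    return [EOPair(expected=float(e), observed=float(o))
            for e, o in zip(exp_v, obs_v)]


def shuffle_controls(
    params: ConductanceParams,
    ie_ratio: float,
    dm: DelayModel,
    g_exc_grid,
    mode: str,
    seed: int = 0,
    n_permutations: int = 1,
    exc_kin: SynapticKinetics = None,
    inh_kin: SynapticKinetics = None,
    stim_onset_ms: float = 20.0,
    permutations=None,
):
    """Break per-stimulus EI pairing (SHUFFLE_I) or delay ordering (SHUFFLE_DELAY).

    Returns a list of EOPair lists, one per permutation. All permutations
    integrate in a single batched pass.
    """
    grid = np.asarray(g_exc_grid, dtype=float)
    if grid.size < 5:
        raise ValueError("sweep grid too short to shuffle meaningfully")
    if mode not in ("SHUFFLE_I", "SHUFFLE_DELAY"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    dflt = _default_kinetics()
    exc_kin = exc_kin or dflt[0]
    inh_kin = inh_kin or dflt[1]

    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(grid.size) for _ in range(n_permutations)]
    perms = np.asarray(permutations)

    delays = delay_of(grid, dm)
    ginh = ie_ratio * grid
    if mode == "SHUFFLE_I":
        ginh_mat = ginh[perms]                      # (P, n)
        delay_mat = np.broadcast_to(delays, ginh_mat.shape)
    else:
        delay_mat = delays[perms]
        ginh_mat = np.broadcast_to(ginh, delay_mat.shape)
    gexc_mat = np.broadcast_to(grid, ginh_mat.shape)

    exp_v, _, _ = simulate_batch(params, grid, np.zeros_like(grid),
                                 np.zeros_like(grid), exc_kin, inh_kin,
                                 stim_onset_ms)
    obs_v, _, _ = simulate_batch(params, gexc_mat, ginh_mat, delay_mat,
                                 exc_kin, inh_kin, stim_onset_ms)
    out = []
    for p in range(obs_v.shape[0]):
        out.append([EOPair(expected=float(e), observed=float(o))
                    for e, o in zip(exp_v, obs_v[p])])
    return out


GAMMA_NO_NORMALIZATION = 40.0


def gamma_phase_map(
    params: ConductanceParams,
    ie_grid,
    k_grid,
    g_exc_grid,
    delta_min_ms: float = 2.0,
    m_ms: float = 8.15,
    exc_kin: SynapticKinetics = None,
    inh_kin: SynapticKinetics = None,
):
    """Fitted normalization parameter gamma over (I/E ratio, delay steepness k).

    Cells whose gamma exceeds GAMMA_NO_NORMALIZATION are effectively linear
    ("no normalization"). Returns (gamma_matrix, no_norm_mask) with rows
    indexed by ie_grid and columns by k_grid.
    """
    from .gainfit import GainModelRegressor

    ie_grid = np.asarray(ie_grid, float)
    k_grid = np.asarray(k_grid, float)
    if ie_grid.size == 0 or k_grid.size == 0:
        raise ValueError("grids must be non-empty")
    gamma = np.full((ie_grid.size, k_grid.size), np.nan)
    for i, ie in enumerate(ie_grid):
        for j, k in enumerate(k_grid):
            dm = DelayModel(delta_min_ms=delta_min_ms, k_per_ns=k, m_ms=m_ms,
                            mode="dynamic")
            pairs = run_sdn_sweep(params, ie, dm, g_exc_grid,
                                  exc_kin=exc_kin, inh_kin=inh_kin)
            try:
                fit = GainModelRegressor(model="DN").fit(
                    [p.expected for p in pairs], [p.observed for p in pairs])
                gamma[i, j] = fit.gamma_
            except (ValueError, RuntimeError):
                pass  # non-converged fit recorded as missing
    return gamma, gamma > GAMMA_NO_NORMALIZATION


# ---------------------------------------------------------------------------
# Hodgkin-Huxley variant
# ---------------------------------------------------------------------------

class HHChannels:
    """Na + delayed-rectifier K channel config (classic kinetics, -65 mV rest).

    Densities are totals for the whole compartment (nS). The spike threshold
    used for latency readout is a first-class parameter because the mapping
    from subthreshold summation to spike timing is sensitive to it.
    """

    def __init__(self, g_na_ns=6000.0, g_k_ns=1800.0, e_na_mv=50.0,
                 e_k_mv=-77.0, gate_shift_mv=15.0, spike_threshold_mv=0.0,
                 refractory_ms=2.0):
        self.g_na_ns = g_na_ns
        self.g_k_ns = g_k_ns
        self.e_na_mv = e_na_mv
        self.e_k_mv = e_k_mv
        # depolarizing shift of all gate kinetics: keeps the channels closed
        # at the passive resting potential so the subthreshold response
        # matches the passive model, and puts spike threshold near -40 mV
        self.gate_shift_mv = gate_shift_mv
        self.spike_threshold_mv = spike_threshold_mv
        self.refractory_ms = refractory_ms


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, float)
    small = np.abs(x / y) < 1e-6
    return np.where(small, y * (1 - x / y / 2.0), x / np.expm1(np.where(small, 1.0, x / y)))


def _hh_rates(v, shift=0.0):
    v = v - shift
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def simulate_hh(
    params: ConductanceParams,
    drive: SynapticDrive,
    channels: HHChannels = None,
    stim_onset_ms: float = 20.0,
    g_inh_bar: float = None,
):
    """Spiking single-compartment model with the same synaptic drive.

    Spike times are upward crossings of the spike threshold, deduplicated with
    a refractory window.
    """
    ch = channels or HHChannels()
    g_exc = drive.exc.g_bar
    if g_inh_bar is None:
        g_inh_bar = drive.inh.g_bar if drive.inh is not None else drive.ie_ratio * g_exc
    inh_kin = drive.inh or SynapticKinetics(g_bar=max(g_inh_bar, 0.0),
                                            tau_rise_ms=2.0, tau_decay_ms=15.0)
    dly = delay_of(g_exc, drive.delay)
    norm_e = waveform_norm_factor(drive.exc.tau_rise_ms, drive.exc.tau_decay_ms)
    norm_i = waveform_norm_factor(inh_kin.tau_rise_ms, inh_kin.tau_decay_ms)
    onset_e = stim_onset_ms + drive.exc.delta_onset_ms
    onset_i = stim_onset_ms + inh_kin.delta_onset_ms + dly

    dt = params.dt_ms
    n_steps = int(round(params.duration_ms / dt))
    cm, gl, el = params.cm_pf, params.g_leak_ns, params.e_leak_mv
    ee, ei = params.e_exc_mv, params.e_inh_mv

    def deriv(state, t):
        v, m, h, n = state
        gexc = _batch_conductance(t, g_exc, drive.exc.tau_rise_ms,
                                  drive.exc.tau_decay_ms, onset_e, norm_e)
        ginh = _batch_conductance(t, g_inh_bar, inh_kin.tau_rise_ms,
                                  inh_kin.tau_decay_ms, onset_i, norm_i)
        i_na = ch.g_na_ns * m ** 3 * h * (v - ch.e_na_mv)
        i_k = ch.g_k_ns * n ** 4 * (v - ch.e_k_mv)
        dv = -(gl * (v - el) + gexc * (v - ee) + ginh * (v - ei) + i_na + i_k) / cm
        am, bm, ah, bh, an, bn = _hh_rates(v, ch.gate_shift_mv)
        return np.array([dv, am * (1 - m) - (am + bm) * m,
                         ah * (1 - h) - (ah + bh) * h,
                         an * (1 - n) - (an + bn) * n])

    am, bm, ah, bh, an, bn = _hh_rates(el, ch.gate_shift_mv)
    state = np.array([el, am / (am + bm), ah / (ah + bh), an / (an + bn)])
    trace = np.empty(n_steps + 1)
    trace[0] = el
    spikes = []
    last_spike = -np.inf
    v_max, v_max_t = 0.0, 0.0
    for step in range(n_steps):
        t = step * dt
        k1 = deriv(state, t)
        k2 = deriv(state + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = deriv(state + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = deriv(state + dt * k3, t + dt)
        new = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (state[0] < ch.spike_threshold_mv <= new[0]
                and t + dt - last_spike > ch.refractory_ms):
            spikes.append(t + dt)
            last_spike = t + dt
        state = new
        trace[step + 1] = state[0]
        if state[0] - el > v_max:
            v_max, v_max_t = state[0] - el, t + dt
    if not np.all(np.isfinite(trace)) or np.max(np.abs(trace)) > VM_INSTABILITY_MV:
        raise FloatingPointError("HH integration diverged; reduce dt")
    tr = Trace(dt_ms=dt, samples=trace, units="mV", stim_onset_ms=stim_onset_ms,
               baseline_window_ms=(0.0, stim_onset_ms),
               interest_window_ms=(stim_onset_ms,
                                   min(params.duration_ms, stim_onset_ms + 100.0)))
    return SimResult(trace=tr, v_max=float(v_max), v_max_time_ms=float(v_max_t),
                     spike_times_ms=spikes)


def amplitude_time_dataset(
    params: ConductanceParams,
    ie_ratio: float,
    dm: DelayModel,
    n_trials: int = 500,
    seed: int = 0,
    g_exc_range_ns=(0.5, 15.0),
    ginh_jitter: float = 0.1,
    amp_noise_mv: float = 0.1,
    time_noise_ms: float = 0.5,
    stim_onset_ms: float = 20.0,
    exc_kin: SynapticKinetics = None,
    inh_kin: SynapticKinetics = None,
):
    """Per-trial (input, peak amplitude, peak time) table for the MI analysis.

    Each trial draws an excitatory drive uniformly over ``g_exc_range_ns`` and
    is simulated twice: with balanced inhibition at the law's delay
    (condition 'CC_CONTROL') and with excitation alone ('CC_GABAZINE').
    The input proxy ('expected') is the excitation-only peak, the analogue of
    the linear sum of single-square responses. Trial-to-trial variability
    comes from multiplicative jitter on the inhibitory conductance plus
    additive measurement noise on the readouts.

    Returns a DataFrame with columns condition, expected, peak_amp, peak_time.
    """
    import pandas as pd

    dflt = _default_kinetics()
    exc_kin = exc_kin or dflt[0]
    inh_kin = inh_kin or dflt[1]
    rng = np.random.default_rng(seed)
    ge = rng.uniform(*g_exc_range_ns, size=n_trials)
    gi = ie_ratio * ge * rng.normal(1.0, ginh_jitter, size=n_trials).clip(0.0)
    delays = delay_of(ge, dm)
    exp_v, exp_t, _ = simulate_batch(params, ge, np.zeros_like(ge),
                                     np.zeros_like(ge), exc_kin, inh_kin,
                                     stim_onset_ms)
    obs_v, obs_t, _ = simulate_batch(params, ge, gi, delays, exc_kin, inh_kin,
                                     stim_onset_ms)
    rows = []
    for cond, v, t in (("CC_CONTROL", obs_v, obs_t),
                       ("CC_GABAZINE", exp_v, exp_t)):
        amp = v + rng.normal(0.0, amp_noise_mv, size=n_trials)
        tpk = (t - stim_onset_ms) + rng.normal(0.0, time_noise_ms, size=n_trials)
        rows.append(pd.DataFrame({"condition": cond, "expected": exp_v,
                                  "peak_amp": amp, "peak_time": tpk}))
    return pd.concat(rows, ignore_index=True)


def extract_ei_delay(exc_kin: SynapticKinetics, inh_kin: SynapticKinetics) -> float:
    """EI onset lag: inhibitory minus excitatory fitted onset delay (ms)."""
    return inh_kin.delta_onset_ms - exc_kin.delta_onset_ms
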