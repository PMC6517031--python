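"""Synthetic grid-photostimulation experiments with known ground truth.

The generator emulates the experimental design this package's analyses
assume: a grid of 16 um stimulus squares over the presynaptic field, stimulus
patterns of N in {1,2,3,5,7,9} squares with a few repeats each, voltage-clamp
recordings at -70 mV (isolated EPSC) and 0 mV (isolated IPSC), and
current-clamp PSPs with inhibition intact or blocked.

Generative model
----------------
* Per-square synaptic weights are i.i.d. lognormal (underlying-normal
  mu = -0.39, sigma = 0.80 by default). Inhibitory weights are the excitatory
  weights shuffled within bins whose size is set by the tuning parameter rho
  (rho = 1: perfectly paired, detailed balance; rho = 0: fully shuffled,
  global balance). The E and I vectors therefore always share one multiset of
  values.
* Each square carries a Poisson (mean 5) number of engaged synapses, drawn
  once per network so that multi-square stimuli are exact unions of their
  single squares (the engaged count is identical for E and I of a square).
* Per trial, each engaged synapse releases independently (binomial, p = 0.2
  excitatory / 0.8 inhibitory); released weights sum into peak conductances.
* Conductances drive difference-of-exponential waveforms (voltage clamp) or
  the passive membrane ODE (current clamp); inhibition lags excitation by the
  input-dependent delay law. Additive Gaussian noise models recording noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .biophys import delay_of, simulate_batch, synaptic_waveform
from .datatypes import (
    Condition,
    ConductanceParams,
    DelayModel,
    GridSpec,
    GroundTruth,
    StimPattern,
    SynapticKinetics,
    Trace,
    TrialRecord,
)

__all__ = [
    "DEFAULT_WEIGHT_MU",
    "DEFAULT_WEIGHT_SIGMA",
    "ExperimentConfig",
    "shuffle_within_bins",
    "generate_network",
    "generate_trial",
    "generate_experiment",
]

DEFAULT_WEIGHT_MU = -0.39
DEFAULT_WEIGHT_SIGMA = 0.80
RELEASE_P_EXC = 0.2
RELEASE_P_INH = 0.8
MEAN_SYNAPSES_PER_SQUARE = 5.0
VC_HOLD = {Condition.VC_MINUS70: -70.0, Condition.VC_0: 0.0}


def shuffle_within_bins(values: np.ndarray, rho: float, rng) -> np.ndarray:
    """Shuffle a vector within contiguous bins of size round((1-rho)*L).

    rho = 1 gives bin size 1 (no reordering); rho = 0 gives one bin spanning
    the whole vector (full shuffle). The multiset of values is conserved for
    every rho.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    out = np.array(values, dtype=float, copy=True)
    L = out.size
    bin_size = max(1, round((1.0 - rho) * L))
    if bin_size == 1:
        return out
    for start in range(0, L, bin_size):
        seg = out[start: start + bin_size]
        out[start: start + bin_size] = rng.permutation(seg)
    return out


def generate_network(
    grid: GridSpec,
    weight_mu: float = DEFAULT_WEIGHT_MU,
    weight_sigma: float = DEFAULT_WEIGHT_SIGMA,
    rho: float = 1.0,
    seed: int = 0,
    conductance_per_weight_ns: float = 0.4,
    ie_conductance_ratio: float = 0.75,
    release_p_exc: float = RELEASE_P_EXC,
    release_p_inh: float = RELEASE_P_INH,
    mean_synapses: float = MEAN_SYNAPSES_PER_SQUARE,
    exc_kinetics: SynapticKinetics = None,
    inh_kinetics: SynapticKinetics = None,
    delay_model: DelayModel = None,
) -> GroundTruth:
    """Draw a ground-truth synaptic network for one simulated cell."""
    if weight_sigma < 0:
        raise ValueError("weight_sigma must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA11CE)))
    L = grid.n_squares
    if weight_sigma == 0:
        exc = np.full(L, np.exp(weight_mu))
    else:
        exc = rng.lognormal(mean=weight_mu, sigma=weight_sigma, size=L)
    inh = shuffle_within_bins(exc, rho, rng)
    engaged = rng.poisson(mean_synapses, size=L)
    return GroundTruth(
        grid=grid, exc_weights=exc, inh_weights=inh, engaged_counts=engaged,
        rho=rho, weight_mu=weight_mu, weight_sigma=weight_sigma,
        exc_kinetics=exc_kinetics or SynapticKinetics(1.0, 2.0, 10.0),
        inh_kinetics=inh_kinetics or SynapticKinetics(1.0, 2.0, 15.0),
        delay_model=delay_model or DelayModel(delta_min_ms=2.0, k_per_ns=0.5,
                                              m_ms=8.15, mode="dynamic"),
        conductance_per_weight_ns=conductance_per_weight_ns,
        ie_conductance_ratio=ie_conductance_ratio,
        release_p_exc=release_p_exc, release_p_inh=release_p_inh,
        seed=int(seed))


def _trial_seed(master_seed: int, pattern_id: str, condition: str, repeat: int):
    """Counter-based per-trial seed: independent yet reproducible trials."""
    key = zlib.crc32(f"{pattern_id}|{condition}|{repeat}".encode())
    return np.random.SeedSequence((int(master_seed), key))


def _trial_conductances(truth: GroundTruth, pattern: StimPattern, rng,
                        release_override: float = None):
    """Released-weight sums -> (g_exc_bar, g_inh_bar) in nS for one trial."""
    idx = np.asarray(pattern.squares, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= truth.grid.n_squares):
        raise ValueError("pattern square outside the network's grid")
    n = truth.engaged_counts[idx] if idx.size else np.zeros(0, dtype=int)
    p_e = truth.release_p_exc if release_override is None else release_override
    p_i = truth.release_p_inh if release_override is None else release_override
    rel_e = rng.binomial(n, p_e) if idx.size else np.zeros(0, dtype=int)
    rel_i = rng.binomial(n, p_i) if idx.size else np.zeros(0, dtype=int)
    kappa = truth.conductance_per_weight_ns
    g_exc = kappa * float(np.sum(truth.exc_weights[idx] * rel_e))
    g_inh = kappa * truth.ie_conductance_ratio * float(
        np.sum(truth.inh_weights[idx] * rel_i))
    return g_exc, g_inh


def _default_noise(condition: Condition) -> float:
    return 2.0 if condition.units == "pA" else 0.05


def generate_trial(
    truth: GroundTruth,
    pattern: StimPattern,
    condition,
    repeat: int = 1,
    noise_sd: float = None,
    seed: int = None,
    stim_onset_ms: float = 100.0,
    duration_ms: float = 200.0,
    dt_ms: float = 0.05,
    release_override: float = None,
) -> TrialRecord:
    """Synthesize one stimulus presentation as a TrialRecord.

    Voltage-clamp conditions emit the isolated synaptic current at the clamped
    potential (superposition-valid closed-form waveforms); current-clamp
    conditions integrate the membrane ODE, with the inhibitory conductance
    removed under GABAzine.
    """
    condition = Condition(condition)
    if noise_sd is None:
        noise_sd = _default_noise(condition)
    ss = (_trial_seed(truth.seed, pattern.pattern_id, condition.value, repeat)
          if seed is None else np.random.SeedSequence(int(seed)))
    rng = np.random.default_rng(ss)
    g_exc, g_inh = _trial_conductances(truth, pattern, rng, release_override)
    inh_delay = delay_of(g_exc, truth.delay_model)

    n_samp = int(round(duration_ms / dt_ms)) + 1
    t = np.arange(n_samp) * dt_ms
    ek, ik = truth.exc_kinetics, truth.inh_kinetics

    if condition in VC_HOLD:
        vhold = VC_HOLD[condition]
        pp = ConductanceParams()
        if condition is Condition.VC_MINUS70:
            kin = SynapticKinetics(g_exc, ek.tau_rise_ms, ek.tau_decay_ms,
                                   stim_onset_ms + ek.delta_onset_ms)
            samples = synaptic_waveform(t, kin) * (vhold - pp.e_exc_mv)
        else:
            kin = SynapticKinetics(g_inh, ik.tau_rise_ms, ik.tau_decay_ms,
                                   stim_onset_ms + ik.delta_onset_ms + inh_delay)
            samples = synaptic_waveform(t, kin) * (vhold - pp.e_inh_mv)
        units = "pA"
    elif condition in (Condition.CC_CONTROL, Condition.CC_GABAZINE):
        params = ConductanceParams(dt_ms=dt_ms, duration_ms=duration_ms)
        gi = g_inh if condition is Condition.CC_CONTROL else 0.0
        _, _, traces = simulate_batch(params, [g_exc], [gi], [inh_delay],
                                      ek, ik, stim_onset_ms=stim_onset_ms,
                                      record=True)
        samples = traces[:, 0]
        units = "mV"
    else:  # pragma: no cover - Condition() above already rejects
        raise ValueError(f"unknown condition {condition!r}")

    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)
    trace = Trace(dt_ms=dt_ms, samples=samples, units=units,
                  stim_onset_ms=stim_onset_ms,
                  baseline_window_ms=(0.0, stim_onset_ms),
                  interest_window_ms=(stim_onset_ms,
                                      min(duration_ms, stim_onset_ms + 100.0)))
    return TrialRecord(cell_id=f"cell{truth.seed:04d}", pattern=pattern,
                       condition=condition, repeat_index=repeat, trace=trace)


@dataclass
class ExperimentConfig:
    """Design of one synthetic experiment (one simulated cell)."""

    grid_rows: int = 5
    grid_cols: int = 5
    design: dict = field(default_factory=lambda: {1: 24, 5: 5})  # N -> n patterns
    n_repeats: int = 3
    conditions: tuple = (Condition.CC_CONTROL,)
    noise_sd: float = None            # None -> per-condition default
    rho: float = 1.0
    weight_mu: float = DEFAULT_WEIGHT_MU
    weight_sigma: float = DEFAULT_WEIGHT_SIGMA
    conductance_per_weight_ns: float = 0.4
    ie_conductance_ratio: float = 0.75
    stim_onset_ms: float = 100.0
    duration_ms: float = 200.0
    dt_ms: float = 0.05


def _draw_patterns(cfg: ExperimentConfig, grid: GridSpec, rng):
    patterns = []
    single_pool = None  # multi-square combos draw from individually-presented squares
    for n_sq in sorted(cfg.design):
        count = cfg.design[n_sq]
        if n_sq > grid.n_squares:
            raise ValueError(f"{n_sq}-square patterns exceed grid of "
                             f"{grid.n_squares} squares")
        if n_sq == 1:
            if count > grid.n_squares:
                raise ValueError("more 1-square patterns than squares")
            squares = np.sort(rng.choice(grid.n_squares, size=count,
                                         replace=False))
            patterns.extend(StimPattern(f"S{int(s):03d}", (int(s),))
                            for s in squares)
            single_pool = squares
        else:
            from math import comb
            pool = (single_pool if single_pool is not None
                    and comb(single_pool.size, n_sq) >= count
                    else np.arange(grid.n_squares))
            if comb(int(pool.size), n_sq) < count:
                raise ValueError(
                    f"cannot draw {count} distinct {n_sq}-square patterns "
                    f"from {pool.size} squares")
            seen = set()
            k = 0
            while k < count:
                combo = tuple(sorted(int(s) for s in
                                     rng.choice(pool, size=n_sq,
                                                replace=False)))
                if combo in seen:
                    continue
                seen.add(combo)
                patterns.append(StimPattern(f"N{n_sq}_{k:03d}", combo))
                k += 1
    return patterns


def generate_experiment(config: ExperimentConfig, seed: int = 0):
    """Generate every trial of a full experiment.

    Returns (trials, truth, manifest): all requested patterns in every
    condition/repeat, the generator's ground truth, and a manifest mapping
    trial -> pattern -> squares that suffices to regenerate the experiment.
    """
    grid = GridSpec(config.grid_rows, config.grid_cols)
    truth = generate_network(
        grid, weight_mu=config.weight_mu, weight_sigma=config.weight_sigma,
        rho=config.rho, seed=seed,
        conductance_per_weight_ns=config.conductance_per_weight_ns,
        ie_conductance_ratio=config.ie_conductance_ratio)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xDE51)))
    patterns = _draw_patterns(config, grid, rng)

    # one integrator pass covers every current-clamp trial; voltage-clamp
    # trials are closed-form waveforms and are synthesized directly
    specs = []  # (pattern, condition, repeat, rng, g_exc, g_inh, delay)
    for pattern in patterns:
        for condition in config.conditions:
            condition = Condition(condition)
            for repeat in range(1, config.n_repeats + 1):
                trng = np.random.default_rng(_trial_seed(
                    truth.seed, pattern.pattern_id, condition.value, repeat))
                g_exc, g_inh = _trial_conductances(truth, pattern, trng)
                specs.append((pattern, condition, repeat, trng, g_exc, g_inh,
                              float(delay_of(g_exc, truth.delay_model))))

    cc_idx = [i for i, s in enumerate(specs) if s[1].is_current_clamp]
    cc_traces = None
    if cc_idx:
        params = ConductanceParams(dt_ms=config.dt_ms,
                                   duration_ms=config.duration_ms)
        ge = np.array([specs[i][4] for i in cc_idx])
        gi = np.array([specs[i][5] if specs[i][1] is Condition.CC_CONTROL
                       else 0.0 for i in cc_idx])
        dly = np.array([specs[i][6] for i in cc_idx])
        _, _, cc_traces = simulate_batch(params, ge, gi, dly,
                                         truth.exc_kinetics, truth.inh_kinetics,
                                         stim_onset_ms=config.stim_onset_ms,
                                         record=True)
    cc_col = {trial_i: col for col, trial_i in enumerate(cc_idx)}

    n_samp = int(round(config.duration_ms / config.dt_ms)) + 1
    t = np.arange(n_samp) * config.dt_ms
    pp = ConductanceParams()
    ek, ik = truth.exc_kinetics, truth.inh_kinetics
    trials = []
    for i, (pattern, condition, repeat, trng, g_exc, g_inh, dly) in enumerate(specs):
        if condition is Condition.VC_MINUS70:
            kin = SynapticKinetics(g_exc, ek.tau_rise_ms, ek.tau_decay_ms,
                                   config.stim_onset_ms + ek.delta_onset_ms)
            samples = synaptic_waveform(t, kin) * (VC_HOLD[condition] - pp.e_exc_mv)
            units = "pA"
        elif condition is Condition.VC_0:
            kin = SynapticKinetics(g_inh, ik.tau_rise_ms, ik.tau_decay_ms,
                                   config.stim_onset_ms + ik.delta_onset_ms + dly)
            samples = synaptic_waveform(t, kin) * (VC_HOLD[condition] - pp.e_inh_mv)
            units = "pA"
        else:
            samples = cc_traces[:, cc_col[i]].copy()
            units = "mV"
        noise_sd = (config.noise_sd if config.noise_sd is not None
                    else _default_noise(condition))
        if noise_sd > 0:
            samples = samples + trng.normal(0.0, noise_sd, size=samples.shape)
        trace = Trace(dt_ms=config.dt_ms, samples=samples, units=units,
                      stim_onset_ms=config.stim_onset_ms,
                      baseline_window_ms=(0.0, config.stim_onset_ms),
                      interest_window_ms=(config.stim_onset_ms,
                                          min(config.duration_ms,
                                              config.stim_onset_ms + 100.0)))
        trials.append(TrialRecord(cell_id=f"cell{truth.seed:04d}",
                                  pattern=pattern, condition=condition,
                                  repeat_index=repeat, trace=trace))
    manifest = {
        "seed": int(seed),
        "grid": {"n_rows": grid.n_rows, "n_cols": grid.n_cols,
                 "square_size_um": grid.square_size_um,
                 "inter_square_pitch_um": grid.inter_square_pitch_um},
        "design": {str(k): v for k, v in config.design.items()},
        "n_repeats": config.n_repeats,
        "conditions": [Condition(c).value for c in config.conditions],
        "generator": {
            "weight_mu": config.weight_mu,
            "weight_sigma": config.weight_sigma,
            "rho": config.rho,
            "conductance_per_weight_ns": config.conductance_per_weight_ns,
            "ie_conductance_ratio": config.ie_conductance_ratio,
            "release_p_exc": truth.release_p_exc,
            "release_p_inh": truth.release_p_inh,
        },
        "patterns": {p.pattern_id: list(p.squares) for p in patterns},
    }
    return trials, truth, manifest
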