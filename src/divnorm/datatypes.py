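"""Core value types shared across the package.

Units convention (dimensionally consistent throughout):
conductance nS, voltage mV, time ms, capacitance pF, current pA
(nS * mV = pA, pA / pF = mV / ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "QCFlag",
    "GridSpec",
    "StimPattern",
    "Trace",
    "TrialRecord",
    "GroundTruth",
    "SynapticKinetics",
    "PSPFeatures",
    "QCVerdict",
    "ConductanceParams",
    "DelayModel",
    "SynapticDrive",
    "SimResult",
    "EOPair",
    "EIBalanceFit",
    "SDNFit",
    "WeightTuningResult",
    "MIResult",
]


class Condition(str, Enum):
    """Recording configuration of a trial."""

    CC_CONTROL = "CC_CONTROL"      # current clamp, inhibition intact (mV)
    CC_GABAZINE = "CC_GABAZINE"    # current clamp, GABA-A blocked (mV)
    VC_MINUS70 = "VC_MINUS70"      # voltage clamp at -70 mV, isolates EPSC (pA)
    VC_0 = "VC_0"                  # voltage clamp at 0 mV, isolates IPSC (pA)

    @property
    def units(self) -> str:
        return "pA" if self.value.startswith("VC") else "mV"

    @property
    def is_current_clamp(self) -> bool:
        return self.value.startswith("CC")


class QCFlag(str, Enum):
    NOISY = "NOISY"
    SPIKE = "SPIKE"
    EXCLUDED_CELL = "EXCLUDED_CELL"


@dataclass(frozen=True)
class GridSpec:
    """Photostimulation grid of small squares covering the presynaptic field.

    Each square is addressed by a flat index in row-major order; physical
    coordinates are the square centres in micrometres.
    """

    n_rows: int
    n_cols: int
    square_size_um: float = 16.0
    inter_square_pitch_um: float = 16.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one square")
        if self.square_size_um <= 0 or self.inter_square_pitch_um <= 0:
            raise ValueError("square size and pitch must be positive")

    @property
    def n_squares(self) -> int:
        return self.n_rows * self.n_cols

    def coords_um(self, indices) -> np.ndarray:
        """(n, 2) array of square-centre coordinates in micrometres."""
        idx = np.atleast_1d(np.asarray(indices, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_squares):
            raise ValueError("square index outside grid")
        rows, cols = np.divmod(idx, self.n_cols)
        return np.column_stack([cols, rows]).astype(float) * self.inter_square_pitch_um


@dataclass(frozen=True)
class StimPattern:
    """A set of simultaneously stimulated grid squares."""

    pattern_id: str
    squares: tuple

    def __post_init__(self) -> None:
        sq = tuple(int(s) for s in self.squares)
        if len(set(sq)) != len(sq):
            raise ValueError(f"pattern {self.pattern_id}: duplicate square indices")
        object.__setattr__(self, "squares", sq)

    @property
    def n_squares(self) -> int:
        return len(self.squares)


@dataclass
class Trace:
    """A uniformly sampled recording with stimulus and analysis windows.

    ``samples`` carries either membrane potential (mV) or clamp current (pA);
    the ``units`` tag disambiguates. Windows are (start, stop) in ms on the
    trace's own time axis (t=0 at the first sample).
    """

    dt_ms: float
    samples: np.ndarray
    units: str
    stim_onset_ms: float
    baseline_window_ms: tuple = None
    interest_window_ms: tuple = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.units not in ("mV", "pA"):
            raise ValueError(f"unknown units tag {self.units!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.baseline_window_ms is None:
            self.baseline_window_ms = (max(0.0, self.stim_onset_ms - 100.0), self.stim_onset_ms)
        if self.interest_window_ms is None:
            end = min(self.duration_ms, self.stim_onset_ms + 100.0)
            self.interest_window_ms = (self.stim_onset_ms, end)
        for name, (a, b) in (("baseline", self.baseline_window_ms),
                             ("interest", self.interest_window_ms)):
            if not (0.0 <= a < b <= self.duration_ms + 1e-9):
                raise ValueError(f"{name} window ({a}, {b}) outside trace extent")

    @property
    def duration_ms(self) -> float:
        return (len(self.samples) - 1) * self.dt_ms

    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms

    def window_slice(self, window: tuple) -> slice:
        a, b = window
        return slice(int(round(a / self.dt_ms)), int(round(b / self.dt_ms)) + 1)

    def baseline(self) -> np.ndarray:
        return self.samples[self.window_slice(self.baseline_window_ms)]

    def interest(self) -> np.ndarray:
        return self.samples[self.window_slice(self.interest_window_ms)]


@dataclass
class TrialRecord:
    """One stimulus presentation to one cell."""

    cell_id: str
    pattern: StimPattern
    condition: Condition
    repeat_index: int
    trace: Trace
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.repeat_index < 1:
            raise ValueError("repeat_index starts at 1")
        expected_units = self.condition.units
        if self.trace.units != expected_units:
            raise ValueError(
                f"{self.condition.value} trials carry {expected_units} traces, "
                f"got {self.trace.units}"
            )


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests.

    ``exc_weights`` / ``inh_weights`` are per-square synaptic weights (the
    inhibitory vector is a bin-shuffled copy of the excitatory one, so the two
    always share the same multiset of values). ``engaged_counts`` holds the
    per-square engaged-synapse draws shared across patterns and repeats.
    """

    grid: GridSpec
    exc_weights: np.ndarray
    inh_weights: np.ndarray
    engaged_counts: np.ndarray
    rho: float
    weight_mu: float
    weight_sigma: float
    exc_kinetics: "SynapticKinetics"
    inh_kinetics: "SynapticKinetics"
    delay_model: "DelayModel"
    conductance_per_weight_ns: float
    ie_conductance_ratio: float
    release_p_exc: float
    release_p_inh: float
    seed: int


@dataclass
class SynapticKinetics:
    """Difference-of-exponentials description of one synaptic conductance/PSC.

    g_bar is the waveform's peak (nS for conductances, pA for currents);
    the waveform is normalized so its maximum equals g_bar exactly.
    """

    g_bar: float
    tau_rise_ms: float
    tau_decay_ms: float
    delta_onset_ms: float = 0.0
    fit_rss: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("requires tau_decay > tau_rise > 0")
        if self.g_bar < 0:
            raise ValueError("g_bar must be non-negative")
        if self.delta_onset_ms < 0:
            raise ValueError("onset delay must be non-negative")


@dataclass
class PSPFeatures:
    """Scalar response measures of one trial (post preprocessing)."""

    peak_amp: float
    peak_time_ms: float
    auc: float
    mean_v: float
    auc_to_peak: float
    onset_time_ms: float = math.nan


@dataclass
class QCVerdict:
    trial_flags: set = field(default_factory=set)
    cell_flags: set = field(default_factory=set)
    passed: bool = True
    reasons: list = field(default_factory=list)
    unknown: bool = False


@dataclass
class ConductanceParams:
    """Passive single-compartment membrane constants."""

    cm_pf: float = 100.0
    g_leak_ns: float = 6.25
    e_leak_mv: float = -65.0
    e_exc_mv: float = 0.0
    e_inh_mv: float = -70.0
    dt_ms: float = 0.01
    duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.cm_pf <= 0 or self.g_leak_ns <= 0:
            raise ValueError("cm and g_leak must be positive")
        if not (self.e_inh_mv <= self.e_leak_mv <= self.e_exc_mv):
            raise ValueError("requires e_inh <= e_leak <= e_exc")
        if self.dt_ms <= 0 or self.dt_ms > 0.05:
            raise ValueError("dt_ms must lie in (0, 0.05]")


@dataclass
class DelayModel:
    """Inhibitory onset lag relative to excitation.

    DYNAMIC mode: delta = delta_min + m * exp(-k * g_exc)  (shrinks with drive)
    STATIC mode:  delta = static_delay_ms (defaults to delta_min + m so the two
    laws agree at g_exc = 0).
    """

    delta_min_ms: float = 2.0
    k_per_ns: float = 0.5
    m_ms: float = 8.15
    mode: str = "dynamic"
    static_delay_ms: float = None

    def __post_init__(self) -> None:
        if self.delta_min_ms < 0 or self.m_ms < 0 or self.k_per_ns < 0:
            raise ValueError("delay-law constants must be non-negative")
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"unknown delay mode {self.mode!r}")
        if self.static_delay_ms is None:
            self.static_delay_ms = self.delta_min_ms + self.m_ms


@dataclass
class SynapticDrive:
    """Paired excitatory/inhibitory conductance input to the model cell."""

    exc: SynapticKinetics
    inh: SynapticKinetics = None
    ie_ratio: float = 0.0
    delay: DelayModel = field(default_factory=DelayModel)


@dataclass
class SimResult:
    trace: Trace
    v_max: float               # peak depolarization above rest, mV
    v_max_time_ms: float
    spike_times_ms: list = field(default_factory=list)


@dataclass
class EOPair:
    """One observed-vs-expected response point.

    expected: linear sum of constituent single-square responses (mV);
    observed: the measured multi-square response (mV).
    """

    expected: float
    observed: float
    n_squares: int = 0
    pattern_id: str = ""


@dataclass
class EIBalanceFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: np.ndarray


@dataclass
class SDNFit:
    model: str
    alpha: float
    beta: float
    gamma: float
    rss: float
    n: int
    k_params: int
    bic: float
    red_chisq: float


@dataclass
class WeightTuningResult:
    rho: float
    weight_sigma: float
    mean_r_squared: float
    sd_correlation: float
    n_repetitions: int


@dataclass
class MIResult:
    """Histogram mutual-information estimate with its shuffle-null verdict.

    ``mi`` is the reported value (set to 0 when not significant, following the
    convention that estimates indistinguishable from the shuffle null carry no
    information); ``mi_raw`` is the plug-in estimate before that rule.
    """

    mi: float
    mi_raw: float
    shuffle_p_like: float
    significant: bool
    n_shuffles: int = 500
    normalized: float = math.nan
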