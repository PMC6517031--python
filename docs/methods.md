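# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the package, in the spirit of a simulator's model
description.

## Membrane and synapse model

The passive cell is a single compartment,

    Cm dVm/dt = -[ g_leak (Vm - E_leak) + g_exc(t)(Vm - E_exc) + g_inh(t)(Vm - E_inh) ],

with the physically consistent sign (the bracketed sum is the total outward
current; any other sign convention fails to produce depolarizing EPSPs).
Units are fixed as nS / mV / ms / pF / pA, which are mutually consistent
(nS·mV = pA, pA/pF = mV/ms).

Synaptic conductances are differences of exponentials normalized so that
the waveform's maximum equals its amplitude parameter exactly:

    g(t) = ḡ [e^{-(t-δ)/τ_d} - e^{-(t-δ)/τ_r}] / N(τ_r, τ_d),  t ≥ δ,

where N is the analytic peak of the unnormalized difference,
N = r^{τ_r/(τ_d-τ_r)} - r^{τ_d/(τ_d-τ_r)} with r = τ_r/τ_d. This makes "peak
conductance" an interpretable parameter and is asserted to 1e-6 relative
accuracy over random kinetics draws.

Inhibition lags excitation by δ_inh(g_exc) = δ_min + m·e^{-k·g_exc}
(dynamic mode) or by a constant (static mode, defaulting to δ_min + m so the
two laws agree at zero drive). Documented working points: (δ_min, k, m) =
(2 ms, 0.5 nS⁻¹, 8.15 ms) for the summation sweeps and (2 ms, 2 nS⁻¹, 13 ms)
for the delay-vs-conductance relationship itself.

Defaults for the passive cell: Cm = 100 pF, g_leak = 6.25 nS (τ_m = 16 ms),
E_leak = -65 mV, E_exc = 0 mV, E_inh = -70 mV; excitatory kinetics
τ_r/τ_d = 2/10 ms, inhibitory 2/15 ms. All are config-overridable; only the
reversal potentials are anchored to measured values, the rest are standard
pyramidal-cell magnitudes.

**Integrator.** Fixed-step classical RK4, dt = 0.01 ms by default (0.05 ms
for 20 kHz synthetic recordings — the dataclass enforces dt ≤ 0.05 ms). The
integrator is vectorized across batches of (g_exc, g_inh, delay) triples, so
a whole sweep, or a whole ensemble of shuffle permutations, integrates in
one pass. Accuracy is checked two ways: dt-halving changes the peak
depolarization by < 0.1% (Richardson check on random drives), and
constant-conductance runs match the closed-form exponential relaxation
segment-by-segment to < 0.1%, which also covers piecewise-constant drives.
Divergence (|Vm| > 200 mV) raises rather than returning garbage.

**Hodgkin–Huxley variant.** Classical squid-convention Na and
delayed-rectifier K kinetics with all gate rate functions shifted +15 mV
depolarized, total densities 6000 nS (Na) and 1800 nS (K) on the same
passive cell. The shift keeps both channels essentially closed at the
-65 mV rest (subthreshold responses match the passive model within 2 mV)
and puts spike threshold near -40 mV. Spike times are upward crossings of a
configurable threshold (0 mV default) with a 2 ms refractory
deduplication. The mapping from subthreshold summation to spike timing is
sensitive to threshold and densities — which is why they are first-class
parameters — and the latency separation between balanced and
excitation-only conditions is only visible in the strong-drive regime
(tens of nS) at moderate I/E ratios.

## Synthetic experiments

The generator emulates grid photostimulation of presynaptic neurons while
recording one postsynaptic cell: a grid of 16 µm squares (≤ 225 by default),
patterns of N ∈ {1,2,3,5,7,9} squares, 2–6 repeats, four recording
conditions (current clamp control / inhibition-blocked; voltage clamp at
-70 mV isolating the EPSC and at 0 mV isolating the IPSC).

Generative assumptions, in order of application:

1. Per-square synaptic weights are i.i.d. lognormal with underlying-normal
   parameters (µ = -0.39, σ = 0.80). A strictly positive "shape" convention
   cannot be negative, so the printed pair is read as the underlying
   normal's (µ, σ). Overridable.
2. The inhibitory weight vector is the excitatory one shuffled within
   contiguous bins of size max(1, round((1-ρ)·L)): ρ = 1 is perfectly
   paired (detailed balance), ρ = 0 fully shuffled (global balance). The
   E and I multisets are identical for every ρ.
3. Each square engages a Poisson(mean 5) number of synapses. The counts are
   drawn once per network and shared by every pattern, repeat and
   condition, with identical counts for E and I of a square ("number
   balance"). Drawing per square (rather than per pattern) makes
   multi-square stimuli exact unions of their constituent single squares,
   which is what the observed-vs-expected analysis presumes; redraw modes
   would break the voltage-clamp superposition identity that the tests
   assert to 1e-9.
4. Per trial, each engaged synapse releases independently (binomial,
   p = 0.2 excitatory / 0.8 inhibitory); released weights sum into peak
   conductances with a conversion of 0.4 nS per weight unit and an
   inhibitory conductance gain of 0.75. With the release asymmetry this
   yields measured I/E response ratios near 3 (the middle of the
   physiological 2–5 band) and keeps inhibition-blocked multi-square PSPs
   subthreshold, as in the recordings being emulated.
5. Voltage-clamp trials are closed-form waveforms times the driving force
   (EPSCs inward/negative at -70 mV, IPSCs outward/positive at 0 mV);
   current-clamp trials integrate the membrane ODE, with g_inh removed in
   the inhibition-blocked condition. Additive i.i.d. Gaussian noise
   (0.05 mV / 2 pA defaults) models recording noise.
6. Seeding: one master seed; each trial derives an independent stream from
   (master, CRC32(pattern|condition|repeat)), so the batched experiment
   path and the single-trial path produce bit-identical traces, and a rerun
   regenerates every file byte-for-byte.

What the generator does **not** emulate: opsin photocurrent kinetics and
desensitization, optical point-spread and cross-stimulation, dendritic
filtering and nonlinearities, feedback inhibition, series-resistance and
space-clamp artifacts in voltage clamp, and slow drift. Passing tests
therefore show that the analysis chain recovers the structure this
generative model produces — not that real recordings contain no further
structure.

## Signal processing and QC

Preprocessing is a 4-pole low-pass Bessel filter (2 kHz default) applied
forward-backward (zero phase, to avoid biasing onset times) followed by
baseline-window mean subtraction (baseline = 100 ms before stimulus,
interest window = 100 ms after). Features are peak amplitude, peak time,
trapezoidal area, window mean and area-to-peak of the condition-rectified
deflection (inward EPSCs and outward IPSCs are both reported positive).

Trial QC: a trial is flagged response-absent ("NOISY") when the two-sample
KS test cannot distinguish interest from baseline samples (p ≥ 0.05 — the
flag fires on *indistinguishable* windows), and "SPIKE" when a
current-clamp trace crosses -20 mV. Cell QC applies the printed exclusion
rules (input-resistance change > 25%; Vm drift > 2.5 mV, or > 5 mV for
presynaptic-side cells; series resistance > 25 MΩ or > 30% change), with
strict inequalities at the boundaries and an explicit "unknown" verdict
when fields are missing.

Onset detection offers three methods: first threshold crossing (default
threshold 10% of the window extremum with a floor of 5 baseline sd — a
3-sd floor would fire on the extreme order statistics of a 2000-sample
noise window), steepest rise before the peak (same noise gate), and the
earliest pair of consecutive 0.5 ms windows whose distributions differ by
KS, with the alpha Bonferroni-corrected over the scanned pairs for the same
reason. Kinetics fits (lmfit least squares) parameterize the decay as
τ_r + Δτ with Δτ > 0 so the τ_d > τ_r invariant survives optimization, and
restart with jittered initials on poor convergence; a non-converged fit is
returned flagged, never silently.

## Gain-model fitting

The composite gain equation θ = ε − β·ε²/(γ+ε) − α nests SI (free α),
DI (free β) and DN (free γ); the composite with all three parameters free is
available but poorly identifiable and not a default. Fits use bounded
least squares (γ ∈ (0, 1e6], β ∈ [0, 2], α ≥ 0) with 5 deterministic
multi-starts. BIC = n·ln(RSS/n) + k·ln(n) under Gaussian errors; reduced
χ² uses a supplied repeat-based noise variance when available and the
residual variance otherwise (in which case it is 1 by construction and only
the BIC comparison is informative). Exactly linear data drives the DN γ to
its upper bound — "no normalization" — which is the intended reading; phase
maps label cells with γ > 40 accordingly.

Observed values default to per-trial points; stimulus-averaged mode is
available. Expected values are sums of stimulus-averaged single-square
responses, so with few repeats and low release probability they carry
sampling noise; this inflates small observed/expected ratios (a
noisy-denominator bias) but does not bias the (ε, θ) regression fits
themselves.

## EI balance and the weight-tuning scan

The balance fit is OLS of I on E with an intercept (slope = I/E ratio; a
through-origin option exists for sensitivity analysis). The weight-tuning
scan draws a weight vector per repetition, tunes inhibition to degree ρ,
delivers 30 stimuli each engaging a Poisson(5) subset of synapses with
6 binomial-release repeats, and summarizes mean-amplitude R² and the
correlation of per-stimulus repeat sds over 100 repetitions (plain mean for
R², Fisher-z mean for correlations).

One modelling decision deserves emphasis: the mean-amplitude correlation is
computed on release-probability-scaled *expected* stimulus amplitudes (the
large-repeat limit of the empirical means), while the binomial trial noise
drives the sd correlations. With ~5 engaged synapses and p = 0.2, the
excitatory side of an empirical 6-repeat mean is dominated by release
sampling noise (≈ 1 released synapse per trial), which caps every R² near
0.6 regardless of tuning and would turn the heatmap into a readout of
release noise rather than of weight tuning. The `mean_mode="empirical"`
option retains the literal small-sample behaviour for anyone who wants it.

## Information analysis

All estimators are plug-in histogram quantities in bits with equal-width
bins over each variable's observed range and Sturges' count
ceil(1 + 3.3·log10 n) (log base 10; both overridable). Significance is a
permutation test: the variable pairing is shuffled 500 times and an
estimate must strictly exceed the null's 90th percentile, else it is
reported as 0. Under independence this criterion's false-significance rate
calibrates to ≈ 8–10% (asserted ≤ 15%). The "total information" identity
H(Z) + H(X,Y) − H(X,Y,Z) equals I((X,Y);Z); the chain-rule decomposition
I(Z;X) + I(Z;Y|X) = I((X,Y);Z) holds exactly on the plug-in estimates and
is asserted to 1e-9. Normalized quantities divide each component by this
total. Conditions with fewer than 80 trials or an input (expected-sum)
inter-quartile range below 2 mV are excluded with explicit reasons. Plug-in
entropies are biased at small n; no Miller–Madow-style correction is
applied (out of scope), which is acceptable here because all comparisons
are within-estimator and shuffle-calibrated. A k-nearest-neighbour
estimator would be a natural extension behind the same interface.

The amplitude/timing analysis assigns Z = expected sum (input proxy),
Y = peak amplitude, X = peak time — exposed as explicit arguments, not
hard-coded.

## Problem sizes

Default analysis sizes were chosen so every result is stable under seed
changes while the full test suite and the acceptance script each run in a
few minutes on one CPU: 16-point conductance sweeps, 100 shuffle
permutations per control, 200 Monte-Carlo seeds for recovery/selection
calibration, 100 repetitions per weight-tuning cell, 5×5 phase maps on
10-point sweeps, 500-trial information datasets with 500-shuffle
significance, and a 37-pattern × 6-repeat × 4-condition demo experiment
(888 trials). All scale up linearly via function arguments.

## Known limitations

- Single compartment: no dendritic saturation, NMDA or Ih contributions;
  the residual sublinearity that survives inhibition block in real cells is
  only partly reproduced (leak-conductance saturation is present, active
  conductances are not).
- The HH variant's channel constants are representative, not fitted to a
  specific cell; conclusions drawn from it are qualitative orderings, not
  quantitative latencies.
- The delay law is imposed, not emergent: interneuron spiking dynamics are
  reduced to δ_inh(g_exc).
- Histogram MI at n ≈ 100–500 with Sturges binning underestimates
  continuous MI; only comparisons between conditions computed identically
  are meaningful.
- The weight-tuning scan's expected-mean convention (above) trades literal
  small-sample fidelity for a readout of the quantity of interest.
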