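"""Excitation-inhibition balance analyses.

A cell is "balanced" when inhibitory response magnitudes are proportional to
excitatory ones across stimuli; the regression slope of I on E is the cell's
I/E ratio and the fit's R-squared quantifies how tightly the proportionality
holds. The weight-tuning scan asks when such balance is observable: synaptic
weights are drawn from a lognormal distribution whose width is set by sigma,
and the inhibitory weight vector is tuned to the excitatory one to a degree
set by rho (1 = detailed balance, 0 = global balance only).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import EIBalanceFit, WeightTuningResult
from .synthgen import (
    DEFAULT_WEIGHT_MU,
    RELEASE_P_EXC,
    RELEASE_P_INH,
    shuffle_within_bins,
)

__all__ = [
    "EIBalanceRegression",
    "fit_ei_balance",
    "derived_inhibition",
    "ei_variability_correlation",
    "run_weight_tuning_scan",
]


class EIBalanceRegression(BaseEstimator, RegressorMixin):
    """Ordinary least-squares line I = slope * E + intercept.

    The slope is reported as the cell's I/E ratio. ``fit_intercept=False``
    forces the line through the origin (sensitivity analysis).

    Attributes after fit: slope_, intercept_, r_squared_, residuals_, n_points_.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        e = np.asarray(X, dtype=float).ravel()
        i = np.asarray(y, dtype=float).ravel()
        if e.shape != i.shape:
            raise ValueError("E and I vectors must have the same length")
        if e.size < 3:
            raise ValueError("need at least 3 points for a reported fit")
        if np.ptp(e) == 0:
            raise ValueError("zero variance in E: slope undefined")
        if self.fit_intercept:
            A = np.column_stack([e, np.ones_like(e)])
        else:
            A = e[:, None]
        coef, *_ = np.linalg.lstsq(A, i, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1]) if self.fit_intercept else 0.0
        pred = A @ coef
        self.residuals_ = i - pred
        ss_res = float(np.sum(self.residuals_ ** 2))
        ss_tot = float(np.sum((i - i.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.r_squared_ = float(np.clip(self.r_squared_, 0.0, 1.0))
        self.n_points_ = int(e.size)
        return self

    def predict(self, X):
        e = np.asarray(X, dtype=float).ravel()
        return self.slope_ * e + self.intercept_


def fit_ei_balance(e_values, i_values, fit_intercept: bool = True) -> EIBalanceFit:
    """I-vs-E regression over stimulus-averaged response magnitudes."""
    reg = EIBalanceRegression(fit_intercept=fit_intercept).fit(e_values, i_values)
    return EIBalanceFit(slope=reg.slope_, intercept=reg.intercept_,
                        r_squared=reg.r_squared_, n_points=reg.n_points_,
                        residuals=reg.residuals_)


def derived_inhibition(control: dict, gabazine: dict) -> dict:
    """Per-pattern inhibition inferred from the inhibition-blocked condition.

    Both arguments map pattern id -> response value (same measure, typically
    AUC); the derived inhibitory component is (GABAzine - control) per
    pattern. Raises when the pattern sets differ, naming the missing ids.
    """
    missing = sorted(set(control) ^ set(gabazine))
    if missing:
        raise ValueError(f"unmatched patterns between conditions: {missing}")
    return {pid: gabazine[pid] - control[pid] for pid in control}


def ei_variability_correlation(e_repeats: dict, i_repeats: dict) -> float:
    """Pearson correlation of per-stimulus E and I repeat variability.

    Arguments map pattern id -> per-repeat response values. For each pattern
    the sample sd across repeats is computed for E and for I; the returned
    value is the correlation of those sds across patterns.
    """
    common = sorted(set(e_repeats) & set(i_repeats))
    if len(common) < 3:
        raise ValueError("need at least 3 matched patterns")
    sds_e, sds_i = [], []
    for pid in common:
        e = np.asarray(e_repeats[pid], dtype=float)
        i = np.asarray(i_repeats[pid], dtype=float)
        if e.size < 2 or i.size < 2:
            raise ValueError(f"pattern {pid}: need >= 2 repeats for an sd")
        sds_e.append(e.std(ddof=1))
        sds_i.append(i.std(ddof=1))
    return float(np.corrcoef(sds_e, sds_i)[0, 1])


def _fisher_mean(correlations) -> float:
    """Variance-stabilized (Fisher z) average of correlation coefficients."""
    r = np.clip(np.asarray(correlations, dtype=float), -0.999999, 0.999999)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(r))))


def _scan_cell(rho, sigma, n_reps, rng, n_weights, n_stimuli, n_repeats,
               mean_synapses, p_exc, p_inh, weight_mu, mean_mode):
    r2s, sdcs = [], []
    for _ in range(n_reps):
        if sigma == 0:
            w_exc = np.full(n_weights, np.exp(weight_mu))
        else:
            w_exc = rng.lognormal(weight_mu, sigma, n_weights)
        w_inh = shuffle_within_bins(w_exc, rho, rng)
        mean_e = np.empty(n_stimuli)
        mean_i = np.empty(n_stimuli)
        sd_e = np.empty(n_stimuli)
        sd_i = np.empty(n_stimuli)
        for s in range(n_stimuli):
            n = max(int(rng.poisson(mean_synapses)), 1)
            idx = rng.choice(n_weights, size=min(n, n_weights), replace=False)
            we, wi = w_exc[idx], w_inh[idx]
            amp_e = (rng.random((n_repeats, idx.size)) < p_exc) @ we
            amp_i = (rng.random((n_repeats, idx.size)) < p_inh) @ wi
            if mean_mode == "expected":
                mean_e[s], mean_i[s] = p_exc * we.sum(), p_inh * wi.sum()
            else:
                mean_e[s], mean_i[s] = amp_e.mean(), amp_i.mean()
            sd_e[s], sd_i[s] = amp_e.std(ddof=1), amp_i.std(ddof=1)
        if np.ptp(mean_e) == 0 or np.ptp(mean_i) == 0:
            continue
        r = np.corrcoef(mean_e, mean_i)[0, 1]
        r2s.append(r * r)
        if np.ptp(sd_e) > 0 and np.ptp(sd_i) > 0:
            sdcs.append(np.corrcoef(sd_e, sd_i)[0, 1])
    return float(np.mean(r2s)), _fisher_mean(sdcs), len(r2s)


def run_weight_tuning_scan(
    rho_grid,
    sigma_grid,
    n_reps: int = 100,
    seed: int = 0,
    n_weights: int = 100,
    n_stimuli: int = 30,
    n_repeats: int = 6,
    mean_synapses: float = 5.0,
    release_p_exc: float = RELEASE_P_EXC,
    release_p_inh: float = RELEASE_P_INH,
    weight_mu: float = DEFAULT_WEIGHT_MU,
    mean_mode: str = "expected",
):
    """EI-balance observability across (rho, sigma): the weight-tuning heatmap.

    For each (rho, sigma) cell: draw a weight vector, tune inhibition to
    degree rho, deliver ``n_stimuli`` stimuli (each engaging a Poisson-mean-5
    subset of synapses, repeated ``n_repeats`` times with independent binomial
    release at 0.2/0.8), fit I vs E across stimuli and correlate the
    per-stimulus repeat sds; average over ``n_reps`` independent runs (plain
    mean for R-squared, Fisher-z mean for the sd correlation).

    ``mean_mode='expected'`` (default) correlates release-probability-scaled
    expected stimulus amplitudes: the binomial trial-to-trial noise then enters
    only the sd correlations, not the mean correlations, which keeps the
    heatmap a readout of weight tuning rather than of release sampling noise.
    ``mean_mode='empirical'`` uses the n_repeats-trial sample means instead.

    Returns a list of WeightTuningResult in row-major (rho, sigma) order.
    """
    rho_grid = np.atleast_1d(np.asarray(rho_grid, dtype=float))
    sigma_grid = np.atleast_1d(np.asarray(sigma_grid, dtype=float))
    if rho_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mean_mode not in ("expected", "empirical"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    results = []
    for i, rho in enumerate(rho_grid):
        for j, sigma in enumerate(sigma_grid):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), i, j)))
            mean_r2, sd_corr, n_ok = _scan_cell(
                rho, sigma, n_reps, rng, n_weights, n_stimuli, n_repeats,
                mean_synapses, release_p_exc, release_p_inh, weight_mu,
                mean_mode)
            results.append(WeightTuningResult(
                rho=float(rho), weight_sigma=float(sigma),
                mean_r_squared=mean_r2, sd_correlation=sd_corr,
                n_repetitions=n_ok))
    return results
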