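"""Histogram Shannon entropy, mutual information and shuffle significance.

All estimates are plug-in (maximum-likelihood) histogram quantities in bits,
with equal-width bins over each variable's observed range and the bin count
chosen by Sturges' rule, ceil(1 + 3.3 log10 n). Significance of an MI
estimate is assessed against a permutation null: the pairing between
variables is shuffled (default 500 times) and the estimate is reported as 0
unless it exceeds the null's 90th percentile.

The three variables of the amplitude/timing analysis are
Z = expected sum (linear sum of single-square responses, the input proxy),
Y = PSP peak amplitude, X = PSP peak time.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import MIResult

__all__ = [
    "sturges_bins",
    "entropy",
    "entropy_of_counts",
    "mutual_info",
    "conditional_mi",
    "total_and_normalized",
    "amplitude_time_analysis",
]

DEFAULT_N_SHUFFLES = 500
SIGNIFICANCE_PERCENTILE = 90.0
MIN_TRIALS = 80
MIN_INPUT_IQR_MV = 2.0


def sturges_bins(n: int, log_base: float = 10.0) -> int:
    """Histogram bin count by Sturges' rule, ceil(1 + 3.3 log10 n)."""
    if n < 2:
        raise ValueError("Sturges' rule needs at least 2 observations")
    return int(math.ceil(1.0 + 3.3 * math.log(n, log_base)))


def entropy(probs) -> float:
    """Shannon entropy (bits) of a probability vector; 0*log0 == 0."""
    p = np.asarray(probs, dtype=float).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def entropy_of_counts(counts) -> float:
    c = np.asarray(counts, dtype=float).ravel()
    n = c.sum()
    return entropy(c / n) if n > 0 else 0.0


def _digitize(x, bins: int) -> np.ndarray:
    """Equal-width bin indices over the observed min-max range."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.intp)
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.intp)
    return np.minimum(idx, bins - 1)


def _joint_entropy(*index_arrays, n_bins: int) -> float:
    flat = index_arrays[0]
    for ix in index_arrays[1:]:
        flat = flat * n_bins + ix
    counts = np.bincount(flat, minlength=n_bins ** len(index_arrays))
    return entropy_of_counts(counts)


def _mi_from_indices(xi, yi, n_bins):
    return (_joint_entropy(xi, n_bins=n_bins)
            + _joint_entropy(yi, n_bins=n_bins)
            - _joint_entropy(xi, yi, n_bins=n_bins))


def _significance(observed: float, null: np.ndarray,
                  percentile: float = SIGNIFICANCE_PERCENTILE):
    crit = float(np.percentile(null, percentile))
    significant = observed > crit
    p_like = float(np.mean(null >= observed))
    return significant, p_like


def _check_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("variables must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return x, y


def mutual_info(x, y, bins: int = None, n_shuffles: int = DEFAULT_N_SHUFFLES,
                seed: int = 0,
                percentile: float = SIGNIFICANCE_PERCENTILE) -> MIResult:
    """MI(X, Y) = H(X) + H(Y) - H(X, Y) with a permutation-null verdict.

    The pairing of y with x is permuted ``n_shuffles`` times; the estimate is
    significant iff it strictly exceeds the null's ``percentile`` percentile,
    and is reported as 0 otherwise.
    """
    x, y = _check_xy(x, y)
    if bins is None:
        bins = sturges_bins(x.size)
    xi, yi = _digitize(x, bins), _digitize(y, bins)
    mi_raw = _mi_from_indices(xi, yi, bins)
    rng = np.random.default_rng(seed)
    null = np.array([_mi_from_indices(xi, rng.permutation(yi), bins)
                     for _ in range(n_shuffles)])
    significant, p_like = _significance(mi_raw, null, percentile)
    return MIResult(mi=mi_raw if significant else 0.0, mi_raw=mi_raw,
                    shuffle_p_like=p_like, significant=significant,
                    n_shuffles=n_shuffles)


def conditional_mi(x, y, z, bins: int = None,
                   n_shuffles: int = DEFAULT_N_SHUFFLES, seed: int = 0,
                   percentile: float = SIGNIFICANCE_PERCENTILE) -> MIResult:
    """I(X; Y | Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z), shuffle-tested on y."""
    x, y = _check_xy(x, y)
    z = np.asarray(z, dtype=float).ravel()
    if z.size != x.size:
        raise ValueError("variables must have equal length")
    if bins is None:
        bins = sturges_bins(x.size)
    xi, yi, zi = _digitize(x, bins), _digitize(y, bins), _digitize(z, bins)

    def cmi(yy):
        return (_joint_entropy(xi, zi, n_bins=bins)
                + _joint_entropy(yy, zi, n_bins=bins)
                - _joint_entropy(xi, yy, zi, n_bins=bins)
                - _joint_entropy(zi, n_bins=bins))

    raw = cmi(yi)
    rng = np.random.default_rng(seed)
    null = np.array([cmi(rng.permutation(yi)) for _ in range(n_shuffles)])
    significant, p_like = _significance(raw, null, percentile)
    return MIResult(mi=raw if significant else 0.0, mi_raw=raw,
                    shuffle_p_like=p_like, significant=significant,
                    n_shuffles=n_shuffles)


def total_information(x, y, z, bins: int = None) -> float:
    """I((X,Y); Z) = H(Z) + H(X,Y) - H(X,Y,Z): joint information about Z."""
    x, y = _check_xy(x, y)
    z = np.asarray(z, dtype=float).ravel()
    if bins is None:
        bins = sturges_bins(x.size)
    xi, yi, zi = _digitize(x, bins), _digitize(y, bins), _digitize(z, bins)
    return (_joint_entropy(zi, n_bins=bins)
            + _joint_entropy(xi, yi, n_bins=bins)
            - _joint_entropy(xi, yi, zi, n_bins=bins))


def total_and_normalized(x, y, z, bins: int = None,
                         n_shuffles: int = DEFAULT_N_SHUFFLES, seed: int = 0):
    """Total information and the component MIs normalized by it.

    Returns a dict with 'total' (I((X,Y);Z) as an MIResult, shuffle-tested by
    permuting z), 'mi_xz', 'mi_yz', 'cmi_xy_given_z' MIResults whose
    ``normalized`` fields divide each raw component by the total. A zero
    total leaves the normalized fields NaN (flagged via 'undefined').
    """
    x, y = _check_xy(x, y)
    z = np.asarray(z, dtype=float).ravel()
    if bins is None:
        bins = sturges_bins(x.size)
    xi, yi, zi = _digitize(x, bins), _digitize(y, bins), _digitize(z, bins)

    def total_of(zz):
        return (_joint_entropy(zz, n_bins=bins)
                + _joint_entropy(xi, yi, n_bins=bins)
                - _joint_entropy(xi, yi, zz, n_bins=bins))

    raw_total = total_of(zi)
    rng = np.random.default_rng(seed)
    null = np.array([total_of(rng.permutation(zi)) for _ in range(n_shuffles)])
    significant, p_like = _significance(raw_total, null)
    total = MIResult(mi=raw_total if significant else 0.0, mi_raw=raw_total,
                     shuffle_p_like=p_like, significant=significant,
                     n_shuffles=n_shuffles)

    mi_xz = mutual_info(x, z, bins=bins, n_shuffles=n_shuffles, seed=seed + 1)
    mi_yz = mutual_info(y, z, bins=bins, n_shuffles=n_shuffles, seed=seed + 2)
    cmi = conditional_mi(z, x, y, bins=bins, n_shuffles=n_shuffles,
                         seed=seed + 3)
    undefined = raw_total <= 0
    for res in (mi_xz, mi_yz, cmi):
        res.normalized = math.nan if undefined else res.mi_raw / raw_total
    total.normalized = math.nan if undefined else 1.0
    return {"total": total, "mi_xz": mi_xz, "mi_yz": mi_yz,
            "cmi_xy_given_z": cmi, "undefined": bool(undefined)}


def amplitude_time_analysis(eo_table: pd.DataFrame, conditions=None,
                            n_shuffles: int = DEFAULT_N_SHUFFLES,
                            seed: int = 0) -> pd.DataFrame:
    """Amplitude-vs-timing information split, per condition.

    ``eo_table`` needs columns ``condition, expected, peak_amp, peak_time``
    (one row per trial). Per condition the function reports MI(input; amp),
    MI(input; time), CMI(input; time | amp), the total information carried
    jointly, and each component normalized by the total. Conditions with
    fewer than 80 trials or an expected-sum inter-quartile range below 2 mV
    are excluded with an explicit reason.
    """
    rows = []
    conds = conditions or sorted(eo_table["condition"].unique())
    for k, cond in enumerate(conds):
        sub = eo_table[eo_table["condition"] == cond]
        n = len(sub)
        if n < MIN_TRIALS:
            rows.append({"condition": cond, "n_trials": n,
                         "excluded": True,
                         "reason": f"fewer than {MIN_TRIALS} trials"})
            continue
        z = sub["expected"].to_numpy()
        iqr = float(np.percentile(z, 75) - np.percentile(z, 25))
        if iqr < MIN_INPUT_IQR_MV:
            rows.append({"condition": cond, "n_trials": n, "excluded": True,
                         "reason": f"expected-sum IQR {iqr:.2f} mV < "
                                   f"{MIN_INPUT_IQR_MV} mV"})
            continue
        amp = sub["peak_amp"].to_numpy()
        tpk = sub["peak_time"].to_numpy()
        res = total_and_normalized(tpk, amp, z, n_shuffles=n_shuffles,
                                   seed=seed + 101 * k)
        rows.append({
            "condition": cond, "n_trials": n, "excluded": False, "reason": "",
            "mi_amp": res["mi_yz"].mi, "mi_time": res["mi_xz"].mi,
            "cmi_time_given_amp": res["cmi_xy_given_z"].mi,
            "cmi_significant": res["cmi_xy_given_z"].significant,
            "total": res["total"].mi_raw,
            "norm_mi_amp": res["mi_yz"].normalized,
            "norm_mi_time": res["mi_xz"].normalized,
            "norm_cmi_time_given_amp": res["cmi_xy_given_z"].normalized,
        })
    return pd.DataFrame(rows)
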