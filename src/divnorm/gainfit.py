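"""Phenomenological gain models of synaptic summation and their comparison.

The composite model relates the observed multi-square response theta to the
expected linear sum of single-square responses epsilon:

    theta = epsilon - beta * epsilon^2 / (gamma + epsilon) - alpha

whose restrictions are the three named operations:

    SI (subtractive inhibition):   theta = epsilon - alpha        (beta=gamma=0)
    DI (divisive inhibition):      theta = epsilon - beta*epsilon (alpha=gamma=0)
    DN (divisive normalization):   theta = gamma*epsilon/(gamma+epsilon)
                                                                  (alpha=0, beta=1)

Smaller gamma means stronger normalization; DN is concave, bounded by gamma,
and scale-consistent (DN(a*eps; a*gamma) = a * DN(eps; gamma)).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import EOPair, GridSpec, SDNFit, StimPattern

logger = logging.getLogger(__name__)

__all__ = [
    "predict_response",
    "GainModelRegressor",
    "fit_model",
    "compare_models",
    "build_eo_pairs",
    "cross_pulse_ratio",
    "distributedness",
]

MODELS = ("SI", "DI", "DN", "COMPOSITE")
_K_PARAMS = {"SI": 1, "DI": 1, "DN": 1, "COMPOSITE": 3}

# bounds of the bounded least-squares fits; multi-start keeps the 1-d problems
# away from flat tails of the DN objective
GAMMA_BOUNDS = (1e-9, 1e6)
BETA_BOUNDS = (0.0, 2.0)
ALPHA_BOUNDS = (0.0, np.inf)
N_STARTS = 5


def predict_response(model: str, eps, alpha: float = 0.0, beta: float = 0.0,
                     gamma: float = 1.0):
    """Predicted observed response for expected input ``eps`` under a model."""
    eps = np.asarray(eps, dtype=float)
    if model == "SI":
        out = eps - alpha
    elif model == "DI":
        out = eps - beta * eps
    elif model == "DN":
        if gamma <= 0:
            raise ValueError("DN requires gamma > 0")
        out = gamma * eps / (gamma + eps)
    elif model == "COMPOSITE":
        if gamma < 0:
            raise ValueError("composite model requires gamma >= 0")
        denom = gamma + eps
        frac = np.divide(eps ** 2, denom, out=np.zeros_like(eps),
                         where=denom != 0)
        out = eps - beta * frac - alpha
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(out) if out.ndim == 0 else out


class GainModelRegressor(BaseEstimator, RegressorMixin):
    """Least-squares fit of one gain model to observed-vs-expected pairs.

    Parameters
    ----------
    model : {'SI', 'DI', 'DN', 'COMPOSITE'}
        Which restriction of the composite equation to fit. COMPOSITE frees
        all three parameters and is poorly identifiable; it is provided for
        sensitivity analysis only.
    n_starts : int
        Number of multi-start initializations of the bounded solver.
    sigma2 : float or None
        Noise variance used for the reduced chi-square. When None it is
        estimated from the fit residuals (rss / (n - k)), which makes
        red_chisq_ identically 1; supply repeat-based variance to get an
        absolute goodness-of-fit scale.

    Attributes (after fit)
    ----------------------
    alpha_, beta_, gamma_ : fitted / fixed parameter values
    rss_, bic_, red_chisq_, n_ : fit quality summaries,
        BIC = n*ln(rss/n) + k*ln(n) under Gaussian errors.
    """

    def __init__(self, model: str = "DN", n_starts: int = N_STARTS,
                 sigma2: float = None):
        self.model = model
        self.n_starts = n_starts
        self.sigma2 = sigma2

    def fit(self, X, y):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        eps = np.asarray(X, dtype=float).ravel()
        theta = np.asarray(y, dtype=float).ravel()
        if eps.shape != theta.shape:
            raise ValueError("X and y must have the same length")
        if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(theta))):
            raise ValueError("inputs must be finite")
        if np.ptp(eps) == 0:
            raise ValueError("degenerate input: all expected values equal")
        n = eps.size

        if self.model == "SI":
            names, bounds = ["alpha"], ([ALPHA_BOUNDS[0]], [ALPHA_BOUNDS[1]])
            starts = [[max(np.mean(eps - theta), 1e-3)], [1e-3], [1.0],
                      [np.ptp(eps) / 2], [10.0]]
        elif self.model == "DI":
            names, bounds = ["beta"], ([BETA_BOUNDS[0]], [BETA_BOUNDS[1]])
            slope = np.sum(eps * theta) / np.sum(eps ** 2)
            starts = [[float(np.clip(1 - slope, 0, 2))], [0.1], [0.5], [0.9], [1.5]]
        elif self.model == "DN":
            names, bounds = ["gamma"], ([GAMMA_BOUNDS[0]], [GAMMA_BOUNDS[1]])
            med = float(np.median(eps[eps > 0])) if np.any(eps > 0) else 1.0
            starts = [[med], [med / 4], [4 * med], [50 * med], [1e4]]
        else:
            names = ["alpha", "beta", "gamma"]
            med = float(np.median(np.abs(eps))) or 1.0
            bounds = ([ALPHA_BOUNDS[0], BETA_BOUNDS[0], GAMMA_BOUNDS[0]],
                      [1e6, BETA_BOUNDS[1], GAMMA_BOUNDS[1]])
            starts = [[0.0, 0.5, med], [0.1, 1.0, med / 2], [1.0, 0.2, 2 * med],
                      [0.0, 1.0, 10 * med], [0.5, 0.8, med]]

        def resid(p):
            kw = dict(zip(names, p))
            return predict_response(self.model, eps, **{**_FIXED[self.model], **kw}) - theta

        best = None
        for s in starts[: max(1, self.n_starts)]:
            s = np.clip(s, bounds[0], bounds[1])
            try:
                sol = least_squares(resid, s, bounds=bounds, method="trf")
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError(f"{self.model} fit did not converge")

        fitted = dict(zip(names, best.x))
        p = {**_FIXED[self.model], **fitted}
        self.alpha_ = float(p.get("alpha", 0.0))
        self.beta_ = float(p.get("beta", 0.0))
        self.gamma_ = float(p.get("gamma", 0.0))
        self.rss_ = float(2 * best.cost)
        self.n_ = int(n)
        self.k_params_ = _K_PARAMS[self.model]
        self.bic_ = float(n * np.log(max(self.rss_, 1e-300) / n)
                          + self.k_params_ * np.log(n))
        s2 = self.sigma2
        dof = max(n - self.k_params_, 1)
        if s2 is None:
            s2 = self.rss_ / dof
        self.red_chisq_ = float(self.rss_ / (s2 * dof)) if s2 > 0 else np.inf
        return self

    def predict(self, X):
        eps = np.asarray(X, dtype=float).ravel()
        return predict_response(self.model, eps, alpha=self.alpha_,
                                beta=self.beta_, gamma=self.gamma_)

    def to_sdnfit(self) -> SDNFit:
        return SDNFit(model=self.model, alpha=self.alpha_, beta=self.beta_,
                      gamma=self.gamma_, rss=self.rss_, n=self.n_,
                      k_params=self.k_params_, bic=self.bic_,
                      red_chisq=self.red_chisq_)


_FIXED = {
    "SI": {"beta": 0.0, "gamma": 1.0},   # gamma unused when beta = 0
    "DI": {"alpha": 0.0, "gamma": 1.0},
    "DN": {"alpha": 0.0, "beta": 1.0},
    "COMPOSITE": {},
}


def _pairs_xy(pairs):
    if pairs and isinstance(pairs[0], EOPair):
        return (np.array([p.expected for p in pairs]),
                np.array([p.observed for p in pairs]))
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_model(pairs, model: str, sigma2: float = None) -> SDNFit:
    """Fit one gain model to EO pairs; thin wrapper over GainModelRegressor."""
    eps, theta = _pairs_xy(pairs)
    if eps.size < 10:
        raise ValueError("need at least 10 observed/expected pairs")
    reg = GainModelRegressor(model=model, sigma2=sigma2).fit(eps, theta)
    return reg.to_sdnfit()


def compare_models(pairs, models=("DI", "DN"), sigma2: float = None):
    """Fit the requested models and rank them by BIC.

    Returns a dict with per-model SDNFit objects, 'delta_bic'
    (= BIC(DN) - BIC(DI); negative means DN preferred) and 'ranked'
    (model names, best first).
    """
    fits = {m: fit_model(pairs, m, sigma2=sigma2) for m in models}
    out = {"fits": fits,
           "ranked": sorted(fits, key=lambda m: fits[m].bic)}
    if "DI" in fits and "DN" in fits:
        out["delta_bic"] = fits["DN"].bic - fits["DI"].bic
    return out


def build_eo_pairs(feature_table, patterns=None, measure: str = "peak_amp",
                   observed: str = "trial"):
    """Observed/expected pairs from a per-trial feature table.

    The table (a pandas DataFrame) needs columns
    ``cell_id, pattern_id, n_squares, condition, repeat, squares, flagged``
    plus the chosen measure; ``squares`` is a ';'-joined list of grid indices
    (or supply a ``patterns`` mapping pattern_id -> iterable of indices).
    Expected = sum of the constituent single-square stimulus-averaged
    responses; observed = per-trial value (default) or stimulus average.
    Flagged trials are dropped; patterns missing a constituent single-square
    response are skipped with a log entry.
    """
    df = feature_table
    if "flagged" in df.columns:
        df = df[~df["flagged"].astype(bool)]
    if patterns is None:
        patterns = {pid: tuple(int(s) for s in str(sq).split(";") if s != "")
                    for pid, sq in zip(df["pattern_id"], df["squares"])}

    singles = df[df["n_squares"] == 1]
    sq_mean = {}
    for pid, grp in singles.groupby("pattern_id"):
        sq = patterns[pid]
        if len(sq) == 1:
            sq_mean[sq[0]] = grp[measure].mean()

    pairs = []
    multi = df[df["n_squares"] > 1]
    for pid, grp in multi.groupby("pattern_id"):
        sq = patterns[pid]
        missing = [s for s in sq if s not in sq_mean]
        if missing:
            logger.info("pattern %s skipped: no single-square response for %s",
                        pid, missing)
            continue
        expected = float(sum(sq_mean[s] for s in sq))
        if observed == "mean":
            pairs.append(EOPair(expected=expected,
                                observed=float(grp[measure].mean()),
                                n_squares=len(sq), pattern_id=pid))
        else:
            for val in grp[measure]:
                pairs.append(EOPair(expected=expected, observed=float(val),
                                    n_squares=len(sq), pattern_id=pid))
    return pairs


def cross_pulse_ratio(paired_responses):
    """Second- over first-position mean response per photostimulation spot.

    ``paired_responses`` maps spot id -> (first_position_responses,
    second_position_responses). Ratios > 1 indicate facilitation by the
    preceding stimulus; a zero first-position mean is flagged as NaN.
    """
    out = {}
    for spot, (first, second) in paired_responses.items():
        m1 = float(np.mean(first))
        m2 = float(np.mean(second))
        out[spot] = m2 / m1 if m1 != 0 else float("nan")
    return out


def distributedness(pattern, grid: GridSpec = None) -> float:
    """Total spread of a pattern: sum of spot distances from their centroid (um).

    Accepts either (StimPattern, GridSpec) or a raw (n, 2) coordinate array
    in micrometres.
    """
    if isinstance(pattern, StimPattern):
        if grid is None:
            raise ValueError("grid required to resolve pattern coordinates")
        xy = grid.coords_um(pattern.squares)
    else:
        xy = np.atleast_2d(np.asarray(pattern, dtype=float))
    centroid = xy.mean(axis=0)
    return float(np.linalg.norm(xy - centroid, axis=1).sum())
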