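"""Per-neuron regression models, Bayesian model stacking, and selectivity.

Single-neuron selectivity is estimated from z-scored firing rates averaged in
four 400-ms windows (offer and delay, for each of the two offers):

    FR = b0 + b_value * Value + b_space * Space + b_int * (interaction) + N(0, s^2)

with Space effects-coded {-1, +1} and Value min-max normalized to [0, 1].
Five candidate models are fitted per neuron and window: intercept-only
("noise"), value + space with a linear or cubic-spline value term, and the
same two plus a value-by-space interaction. Models are combined by stacking
weights that maximize the leave-one-out log score of the mixture; for
Gaussian OLS the pointwise LOO predictive densities are available in closed
form through the hat matrix, so no importance sampling is needed. WAIC is
reported per model from draws of the asymptotic-normal posterior.

Selectivity of single neurons is also assessed with a permutation ANOVA
(value discretized to 7 levels, side, and their interaction), with p-values
of the form (#(F_perm > F_obs) + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, stats
from scipy.special import logsumexp

from .syndata import (BehavioralSession, NeuralSession, OFFER_WINDOW_MS,
                      DELAY_WINDOW_MS, SOA_MS)

__all__ = [
    "WINDOWS_MS",
    "MODEL_IDS",
    "WindowRates",
    "NeuronFit",
    "compute_window_rates",
    "spline_basis",
    "fit_neuron_models",
    "stack_models",
    "permutation_anova",
]

#: the four analysis windows, ms relative to offer-1 onset
WINDOWS_MS = {
    "offer1": (OFFER_WINDOW_MS[0], OFFER_WINDOW_MS[1]),
    "delay1": (DELAY_WINDOW_MS[0], DELAY_WINDOW_MS[1]),
    "offer2": (SOA_MS + OFFER_WINDOW_MS[0], SOA_MS + OFFER_WINDOW_MS[1]),
    "delay2": (SOA_MS + DELAY_WINDOW_MS[0], SOA_MS + DELAY_WINDOW_MS[1]),
}

MODEL_IDS = ("noise", "linear-lin", "linear-spline", "interaction-lin",
             "interaction-spline")

MIN_TRIALS_PER_NEURON = 300


@dataclass
class WindowRates:
    """Z-scored window-averaged rates: window -> (trials x neurons)."""

    windows: dict
    neuron_ids: np.ndarray
    exclusions: list = field(default_factory=list)


def compute_window_rates(neural: NeuralSession, behavioral: BehavioralSession | None = None,
                         min_trials: int = MIN_TRIALS_PER_NEURON) -> WindowRates:
    """Mean rate per 400-ms window per trial, z-scored per neuron and window.

    Neurons recorded on fewer than ``min_trials`` trials (NaN rates count as
    missing) or with zero variance in any window are excluded and logged.
    """
    exclusions = []
    n_trials, n_neurons, _ = neural.rates.shape
    window_means = {}
    for name, (w0, w1) in WINDOWS_MS.items():
        bins = neural.window_bins(w0, w1)
        if len(bins) == 0:
            raise ValueError(f"no bins tile window {name} [{w0}, {w1})")
        window_means[name] = neural.rates[:, :, bins].mean(axis=2)

    keep = np.ones(n_neurons, dtype=bool)
    for n in range(n_neurons):
        valid = np.all([np.isfinite(window_means[w][:, n]) for w in WINDOWS_MS], axis=0)
        if valid.sum() < min_trials:
            keep[n] = False
            exclusions.append((n, f"only {int(valid.sum())} trials < {min_trials}"))
            continue
        for w in WINDOWS_MS:
            if np.std(window_means[w][valid, n]) == 0:
                keep[n] = False
                exclusions.append((n, f"zero variance in window {w}"))
                break

    ids = np.where(keep)[0]
    out = {}
    for w, m in window_means.items():
        m = m[:, keep]
        mu = np.nanmean(m, axis=0)
        sd = np.nanstd(m, axis=0)
        out[w] = (m - mu) / sd
    return WindowRates(windows=out, neuron_ids=ids, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Candidate models
# ---------------------------------------------------------------------------

def spline_basis(value: np.ndarray, n_interior_knots: int = 3, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis (no intercept column) with interior knots at quantiles."""
    value = np.asarray(value, dtype=float)
    qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
    interior = np.quantile(value, qs)
    lo, hi = value.min(), value.max()
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(knots) - degree - 1
    cols = []
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        cols.append(interpolate.BSpline(knots, c, degree, extrapolate=False)(value))
    B = np.nan_to_num(np.column_stack(cols))
    return B[:, 1:]  # drop one column; the intercept lives in the design


def _design(value: np.ndarray, side: np.ndarray, model_id: str) -> np.ndarray:
    n = len(value)
    one = np.ones(n)
    if model_id == "noise":
        return one[:, None]
    if model_id.endswith("-lin"):
        V = value[:, None]
    else:
        V = spline_basis(value)
    cols = [one[:, None], V, side[:, None]]
    if model_id.startswith("interaction"):
        cols.append(V * side[:, None])
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {model_id}: {X.shape[1]} columns, rank {rank} "
            "(value or side lacks variation)")
    return X


@dataclass
class NeuronFit:
    """OLS fit of one candidate model for one neuron and window."""

    model_id: str
    beta0: float
    beta_value: np.ndarray
    beta_space: float
    beta_interaction: np.ndarray
    residual_sd: float
    loglik_pointwise: np.ndarray
    loo_lpd_pointwise: np.ndarray
    coef: np.ndarray
    coef_se: np.ndarray
    window_id: str | None = None
    n_params: int = 0


def _ols_fit(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = max(n - p, 1)
    s2 = rss / dof
    cov = s2 * np.linalg.inv(XtX)
    # exact LOO via hat-matrix identities
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtX), X)
    hat = np.clip(hat, 0.0, 1.0 - 1e-10)
    loo_resid = resid / (1.0 - hat)
    loo_rss = rss - resid ** 2 / (1.0 - hat)
    loo_s2 = np.maximum(loo_rss / np.maximum(n - 1 - p, 1), 1e-12)
    loo_lpd = stats.norm.logpdf(loo_resid, scale=np.sqrt(loo_s2 * (1.0 + hat)))
    # in-sample pointwise log-likelihood at the ML plug-in
    sigma_ml = np.sqrt(max(rss / n, 1e-12))
    loglik = stats.norm.logpdf(resid, scale=sigma_ml)
    return beta, cov, np.sqrt(s2), loglik, loo_lpd


def fit_neuron_models(y: np.ndarray, value: np.ndarray, side: np.ndarray,
                      window_id: str | None = None) -> dict:
    """Fit all five candidate models to one neuron's window rates.

    ``value`` must lie in [0, 1] (min-max normalized); ``side`` in {-1, +1}.
    Returns a dict model_id -> NeuronFit, each with pointwise in-sample and
    exact-LOO log predictive densities for downstream stacking.
    """
    y = np.asarray(y, dtype=float)
    value = np.asarray(value, dtype=float)
    side = np.asarray(side, dtype=float)
    if value.min() < -1e-9 or value.max() > 1 + 1e-9:
        raise ValueError("value must be min-max normalized to [0, 1]")
    if not np.isin(side, (-1.0, 1.0)).all():
        raise ValueError("side must be effects-coded {-1, +1}")

    fits = {}
    for mid in MODEL_IDS:
        X = _design(value, side, mid)
        beta, cov, res_sd, loglik, loo_lpd = _ols_fit(X, y)
        p = X.shape[1]
        if mid == "noise":
            bv = np.zeros(0); bs = 0.0; bi = np.zeros(0)
        else:
            n_v = (p - 2) if mid.startswith("linear") else (p - 2) // 2
            bv = beta[1:1 + n_v]
            bs = float(beta[1 + n_v])
            bi = beta[2 + n_v:] if mid.startswith("interaction") else np.zeros(0)
        fits[mid] = NeuronFit(
            model_id=mid, beta0=float(beta[0]), beta_value=bv, beta_space=bs,
            beta_interaction=bi, residual_sd=float(res_sd),
            loglik_pointwise=loglik, loo_lpd_pointwise=loo_lpd,
            coef=beta, coef_se=np.sqrt(np.diag(cov)), window_id=window_id,
            n_params=p)
    return fits


# ---------------------------------------------------------------------------
# Stacking and WAIC
# ---------------------------------------------------------------------------

def _waic(X: np.ndarray, y: np.ndarray, beta: np.ndarray, cov_beta: np.ndarray,
          sigma: float, n_draws: int, rng: np.random.Generator) -> float:
    """WAIC from draws of the asymptotic-normal posterior over coefficients."""
    draws = rng.multivariate_normal(beta, cov_beta, size=n_draws)
    mu = draws @ X.T  # (draws, n)
    ll = stats.norm.logpdf(y[None, :], loc=mu, scale=sigma)
    lppd = np.sum(logsumexp(ll, axis=0) - np.log(n_draws))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return float(lppd - p_waic)


@dataclass
class ModelStackWeights:
    weights: dict
    family_weights: dict
    loo_score: float
    waic: dict


def stack_models(fits: dict, n_waic_draws: int = 400, seed: int | None = 0,
                 X_by_model: dict | None = None, y: np.ndarray | None = None) -> ModelStackWeights:
    """Stacking weights maximizing the LOO log score of the mixture.

    Weights are nonnegative and sum to one; they are invariant to adding a
    constant to all pointwise log densities. Family weights pool the linear
    and interaction variants. WAIC is reported per model when the designs and
    response are supplied.
    """
    mids = list(fits)
    lpd = np.column_stack([fits[m].loo_lpd_pointwise for m in mids])  # (n, K)
    n, K = lpd.shape
    row_max = lpd.max(axis=1, keepdims=True)
    lpd = lpd - row_max  # stabilize; the stacking optimum is shift-invariant

    P = np.exp(lpd)  # (n, K), scaled

    def neg_score(w):
        mix = P @ w
        return -np.sum(np.log(mix + 1e-300))

    def grad(w):
        mix = P @ w + 1e-300
        return -(P / mix[:, None]).sum(axis=0)

    # concave maximization over the simplex: single SLSQP solve suffices
    w0 = np.full(K, 1.0 / K)
    res = optimize.minimize(neg_score, w0, jac=grad, method="SLSQP",
                            bounds=[(0.0, 1.0)] * K,
                            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                                          "jac": lambda w: np.ones(K)}],
                            options={"maxiter": 500, "ftol": 1e-12})
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    weights = dict(zip(mids, w))
    best = res

    family = {"noise": 0.0, "linear": 0.0, "interaction": 0.0}
    for m, wi in weights.items():
        family[m.split("-")[0]] += wi

    waic = {}
    if X_by_model is not None and y is not None:
        rng = np.random.default_rng(seed)
        for m in mids:
            X = X_by_model[m]
            beta, cov, res_sd, _, _ = _ols_fit(X, y)
            waic[m] = _waic(X, y, beta, cov, res_sd, n_waic_draws, rng)
    return ModelStackWeights(weights=weights, family_weights=family,
                             loo_score=float(-best.fun + row_max.sum()), waic=waic)


def designs_for(value: np.ndarray, side: np.ndarray) -> dict:
    """Design matrices for all candidate models (for WAIC reporting)."""
    return {m: _design(np.asarray(value, float), np.asarray(side, float), m)
            for m in MODEL_IDS}


# ---------------------------------------------------------------------------
# Permutation ANOVA
# ---------------------------------------------------------------------------

def _anova_projections(value_level: np.ndarray, side: np.ndarray):
    """Thin orthonormal bases for the nested two-way ANOVA model sequence."""
    n = len(value_level)
    levels = np.unique(value_level)
    if len(levels) < 2:
        raise ValueError("value has a single occupied bin; re-bin value")
    V = np.column_stack([(value_level == lv).astype(float) for lv in levels[1:]])
    S = np.asarray(side, float)[:, None]
    VS = V * S
    one = np.ones((n, 1))

    X_full = np.hstack([one, V, S, VS])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("an empty or collinear value bin makes the ANOVA design rank-deficient; re-bin value")
    # type-II style nested comparisons; Q has orthonormal columns so the
    # explained sum of squares is |Q^T Y|^2
    models = {
        "value": (np.hstack([one, S]), np.hstack([one, V, S])),
        "side": (np.hstack([one, V]), np.hstack([one, V, S])),
        "interaction": (np.hstack([one, V, S]), X_full),
    }
    proj = {}
    for term, (Xr, Xf) in models.items():
        Qr = np.linalg.qr(Xr)[0]
        Qf = np.linalg.qr(Xf)[0]
        proj[term] = (Qr, Qf, Xf.shape[1] - Xr.shape[1], n - Xf.shape[1])
    return proj


def _f_stats(Y: np.ndarray, proj: dict) -> dict:
    """F statistics for each term; Y is (trials x units)."""
    tot = np.sum(Y * Y, axis=0)
    out = {}
    for term, (Qr, Qf, df1, df2) in proj.items():
        rss_r = tot - np.sum((Qr.T @ Y) ** 2, axis=0)
        rss_f = tot - np.sum((Qf.T @ Y) ** 2, axis=0)
        out[term] = ((rss_r - rss_f) / df1) / np.maximum(rss_f / df2, 1e-300)
    return out


def discretize_value(value: np.ndarray, n_levels: int = 7) -> np.ndarray:
    """Quantile-bin a continuous value into ``n_levels`` equally filled levels."""
    edges = np.quantile(value, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(edges, value, side="right")


def permutation_anova(rates: np.ndarray, value_level: np.ndarray, side: np.ndarray,
                      n_perm: int = 1000, seed: int | None = None) -> dict:
    """Permutation p-values for value (7 levels), side, and interaction.

    Firing rates are permuted against the joint label set; for each term,
    p = (#(F_perm > F_obs) + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y = np.asarray(rates, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    proj = _anova_projections(np.asarray(value_level), np.asarray(side))
    f_obs = _f_stats(Y, proj)
    rng = np.random.default_rng(seed)
    counts = {term: np.zeros(Y.shape[1]) for term in f_obs}
    for _ in range(n_perm):
        Yp = Y[rng.permutation(Y.shape[0])]
        f_perm = _f_stats(Yp, proj)
        for term in counts:
            counts[term] += f_perm[term] > f_obs[term]
    return {term: (counts[term] + 1.0) / (n_perm + 1.0) for term in counts}
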