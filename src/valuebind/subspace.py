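"""Population value subspaces, noise ceilings, and the behavior link.

A value subspace for one (side, epoch) is the population vector pointing from
the model-predicted response at the lowest value to the response at the
highest value, built from per-neuron interaction-model coefficients:

    v_side(n) = beta_value(n) + side_code * beta_interaction(n),

with side_code in {+1, -1}. Intercept and side main effects cancel in the
subtraction. The subspace correlation is the cosine (unit-vector dot
product) between two such vectors; Pearson correlation is reported alongside.

Because firing-rate noise alone drags the correlation below 1, observed
left-right correlations are compared against a bootstrap noise ceiling: the
distribution of same-side correlations across independent bootstrap refits,
i.e. what the statistic would look like if both sides shared one value code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "value_subspace_vector",
    "subspace_correlation",
    "pearson_correlation",
    "bootstrap_value_vectors",
    "noise_ceiling_test",
    "alignment_index",
    "estimate_min_population_size",
    "behavior_link",
    "SubspaceCorrelationResult",
    "BehaviorLinkResult",
]


def value_subspace_vector(beta_value: np.ndarray, beta_interaction: np.ndarray,
                          side: str) -> np.ndarray:
    """Value vector for one side from interaction-model coefficients.

    ``side`` is "left" (+1) or "right" (-1) under effects coding.
    """
    code = {"left": 1.0, "right": -1.0}[side]
    beta_value = np.asarray(beta_value, dtype=float)
    beta_interaction = np.asarray(beta_interaction, dtype=float)
    if beta_value.shape != beta_interaction.shape:
        raise ValueError("coefficient arrays must align neuron-by-neuron")
    v = beta_value + code * beta_interaction
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite coefficients in value vector")
    return v


def subspace_correlation(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity between two population value vectors."""
    v1 = np.asarray(v1, float).ravel()
    v2 = np.asarray(v2, float).ravel()
    if v1.shape != v2.shape or len(v1) < 2:
        raise ValueError("vectors must have equal length >= 2")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("subspace correlation undefined for a zero vector")
    return float(v1 @ v2 / (n1 * n2))


def pearson_correlation(v1: np.ndarray, v2: np.ndarray) -> float:
    return float(np.corrcoef(np.ravel(v1), np.ravel(v2))[0, 1])


# ---------------------------------------------------------------------------
# Bootstrap refits and the noise ceiling
# ---------------------------------------------------------------------------

def _interaction_betas(X: np.ndarray, Y: np.ndarray):
    """Joint OLS over all neurons: returns (beta_value, beta_interaction) rows."""
    beta = np.linalg.solve(X.T @ X, X.T @ Y)  # (4, N)
    return beta[1], beta[3]


def bootstrap_value_vectors(rates: np.ndarray, value: np.ndarray, side: np.ndarray,
                            n_boot: int, seed: int | None = None,
                            indices: np.ndarray | None = None):
    """Left/right value vectors over bootstrap trial resamples.

    ``rates`` is (trials x neurons); ``value`` in [0, 1]; ``side`` in {-1, +1}.
    Returns (v_left, v_right) of shape (n_boot, neurons) and the resample
    index matrix used (so callers can compute paired per-bootstrap behavior
    statistics on the identical trial sets).
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(rates, float)
    value = np.asarray(value, float)
    side = np.asarray(side, float)
    T = len(value)
    X = np.column_stack([np.ones(T), value, side, value * side])
    if indices is None:
        indices = rng.integers(0, T, size=(n_boot, T))
    v_l = np.empty((n_boot, Y.shape[1]))
    v_r = np.empty((n_boot, Y.shape[1]))
    for b in range(n_boot):
        idx = indices[b]
        bv, bi = _interaction_betas(X[idx], Y[idx])
        v_l[b] = bv + bi
        v_r[b] = bv - bi
    return v_l, v_r, indices


def _cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = np.einsum("bn,bn->b", A, B)
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    return num / den


def _debiased_cosine_rows(A: np.ndarray, B: np.ndarray, trace: float) -> np.ndarray:
    num = np.einsum("bn,bn->b", A, B) - trace
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    return np.clip(num / den, -1.0, 1.0)


@dataclass
class SubspaceCorrelationResult:
    observed: np.ndarray
    ceiling: np.ndarray
    p: float
    observed_mean: float = 0.0
    ceiling_mean: float = 0.0

    def __post_init__(self):
        self.observed_mean = float(np.mean(self.observed))
        self.ceiling_mean = float(np.mean(self.ceiling))


def noise_ceiling_test(rates: np.ndarray, value: np.ndarray, side: np.ndarray,
                       n_boot: int = 1000, seed: int | None = None) -> SubspaceCorrelationResult:
    """Observed left-right correlations vs a same-side bootstrap noise ceiling.

    The observed distribution is the left-vs-right correlation in each of
    ``n_boot`` bootstrap refits. The ceiling pairs the left vectors of the
    first and last n_boot/2 resamples (and likewise right), giving n_boot
    same-code correlations. p is the (add-one corrected) fraction of
    observed >= ceiling draws over all pairs; small p flags genuine subspace
    separation beyond what noise alone produces.
    """
    if n_boot % 2:
        raise ValueError("n_boot must be even (the ceiling splits resamples in halves)")
    v_l, v_r, _ = bootstrap_value_vectors(rates, value, side, n_boot, seed)
    observed = _cosine_rows(v_l, v_r)
    half = n_boot // 2
    # Same-side pairs share the dataset's estimation noise through their
    # common center, which would count as signal and make the ceiling
    # anticonservative; subtracting the bootstrap covariance trace from the
    # cross products removes that shared-noise inflation (the bootstrap
    # spread estimates each side's sampling noise).
    tr_l = float(np.sum(np.var(v_l, axis=0, ddof=1)))
    tr_r = float(np.sum(np.var(v_r, axis=0, ddof=1)))
    ceiling = np.concatenate([
        _debiased_cosine_rows(v_l[:half], v_l[half:], tr_l),
        _debiased_cosine_rows(v_r[:half], v_r[half:], tr_r),
    ])
    ge = observed[:, None] >= ceiling[None, :]
    p = (ge.sum() + 1.0) / (observed.size * ceiling.size + 1.0)
    return SubspaceCorrelationResult(observed=observed, ceiling=ceiling, p=float(p))


def alignment_index(subspace: np.ndarray, data: np.ndarray) -> float:
    """Fraction of data variance captured by a subspace, ceiling-normalized.

    ``subspace`` is (N x k) with orthonormal columns; ``data`` (trials x N).
    The numerator is the variance of the data projected onto the subspace;
    the denominator is the variance captured by the data's own top-k
    principal subspace, so the index lies in [0, 1].
    """
    A = np.asarray(subspace, float)
    if A.ndim == 1:
        A = A[:, None]
    N, k = A.shape
    X = np.asarray(data, float)
    if k > X.shape[1] or N != X.shape[1]:
        raise ValueError("subspace dimension exceeds or mismatches the neuron count")
    if not np.allclose(A.T @ A, np.eye(k), atol=1e-8):
        A, _ = np.linalg.qr(A)
    X = X - X.mean(axis=0)
    C = X.T @ X / max(len(X) - 1, 1)
    total = np.trace(C)
    if total <= 0:
        raise ValueError("data has zero variance")
    captured = np.trace(A.T @ C @ A)
    evals = np.linalg.eigvalsh(C)
    ceiling = evals[::-1][:k].sum()
    return float(captured / ceiling)


def estimate_min_population_size(coefficients: np.ndarray, sizes=None,
                                 n_draws: int = 500, seed: int | None = None,
                                 rel_tol: float = 0.05):
    """Plateau of the coefficient-variance curve over random subpopulations.

    For each candidate size the variance of the coefficient distribution is
    averaged over ``n_draws`` random neuron subsets; the estimate is the first
    size at which the relative change from the previous size drops below
    ``rel_tol``. Returns (size, variance_curve dict).
    """
    coefficients = np.asarray(coefficients, float).ravel()
    sizes = np.arange(5, 56, 5) if sizes is None else np.asarray(sizes)
    if coefficients.size < sizes.max():
        raise ValueError("need at least max(sizes) neurons")
    rng = np.random.default_rng(seed)
    curve = {}
    for s in sizes:
        draws = np.array([np.var(rng.choice(coefficients, size=s, replace=False), ddof=1)
                          for _ in range(n_draws)])
        curve[int(s)] = float(draws.mean())
    vals = np.array([curve[int(s)] for s in sizes])
    for i in range(1, len(sizes)):
        denom = vals[i - 1] if vals[i - 1] != 0 else 1.0
        if abs(vals[i] - vals[i - 1]) / abs(denom) < rel_tol or vals[i - 1] == 0:
            return int(sizes[i]), curve
    import warnings
    warnings.warn("coefficient variance did not plateau within the size grid")
    return int(sizes[-1]), curve


# ---------------------------------------------------------------------------
# Linking subspace separability to behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorLinkResult:
    correlations: np.ndarray
    suboptimal_rates: np.ndarray
    r_empirical: float
    null_mean: float
    null_sd: float
    p: float
    pairs: np.ndarray = field(default=None, repr=False)


def behavior_link(rates: np.ndarray, value: np.ndarray, side: np.ndarray,
                  sv_diff: np.ndarray, chose_lower: np.ndarray,
                  n_boot: int = 500, n_perm: int = 1000,
                  seed: int | None = None, min_neurons: int = 30) -> BehaviorLinkResult:
    """Bootstrap correlation between subspace correlation and suboptimal choice.

    Per bootstrap resample of trials, the left-right subspace correlation and
    the suboptimal-choice rate (fraction of resampled non-tied trials on
    which the lower-SV offer was chosen) are recomputed on the identical
    trial set. ``sv_diff`` is SV1 - SV2 per trial and ``chose_lower`` a
    boolean per trial. The empirical Pearson r across bootstraps is compared
    to a permutation null; p = 1 - Phi((r - mu_null) / sd_null).
    """
    Y = np.asarray(rates, float)
    if Y.shape[1] < min_neurons:
        raise ValueError(f"need >= {min_neurons} simultaneous neurons, got {Y.shape[1]}")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap pairs")
    rng = np.random.default_rng(seed)
    T = len(value)
    indices = rng.integers(0, T, size=(n_boot, T))
    v_l, v_r, _ = bootstrap_value_vectors(Y, value, side, n_boot, indices=indices)
    corr = _cosine_rows(v_l, v_r)

    sv_diff = np.asarray(sv_diff, float)
    chose_lower = np.asarray(chose_lower, bool)
    not_tied = np.abs(sv_diff) > 1e-9
    subopt = np.array([
        chose_lower[idx][not_tied[idx]].mean() if not_tied[idx].any() else np.nan
        for idx in indices
    ])

    ok = np.isfinite(subopt)
    r_emp = float(np.corrcoef(corr[ok], subopt[ok])[0, 1])
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.corrcoef(corr[ok][rng.permutation(ok.sum())], subopt[ok])[0, 1]
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    p = float(1.0 - stats.norm.cdf((r_emp - mu) / sd))
    return BehaviorLinkResult(correlations=corr, suboptimal_rates=subopt,
                              r_empirical=r_emp, null_mean=mu, null_sd=sd, p=p,
                              pairs=np.column_stack([corr, subopt]))
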