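"""Linear-nonlinear geometry: distance decomposition and error-rate theory.

The four (value level x context level) condition centroids are modeled as a
rectangular scaffold (side lengths d_LV for value, d_LA for context) plus
equal-length orthogonal conjunctive perturbations whose pairwise displacement
is d_N. Squared centroid distances are then

    value-differing pairs:    d_LV^2 + d_N^2
    context-differing pairs:  d_LA^2 + d_N^2
    diagonal pairs:           d_LV^2 + d_LA^2 + d_N^2

and the subspace correlation implied by the geometry is
rho = d_LV^2 / (d_LV^2 + d_N^2).

Distances are estimated from data with the cross-validated ("crossnobis")
squared Euclidean estimator, which is unbiased (zero expectation under
identical distributions, possibly negative) because the two mean-difference
vectors in the inner product come from independent trial folds. No noise
whitening is applied.

Closed-form error rates (Phi is the standard normal CDF):

* binding:  P ~= N_S * Phi(-d_S / (2 sigma)) with d_S = sqrt(2) d_N and N_S
  the average number of linearly confusable chimeric stimulus sets, found by
  enumeration (1/4 for two stimuli over the 2x2 grid).
* generalization (CCGP): P ~= Phi(-(1/sigma) * d_LV^2 / (2 sqrt(d_LV^2 +
  d_Ne^2))) with d_Ne^2 = d_N^2 + eps^2, where eps is the standard-error
  distance of the estimated centroids.

Both predictions are validated against brute-force Monte-Carlo decoder
oracles (maximum-likelihood set decoder for binding; prototype decoder for
generalization).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .syndata import PopulationCodeSpec, grid_labels, simulate_population

__all__ = [
    "CONDITIONS",
    "crossnobis_matrix",
    "decompose_distances",
    "estimate_noise_sigma",
    "estimate_sem_distance",
    "predicted_binding_error",
    "binding_error_oracle",
    "predicted_ccgp_error",
    "ccgp_oracle",
    "implied_subspace_correlation",
    "enumerate_confusable_sets",
    "estimate_geometry",
    "GeometryEstimate",
    "ErrorRatePrediction",
]

#: condition order used throughout: (value level, context level)
CONDITIONS = ((1, 1), (1, 2), (2, 1), (2, 2))

_PAIR_KIND = {}
for _a in range(4):
    for _b in range(_a + 1, 4):
        va, ca = CONDITIONS[_a]
        vb, cb = CONDITIONS[_b]
        if va != vb and ca != cb:
            _PAIR_KIND[(_a, _b)] = "diagonal"
        elif va != vb:
            _PAIR_KIND[(_a, _b)] = "value"
        else:
            _PAIR_KIND[(_a, _b)] = "context"


def split_by_condition(data: np.ndarray, labels: np.ndarray) -> dict:
    """Group (trials x neurons) rows by their (value, context) grid label."""
    labels = np.asarray(labels)
    return {c: data[(labels[:, 0] == c[0]) & (labels[:, 1] == c[1])] for c in CONDITIONS}


# ---------------------------------------------------------------------------
# Cross-validated distances
# ---------------------------------------------------------------------------

def crossnobis_matrix(data_by_condition: dict, n_folds: int = 5,
                      seed: int | None = None) -> np.ndarray:
    """Unbiased cross-validated squared Euclidean distances, 4x4.

    Trials of each condition are partitioned into ``n_folds`` folds; for each
    condition pair the estimate averages, over ordered fold pairs (a, b) with
    a != b, the inner product of the fold-a and fold-b mean-difference
    vectors. Entries may be negative; the diagonal is zero.
    """
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    rng = np.random.default_rng(seed)
    folds = {}
    for c in CONDITIONS:
        if c not in data_by_condition:
            raise ValueError(f"missing condition {c}")
        X = np.asarray(data_by_condition[c], float)
        if len(X) < n_folds:
            raise ValueError(f"condition {c} has {len(X)} trials < {n_folds} folds")
        perm = rng.permutation(len(X))
        folds[c] = [X[ix] for ix in np.array_split(perm, n_folds)]

    D = np.zeros((4, 4))
    for (i, j), _kind in _PAIR_KIND.items():
        ci, cj = CONDITIONS[i], CONDITIONS[j]
        means_i = np.stack([f.mean(axis=0) for f in folds[ci]])
        means_j = np.stack([f.mean(axis=0) for f in folds[cj]])
        diffs = means_i - means_j  # (n_folds, N)
        G = diffs @ diffs.T
        off = G[~np.eye(n_folds, dtype=bool)]
        D[i, j] = D[j, i] = off.mean()
    return D


def decompose_distances(D: np.ndarray, n_starts: int = 10,
                        seed: int | None = 0):
    """Nonnegative least-squares fit of (d_LV, d_LA, d_N) to a 4x4 estimate.

    Minimizes the squared reconstruction error between the six off-diagonal
    squared-distance estimates and the model entries; multistart with a
    stability report (max spread of converged solutions).
    """
    D = np.asarray(D, float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    pairs = list(_PAIR_KIND.items())
    target = np.array([D[i, j] for (i, j), _ in pairs])
    kind = [k for _, k in pairs]

    def model(theta):
        a, b, c = theta ** 2  # d_LV^2, d_LA^2, d_N^2
        return np.array([
            {"value": a + c, "context": b + c, "diagonal": a + b + c}[k] for k in kind
        ])

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(np.abs(target).max(), 1e-12))
    sols, costs = [], []
    # the model is linear in the squared distances, so a nonnegative linear
    # solve gives the exact optimum; the multistart confirms stability
    A = np.zeros((len(kind), 3))
    for r, k in enumerate(kind):
        A[r] = {"value": (1, 0, 1), "context": (0, 1, 1),
                "diagonal": (1, 1, 1)}[k]
    sq, _ = optimize.nnls(A, target)
    sols.append(np.sqrt(sq))
    costs.append(0.5 * np.sum((A @ sq - target) ** 2))
    for s in range(n_starts):
        x0 = scale * (0.2 + rng.random(3))
        res = optimize.least_squares(lambda th: model(th) - target, x0,
                                     bounds=(0.0, np.inf))
        sols.append(np.abs(res.x))
        costs.append(res.cost)
    best = np.argmin(costs)
    sols = np.array(sols)
    good = sols[np.array(costs) <= costs[best] * (1 + 1e-6) + 1e-12]
    stability = float(np.ptp(good, axis=0).max()) if len(good) > 1 else 0.0
    d_lv, d_la, d_n = sols[best]
    return (float(d_lv), float(d_la), float(d_n)), {
        "residual": float(np.sqrt(2 * costs[best])), "stability": stability}


def estimate_noise_sigma(data_by_condition: dict, decoder_axis: np.ndarray) -> float:
    """Noise SD of within-condition residuals projected on the unit decoder axis."""
    axis = np.asarray(decoder_axis, float).ravel()
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("decoder axis has zero norm")
    axis = axis / norm
    sq = []
    for c, X in data_by_condition.items():
        X = np.asarray(X, float)
        if len(X) < 2:
            raise ValueError(f"condition {c} has a single trial; noise undefined")
        resid = X - X.mean(axis=0)
        sq.append((resid @ axis) ** 2)
    return float(np.sqrt(np.concatenate(sq).mean()))


def estimate_sem_distance(data_by_condition: dict) -> float:
    """Standard-error distance eps of the estimated condition centroids.

    Per condition, the squared SEM distance is sum_n var_n / n_trials (the
    expected squared norm of the centroid error); eps is the RMS across
    conditions. Scales as sigma * sqrt(N / n) for isotropic noise.
    """
    eps2 = []
    for c, X in data_by_condition.items():
        X = np.asarray(X, float)
        if len(X) < 2:
            raise ValueError(f"condition {c} needs >= 2 trials")
        eps2.append(np.sum(X.var(axis=0, ddof=1)) / len(X))
    return float(np.sqrt(np.mean(eps2)))


# ---------------------------------------------------------------------------
# Enumeration of confusable stimulus sets
# ---------------------------------------------------------------------------

def _grid(n_features: int, n_levels: int):
    return list(itertools.product(range(1, n_levels + 1), repeat=n_features))


def _zsum(stims) -> tuple:
    """Summed centered linear code of a stimulus multiset (exact rationals x2)."""
    k = len(stims[0])
    tot = [0] * k
    for s in stims:
        for i, lv in enumerate(s):
            tot[i] += 2 * lv  # x2 keeps arithmetic integral for +-1/2 coding
    return tuple(tot)


def enumerate_confusable_sets(n_features: int = 2, n_levels: int = 2,
                              n_stimuli: int = 2):
    """Enumerate linearly confusable chimeric sets; returns (N_S, table).

    Stimulus sets are ordered tuples of ``n_stimuli`` stimuli over the full
    feature grid. For each ordered set X, the confusable sets C_X are the
    *multisets* S different from X's multiset whose summed linear (centered)
    code is identical — i.e. sets a purely linear code cannot distinguish
    from X. N_S is the average |C_X| over all ordered sets.
    """
    grid = _grid(n_features, n_levels)
    ordered = list(itertools.product(grid, repeat=n_stimuli))
    by_sum = {}
    multisets = set()
    for stims in itertools.combinations_with_replacement(grid, n_stimuli):
        key = tuple(sorted(stims))
        multisets.add(key)
        by_sum.setdefault(_zsum(stims), set()).add(key)
    table = {}
    sizes = []
    for X in ordered:
        mkey = tuple(sorted(X))
        conf = by_sum[_zsum(X)] - {mkey}
        table[X] = sorted(conf)
        sizes.append(len(conf))
    return float(np.mean(sizes)), table


# ---------------------------------------------------------------------------
# Closed-form error rates
# ---------------------------------------------------------------------------

def predicted_binding_error(d_n: float, sigma: float,
                            n_features: int = 2, n_levels: int = 2,
                            n_stimuli: int = 2) -> float:
    """Union-bound misbinding rate N_S * Phi(-d_S / (2 sigma)), d_S = sqrt(2) d_N."""
    if d_n < 0 or sigma < 0:
        raise ValueError("d_n and sigma must be nonnegative")
    n_s, _ = enumerate_confusable_sets(n_features, n_levels, n_stimuli)
    if sigma == 0:
        return 0.0 if d_n > 0 else n_s / 2.0
    d_s = np.sqrt(2.0) * d_n
    return float(n_s * stats.norm.cdf(-d_s / (2.0 * sigma)))


def predicted_ccgp_error(d_lv: float, d_n: float, sigma: float,
                         epsilon: float = 0.0) -> float:
    """Generalization (CCGP) error of a prototype decoder across contexts."""
    if min(d_lv, d_n, sigma, epsilon) < 0:
        raise ValueError("inputs must be nonnegative")
    if sigma == 0:
        return 0.0 if d_lv > 0 else 0.5
    d_ne2 = d_n ** 2 + epsilon ** 2
    if d_lv == 0 and d_ne2 == 0:
        return 0.5
    arg = 0.5 * d_lv ** 2 / np.sqrt(d_lv ** 2 + d_ne2)
    return float(stats.norm.cdf(-arg / sigma))


def implied_subspace_correlation(d_lv: float, d_n: float) -> float:
    """rho = d_LV^2 / (d_LV^2 + d_N^2)."""
    if d_lv == 0 and d_n == 0:
        raise ValueError("subspace correlation undefined when both distances are zero")
    return float(d_lv ** 2 / (d_lv ** 2 + d_n ** 2))


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------

def _set_centroids(spec: PopulationCodeSpec, multisets) -> np.ndarray:
    """Summed population response of each stimulus multiset, (n_sets x N)."""
    cents = spec.centroids()
    idx = {c: k for k, c in enumerate(CONDITIONS)}
    return np.stack([cents[idx[a]] + cents[idx[b]] for a, b in multisets])


def binding_error_oracle(spec: PopulationCodeSpec, n_mc: int = 100_000,
                         seed: int | None = None):
    """Monte-Carlo misbinding rate of a maximum-likelihood set decoder.

    Presents each ordered two-stimulus set equally often; the decoder picks
    the candidate multiset whose summed centroid is nearest to the noisy
    summed response (ties broken uniformly at random). An error is counted
    when the decoded multiset is a linearly confusable chimeric set of the
    presented one. Returns (rate, standard error).
    """
    if n_mc < 1000:
        import warnings
        warnings.warn("n_mc < 1000 gives a large Monte-Carlo standard error")
    _, table = enumerate_confusable_sets()
    ordered = list(table)
    multisets = sorted({tuple(sorted(X)) for X in ordered})
    ms_index = {m: i for i, m in enumerate(multisets)}
    cand = _set_centroids(spec, multisets)  # (10, N)
    rng = np.random.default_rng(seed)

    per = np.full(len(ordered), n_mc // len(ordered))
    per[: n_mc % len(ordered)] += 1
    errors = 0
    total = 0
    for X, n_x in zip(ordered, per):
        if n_x == 0:
            continue
        conf = {ms_index[s] for s in table[X]}
        true_sum = _set_centroids(spec, [tuple(sorted(X))])[0]
        # the population response to the set carries one noise draw of SD sigma
        r = true_sum + rng.normal(0.0, spec.sigma, size=(n_x, spec.n_neurons))
        d2 = ((r[:, None, :] - cand[None, :, :]) ** 2).sum(axis=2)
        jitter = rng.random(d2.shape) * 1e-9  # uniform tie-break
        decoded = (d2 + jitter).argmin(axis=1)
        if conf:
            errors += np.isin(decoded, list(conf)).sum()
        total += n_x
    rate = errors / total
    se = np.sqrt(max(rate * (1 - rate), 1e-12) / total)
    return float(rate), float(se)


def ccgp_oracle(spec: PopulationCodeSpec, n_mc: int = 50_000,
                seed: int | None = None, n_train: int | None = None):
    """Monte-Carlo CCGP error of a prototype decoder across contexts.

    Trains on the x11 vs x21 value contrast (context level 1) and tests on
    noisy draws from x12 and x22 (context level 2). With ``n_train`` set, the
    class centroids are estimated from that many noisy training trials per
    condition (centroid error enters like the standard-error distance eps);
    otherwise the true centroids are used (eps = 0). Returns (rate, SE).
    """
    rng = np.random.default_rng(seed)
    cents = spec.centroids()
    idx = {c: k for k, c in enumerate(CONDITIONS)}
    c11, c21 = cents[idx[(1, 1)]], cents[idx[(2, 1)]]
    if n_train is not None:
        c11 = c11 + rng.normal(0.0, spec.sigma / np.sqrt(n_train), spec.n_neurons)
        c21 = c21 + rng.normal(0.0, spec.sigma / np.sqrt(n_train), spec.n_neurons)
    w = c21 - c11
    b = w @ (c11 + c21) / 2.0  # boundary at the midpoint between prototypes
    n_half = n_mc // 2
    errors = 0
    for cond, is_high in (((1, 2), False), ((2, 2), True)):
        mu = cents[idx[cond]]
        r = mu + rng.normal(0.0, spec.sigma, size=(n_half, spec.n_neurons))
        pred_high = (r @ w - b) > 0
        errors += int(np.sum(pred_high != is_high))
    total = 2 * n_half
    rate = errors / total
    se = np.sqrt(max(rate * (1 - rate), 1e-12) / total)
    return float(rate), float(se)


# ---------------------------------------------------------------------------
# End-to-end geometry estimation
# ---------------------------------------------------------------------------

@dataclass
class GeometryEstimate:
    d_lv: float
    d_la: float
    d_n: float
    sigma: float
    epsilon: float
    rho: float
    residual: float
    distance_matrix: np.ndarray = field(repr=False, default=None)


@dataclass
class ErrorRatePrediction:
    binding_error: float
    ccgp_error: float
    binding_oracle: tuple | None = None
    ccgp_oracle: tuple | None = None


def estimate_geometry(data: np.ndarray, labels: np.ndarray, n_folds: int = 5,
                      seed: int | None = None) -> GeometryEstimate:
    """Crossnobis -> decomposition -> noise/SEM estimates from labeled trials."""
    by_cond = split_by_condition(np.asarray(data, float), labels)
    D = crossnobis_matrix(by_cond, n_folds=n_folds, seed=seed)
    (d_lv, d_la, d_n), info = decompose_distances(D)
    axis = by_cond[(2, 1)].mean(axis=0) - by_cond[(1, 1)].mean(axis=0)
    sigma = estimate_noise_sigma(by_cond, axis)
    eps = estimate_sem_distance(by_cond)
    rho = implied_subspace_correlation(d_lv, d_n) if (d_lv or d_n) else np.nan
    return GeometryEstimate(d_lv=d_lv, d_la=d_la, d_n=d_n, sigma=sigma,
                            epsilon=eps, rho=rho, residual=info["residual"],
                            distance_matrix=D)


def predict_error_rates(est: GeometryEstimate) -> ErrorRatePrediction:
    return ErrorRatePrediction(
        binding_error=predicted_binding_error(est.d_n, est.sigma),
        ccgp_error=predicted_ccgp_error(est.d_lv, est.d_n, est.sigma, est.epsilon),
    )
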