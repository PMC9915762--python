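"""Subjective-value choice models for the risky choice task.

Four nested models of an offer's subjective value SV = w(p) * u(s):

=============  =================  ==========================================
model_id       utility u(s)       probability weight w(p)
=============  =================  ==========================================
obj-obj        s                  p
obj-prelec     s                  exp(-beta * (-ln p) ** gamma)
pow-obj        s ** alpha         p
pow-prelec     s ** alpha         exp(-beta * (-ln p) ** gamma)
=============  =================  ==========================================

Choices follow a softmax over the relative subjective value,
P(choose offer 1) = logistic((SV1 - SV2) / tau). Models are fitted by
penalized maximum likelihood (weak lognormal priors on all positive
parameters) with seeded multistart, and compared by a Laplace approximation
to the log evidence. The two-parameter Prelec function nests the
one-parameter version at beta = 1 and has the fixed point w(1/e) = 1/e there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .syndata import BehavioralSession

__all__ = [
    "MODEL_IDS",
    "SubjectiveValueParams",
    "BehaviorFitResult",
    "subjective_value",
    "filter_trials",
    "fit_choice_model",
    "suboptimal_choice_rate",
]

MODEL_IDS = ("obj-obj", "obj-prelec", "pow-obj", "pow-prelec")

#: free parameters per model (tau is always free)
_FREE = {
    "obj-obj": ("tau",),
    "obj-prelec": ("gamma", "beta", "tau"),
    "pow-obj": ("alpha", "tau"),
    "pow-prelec": ("alpha", "gamma", "beta", "tau"),
}

_BOUNDS = {"alpha": (0.05, 5.0), "gamma": (0.05, 5.0), "beta": (0.05, 5.0),
           "tau": (1e-4, 10.0)}

#: lognormal prior log-SD; wide enough to be weakly informative
_PRIOR_SD = 1.0


@dataclass
class SubjectiveValueParams:
    """Parameters of one subjective-value model; fixed ones sit at identity."""

    alpha: float = 1.0
    gamma: float = 1.0
    beta: float = 1.0
    tau: float = 0.03
    model_id: str = "pow-prelec"

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in ("alpha", "gamma", "beta", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _prelec(p: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = np.exp(-beta * (-np.log(p[pos])) ** gamma)
    return out


def subjective_value(p, stakes, params: SubjectiveValueParams):
    """SV = w(p) * u(s); monotone increasing in both p and s."""
    p = np.asarray(p, dtype=float)
    stakes = np.asarray(stakes, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if params.model_id in ("obj-prelec", "pow-prelec"):
        w = _prelec(p, params.gamma, params.beta)
    else:
        w = p
    if params.model_id in ("pow-obj", "pow-prelec"):
        u = stakes ** params.alpha
    else:
        u = stakes
    return w * u


def filter_trials(session: BehavioralSession):
    """Drop inattentive (> 7 s) trials and trials containing a safe offer.

    Returns (filtered session, removal log dict).
    """
    t = session.trials
    if "duration_s" not in t.columns:
        raise ValueError("durations missing from session")
    slow = t["duration_s"] > 7.0
    safe = (t["kind1"] == "safe") | (t["kind2"] == "safe")
    keep = ~(slow | safe)
    log = {"n_input": len(t), "n_slow": int(slow.sum()),
           "n_safe": int((safe & ~slow).sum()), "n_kept": int(keep.sum())}
    if log["n_kept"] == 0:
        raise RuntimeError(f"all trials removed by filters: {log}")
    out = replace(session, trials=t.loc[keep].reset_index(drop=True))
    return out, log


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _nll(theta: np.ndarray, names, p1, s1, p2, s2, choice) -> float:
    params = SubjectiveValueParams(model_id=_model_for(names), **dict(zip(names, theta)))
    sv1 = subjective_value(p1, s1, params)
    sv2 = subjective_value(p2, s2, params)
    z = (sv1 - sv2) / params.tau
    # log P(observed choice): choice==0 picks offer 1
    logp = -np.logaddexp(0.0, -z)
    logq = -np.logaddexp(0.0, z)
    ll = np.where(choice == 0, logp, logq).sum()
    # lognormal prior centered at identity values
    pen = 0.5 * np.sum((np.log(theta) - np.log(_prior_center(names))) ** 2) / _PRIOR_SD ** 2
    return -(ll) + pen


def _model_for(names) -> str:
    for mid, free in _FREE.items():
        if tuple(names) == free:
            return mid
    raise KeyError(names)


def _prior_center(names) -> np.ndarray:
    centers = {"alpha": 1.0, "gamma": 1.0, "beta": 1.0, "tau": 0.2}
    return np.array([centers[n] for n in names])


def _hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            f = (fun(x + ei + ej) - fun(x + ei - ej)
                 - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = f
    return H


@dataclass
class ModelFit:
    model_id: str
    params: SubjectiveValueParams
    log_evidence: float
    nll: float
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    identifiable: bool = True


@dataclass
class BehaviorFitResult:
    fits: dict
    selected: str
    sv1: np.ndarray
    sv2: np.ndarray
    accuracy: float

    @property
    def params(self) -> SubjectiveValueParams:
        return self.fits[self.selected].params


def fit_choice_model(session: BehavioralSession, seed: int | None = None,
                     n_starts: int = 10) -> BehaviorFitResult:
    """Fit all four models, select by Laplace log evidence.

    Each model is optimized in log-parameter space from ``n_starts`` seeded
    starting points; the log evidence is the penalized log likelihood at the
    optimum plus the Laplace volume term. Wald 95% intervals come from the
    inverse Hessian.
    """
    t = session.trials
    choice = t["choice"].to_numpy()
    if len(np.unique(choice)) < 2:
        raise ValueError("need both choices present to fit")
    p1, s1 = t["p1"].to_numpy(), t["stakes1"].to_numpy()
    p2, s2 = t["p2"].to_numpy(), t["stakes2"].to_numpy()
    rng = np.random.default_rng(seed)

    fits = {}
    for mid in MODEL_IDS:
        names = _FREE[mid]
        k = len(names)
        lb = np.log([_BOUNDS[n][0] for n in names])
        ub = np.log([_BOUNDS[n][1] for n in names])

        def obj(logtheta):
            return _nll(np.exp(logtheta), names, p1, s1, p2, s2, choice)

        best = None
        for s in range(n_starts):
            x0 = np.log(_prior_center(names)) + 0.5 * rng.standard_normal(k)
            x0 = np.clip(x0, lb, ub)
            res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                    bounds=list(zip(lb, ub)))
            if best is None or res.fun < best.fun:
                best = res
        theta = np.exp(best.x)
        H = _hessian(obj, best.x)
        sign, logdet = np.linalg.slogdet(H)
        identifiable = sign > 0 and np.isfinite(logdet)
        if identifiable:
            log_evidence = -best.fun + 0.5 * k * np.log(2 * np.pi) - 0.5 * logdet
            cov = np.linalg.inv(H)
            se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        else:
            log_evidence = -np.inf
            se_log = np.full(k, np.nan)
        params = SubjectiveValueParams(model_id=mid, **dict(zip(names, theta)))
        se = dict(zip(names, theta * se_log))  # delta method on exp
        ci95 = {n: (float(np.exp(np.log(th) - 1.96 * sl)),
                    float(np.exp(np.log(th) + 1.96 * sl)))
                for n, th, sl in zip(names, theta, se_log)}
        fits[mid] = ModelFit(mid, params, float(log_evidence), float(best.fun),
                             se, ci95, identifiable)

    candidates = {m: f for m, f in fits.items() if f.identifiable}
    if not candidates:
        raise RuntimeError("no model produced an identifiable fit")
    selected = max(candidates, key=lambda m: candidates[m].log_evidence)

    best_params = fits[selected].params
    sv1 = subjective_value(p1, s1, best_params)
    sv2 = subjective_value(p2, s2, best_params)
    predicted = (sv2 > sv1).astype(int)
    ties = np.abs(sv1 - sv2) < 1e-12
    accuracy = float(np.mean(predicted[~ties] == choice[~ties])) if (~ties).any() else np.nan
    return BehaviorFitResult(fits=fits, selected=selected, sv1=sv1, sv2=sv2,
                             accuracy=accuracy)


def suboptimal_choice_rate(session: BehavioralSession, sv1=None, sv2=None,
                           tie_tol: float = 1e-9) -> float:
    """Fraction of non-tied trials where the chosen offer has the lower SV."""
    t = session.trials
    sv1 = t["sv1"].to_numpy() if sv1 is None else np.asarray(sv1)
    sv2 = t["sv2"].to_numpy() if sv2 is None else np.asarray(sv2)
    choice = t["choice"].to_numpy()
    diff = sv1 - sv2
    not_tied = np.abs(diff) > tie_tol
    if not not_tied.any():
        raise ValueError("all trials are subjective-value ties; rate undefined")
    chose_lower = np.where(choice == 0, diff < 0, diff > 0)
    return float(np.mean(chose_lower[not_tied]))
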