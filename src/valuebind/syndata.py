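"""Synthetic risky-choice sessions and linear-nonlinear neural populations.

This module generates the two kinds of data the analysis pipeline consumes:

1. Behavioral sessions from a two-offer risky choice task. On each trial two
   gamble offers appear in sequence on opposite sides of a display, one second
   apart. Each offer is a (probability, stakes) pair: probabilities are uniform
   on a 1% grid, stakes are one of three juice volumes (safe 0.125 mL, medium
   0.165 mL, large 0.240 mL), and offer kinds are drawn at 43.75% / 43.75% /
   12.5% (medium / large / safe). Choices can be filled in by a softmax over
   subjective values (see :mod:`valuebind.behavior`).

2. Neural populations following a linear-nonlinear code

       r(x) = L x_z + M f_N(x) + eps,    eps ~ N(0, sigma^2 I)

   over the 2x2 stimulus grid of (value level, context level), where the
   context is the spatial side (or offer epoch). L has orthogonal columns of
   lengths d_LV (value) and d_LA (context); M has four mutually orthogonal
   columns of equal length m = d_N / sqrt(2), orthogonal to L, carrying the
   conjunctive (one-hot) part of the code. Stimulus levels are coded +-1/2 so
   the centroid displacement between the two levels of a feature equals the
   corresponding column length exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "STAKES_ML",
    "OFFER_KIND_PROBS",
    "SOA_MS",
    "TaskParams",
    "BehavioralSession",
    "PopulationCodeSpec",
    "NeuralSession",
    "generate_task_session",
    "simulate_choices",
    "simulate_population",
    "grid_labels",
    "simulate_session_rates",
]

#: Juice volume (mL) per offer kind.
STAKES_ML = {"safe": 0.125, "medium": 0.165, "large": 0.240}

#: Sampling probability per offer kind.
OFFER_KIND_PROBS = {"medium": 0.4375, "large": 0.4375, "safe": 0.125}

#: Stimulus onset asynchrony between the two offers (ms).
SOA_MS = 1000.0

#: Default analysis windows (ms, relative to each offer's onset).
OFFER_WINDOW_MS = (0.0, 400.0)
DELAY_WINDOW_MS = (450.0, 850.0)

BIN_WIDTH_MS = 20.0


@dataclass
class TaskParams:
    """Configuration of the task generator.

    ``slow_trial_rate`` sets the fraction of trials whose total duration
    exceeds the inattentive cutoff; durations are lognormal with the stated
    median and a tail width solved from that rate.
    """

    kind_probs: dict = field(default_factory=lambda: dict(OFFER_KIND_PROBS))
    prob_resolution: float = 0.01
    duration_median_s: float = 3.5
    slow_trial_rate: float = 0.01
    inattentive_cutoff_s: float = 7.0

    def validate(self) -> None:
        total = sum(self.kind_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.kind_probs.values()):
            raise ValueError(f"offer-kind probabilities must be nonnegative and sum to 1, got {self.kind_probs}")
        if not 0 < self.prob_resolution <= 1:
            raise ValueError("prob_resolution must be in (0, 1]")
        if not 0 <= self.slow_trial_rate < 1:
            raise ValueError("slow_trial_rate must be in [0, 1)")

    def duration_sigma(self) -> float:
        """Lognormal log-SD putting ``slow_trial_rate`` mass above the cutoff."""
        if self.slow_trial_rate == 0:
            return 0.0
        z = stats.norm.ppf(1.0 - self.slow_trial_rate)
        return float(np.log(self.inattentive_cutoff_s / self.duration_median_s) / z)


@dataclass
class BehavioralSession:
    """One session of trials, stored as a tidy DataFrame (one row per trial).

    Columns: ``p1, stakes1, kind1, side1, p2, stakes2, kind2, side2, order,
    duration_s, t_offer1_ms, t_offer2_ms, t_choice_ms, choice, reward_ml``.
    ``choice`` is 0 (offer 1) or 1 (offer 2); -1 when not yet simulated.
    """

    trials: pd.DataFrame
    subject_id: str = "synthetic"
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def copy(self) -> "BehavioralSession":
        return replace(self, trials=self.trials.copy())


def generate_task_session(n_trials: int, params: TaskParams | None = None,
                          seed: int | None = None,
                          subject_id: str = "synthetic") -> BehavioralSession:
    """Generate offers, sides, order and durations for ``n_trials`` trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or TaskParams()
    params.validate()
    rng = np.random.default_rng(seed)

    kinds = list(params.kind_probs)
    kind_p = np.array([params.kind_probs[k] for k in kinds])
    n_grid = int(round(1.0 / params.prob_resolution))

    def draw_offers(n):
        kind = rng.choice(kinds, size=n, p=kind_p)
        prob = rng.integers(0, n_grid + 1, size=n) / n_grid
        # safe offers are guaranteed payouts
        prob = np.where(kind == "safe", 1.0, prob)
        stakes = np.array([STAKES_ML[k] for k in kind])
        return prob, stakes, kind

    p1, s1, k1 = draw_offers(n_trials)
    p2, s2, k2 = draw_offers(n_trials)
    side1 = np.where(rng.random(n_trials) < 0.5, "L", "R")
    side2 = np.where(side1 == "L", "R", "L")
    order = np.where(side1 == "L", "left_first", "right_first")

    sigma = params.duration_sigma()
    durations = params.duration_median_s * np.exp(sigma * rng.standard_normal(n_trials))

    trials = pd.DataFrame({
        "p1": p1, "stakes1": s1, "kind1": k1, "side1": side1,
        "p2": p2, "stakes2": s2, "kind2": k2, "side2": side2,
        "order": order,
        "duration_s": durations,
        "t_offer1_ms": 0.0,
        "t_offer2_ms": SOA_MS,
        "t_choice_ms": durations * 1000.0,
        "choice": -1,
        "reward_ml": np.nan,
    })
    return BehavioralSession(trials=trials, subject_id=subject_id, seed=seed)


def simulate_choices(session: BehavioralSession, sv_params, seed: int | None = None) -> BehavioralSession:
    """Fill in softmax choices: P(choose offer 1) = logistic((SV1 - SV2) / tau)."""
    from .behavior import subjective_value  # local import avoids a cycle

    if sv_params.tau <= 0:
        raise ValueError("softmax temperature tau must be > 0")
    rng = np.random.default_rng(seed)
    out = session.copy()
    t = out.trials
    sv1 = subjective_value(t["p1"].to_numpy(), t["stakes1"].to_numpy(), sv_params)
    sv2 = subjective_value(t["p2"].to_numpy(), t["stakes2"].to_numpy(), sv_params)
    p_choose_1 = special.expit((sv1 - sv2) / sv_params.tau)
    choice = (rng.random(len(t)) >= p_choose_1).astype(int)  # 0 = offer1, 1 = offer2
    chosen_p = np.where(choice == 0, t["p1"], t["p2"])
    chosen_s = np.where(choice == 0, t["stakes1"], t["stakes2"])
    win = rng.random(len(t)) < chosen_p
    t["choice"] = choice
    t["reward_ml"] = np.where(win, chosen_s, 0.0)
    t["sv1"] = sv1
    t["sv2"] = sv2
    return out


# ---------------------------------------------------------------------------
# Linear-nonlinear population code
# ---------------------------------------------------------------------------

@dataclass
class PopulationCodeSpec:
    """Generative linear-nonlinear code over the 2x2 (value, context) grid.

    ``L`` (N x 2) carries the factorized part; its columns are orthogonal with
    norms d_LV and d_LA. ``M`` (N x 4) carries the conjunctive part; its
    columns are mutually orthogonal, orthogonal to L, and all have norm
    m = d_N / sqrt(2), so the nonlinear displacement between any two
    conditions is exactly d_N.
    """

    n_neurons: int
    d_lv: float
    d_la: float
    d_n: float
    sigma: float
    L: np.ndarray
    M: np.ndarray
    seed: int | None = None

    @classmethod
    def create(cls, n_neurons: int, d_lv: float, d_la: float, d_n: float,
               sigma: float, seed: int | None = None) -> "PopulationCodeSpec":
        """Build L and M by orthonormalizing seeded Gaussian vectors."""
        if n_neurons < 6:
            raise ValueError("need at least 6 neurons to hold 6 orthogonal columns")
        if min(d_lv, d_la, d_n, sigma) < 0:
            raise ValueError("distances and sigma must be nonnegative")
        rng = np.random.default_rng(seed)
        basis, _ = np.linalg.qr(rng.standard_normal((n_neurons, 6)))
        L = basis[:, :2] * np.array([d_lv, d_la])
        M = basis[:, 2:] * (d_n / np.sqrt(2.0))
        return cls(n_neurons, d_lv, d_la, d_n, sigma, L, M, seed)

    def centroids(self) -> np.ndarray:
        """Condition means, shape (4, N), ordered (1,1), (1,2), (2,1), (2,2).

        The first index is the value level, the second the context level.
        """
        out = np.empty((4, self.n_neurons))
        for k, (i, j) in enumerate(itertools.product((1, 2), (1, 2))):
            xz = np.array([i - 1.5, j - 1.5])
            f = np.zeros(4)
            f[k] = 1.0
            out[k] = self.L @ xz + self.M @ f
        return out

    def condition_index(self, value_level: np.ndarray, context_level: np.ndarray) -> np.ndarray:
        return (np.asarray(value_level) - 1) * 2 + (np.asarray(context_level) - 1)


def grid_labels(n_repeats: int) -> np.ndarray:
    """Balanced per-trial labels over the 2x2 grid, shape (4*n_repeats, 2)."""
    base = np.array(list(itertools.product((1, 2), (1, 2))))
    return np.tile(base, (n_repeats, 1))


def simulate_population(spec: PopulationCodeSpec, labels: np.ndarray,
                        seed: int | None = None) -> np.ndarray:
    """Single-trial responses (trials x neurons) for per-trial grid labels.

    ``labels`` is (n_trials, 2) with entries in {1, 2}: (value level, context
    level). Each response is the condition centroid plus isotropic Gaussian
    noise of SD sigma.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] != 2 or not np.isin(labels, (1, 2)).all():
        raise ValueError("labels must be (n_trials, 2) with entries in {1, 2}")
    rng = np.random.default_rng(seed)
    idx = spec.condition_index(labels[:, 0], labels[:, 1])
    resp = spec.centroids()[idx]
    if spec.sigma > 0:
        resp = resp + rng.normal(0.0, spec.sigma, size=resp.shape)
    return resp


# ---------------------------------------------------------------------------
# Binned neural sessions
# ---------------------------------------------------------------------------

@dataclass
class NeuralSession:
    """Binned firing rates (trials x neurons x bins) with explicit bin times.

    ``bin_starts_ms`` gives each 20-ms bin's start relative to offer-1 onset;
    bins are aligned to the analysis windows they tile (offer windows start at
    the offer onset, delay windows 450 ms later), so a window mean is an exact
    mean over its 20 bins.
    """

    rates: np.ndarray
    bin_starts_ms: np.ndarray
    labels: pd.DataFrame
    bin_width_ms: float = BIN_WIDTH_MS
    alignment: str = "offer1_onset"
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def window_bins(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of bins lying entirely inside [start_ms, stop_ms)."""
        starts = self.bin_starts_ms
        return np.where((starts >= start_ms - 1e-9) & (starts + self.bin_width_ms <= stop_ms + 1e-9))[0]


def default_bin_starts() -> np.ndarray:
    """Bin starts tiling the four analysis windows (2 epochs x 2 windows)."""
    starts = []
    for onset in (0.0, SOA_MS):
        for w0, w1 in (OFFER_WINDOW_MS, DELAY_WINDOW_MS):
            starts.append(onset + np.arange(w0, w1, BIN_WIDTH_MS))
    return np.concatenate(starts)


def simulate_session_rates(spec: PopulationCodeSpec, session: BehavioralSession,
                           seed: int | None = None,
                           bin_starts_ms: np.ndarray | None = None) -> NeuralSession:
    """Binned rates for a behavioral session under a linear-nonlinear code.

    The code is applied per offer epoch: each trial's offer-1 bins carry the
    code for (offer-1 value level, offer-1 side) and offer-2 bins likewise.
    Value is binarized at the median subjective value (sides of the grid);
    per-bin noise is scaled so that a 400-ms window mean has noise SD sigma.
    """
    from .behavior import subjective_value  # noqa: F401  (SVs already on trials if simulated)

    rng = np.random.default_rng(seed)
    t = session.trials
    if "sv1" not in t.columns:
        raise ValueError("session has no subjective values; run simulate_choices first")
    bin_starts = default_bin_starts() if bin_starts_ms is None else np.asarray(bin_starts_ms)
    n_bins = len(bin_starts)
    n_trials = len(t)

    sv = np.concatenate([t["sv1"], t["sv2"]])
    median = np.median(sv)
    value_level = {
        1: np.where(t["sv1"] >= median, 2, 1),
        2: np.where(t["sv2"] >= median, 2, 1),
    }
    side_level = {
        1: np.where(t["side1"] == "L", 1, 2),
        2: np.where(t["side2"] == "L", 1, 2),
    }

    centroids = spec.centroids()
    rates = np.empty((n_trials, spec.n_neurons, n_bins))
    bins_per_window = int(round((OFFER_WINDOW_MS[1] - OFFER_WINDOW_MS[0]) / BIN_WIDTH_MS))
    bin_sigma = spec.sigma * np.sqrt(bins_per_window)
    epoch_of_bin = np.where(bin_starts < SOA_MS, 1, 2)
    for epoch in (1, 2):
        cols = np.where(epoch_of_bin == epoch)[0]
        idx = spec.condition_index(value_level[epoch], side_level[epoch])
        mean = centroids[idx]  # (trials, neurons)
        noise = rng.normal(0.0, bin_sigma, size=(n_trials, spec.n_neurons, len(cols)))
        rates[:, :, cols] = mean[:, :, None] + noise

    labels = pd.DataFrame({
        "value_level_offer1": value_level[1],
        "value_level_offer2": value_level[2],
        "side_level_offer1": side_level[1],
        "side_level_offer2": side_level[2],
        "sv1": t["sv1"].to_numpy(),
        "sv2": t["sv2"].to_numpy(),
        "side1": t["side1"].to_numpy(),
        "side2": t["side2"].to_numpy(),
        "order": t["order"].to_numpy(),
    })
    meta = {"seed": seed, "n_neurons": spec.n_neurons, "d_lv": spec.d_lv,
            "d_la": spec.d_la, "d_n": spec.d_n, "sigma": spec.sigma}
    return NeuralSession(rates=rates, bin_starts_ms=bin_starts, labels=labels, meta=meta)
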