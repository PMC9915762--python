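"""Population-structure statistics: who carries the subspaces?

Two competing single-neuron accounts of separable value subspaces are
distinguished here. If the population splits into side-specific
subpopulations (a gain/receptive-field code), the distribution of left-right
differences in value sensitivity is bimodal; if a shared population encodes
value heterogeneously across sides, it is unimodal. The sensitivity index
z-scores each neuron's value-response profile per side before differencing,
so per-side gain and offset drop out by construction. Unimodality is tested
with Hartigan's dip statistic against a bootstrap uniform null.

Neurons contributing to both side subspaces (participation-ratio style
fourth-power share of the subspace vector) are further classified as
gain-modulated (same preferred value level in both subspaces) or
heterogeneous (significantly shifted peak) with a bootstrap test over 7
value levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._dip import hartigan_dip

__all__ = [
    "sensitivity_index",
    "dip_test",
    "subspace_contribution",
    "retained_neurons",
    "classify_gain_vs_heterogeneous",
    "SensitivityDistribution",
    "NeuronClassification",
]


def sensitivity_index(left_profiles: np.ndarray, right_profiles: np.ndarray):
    """Per-neuron signed value-space sensitivity, gain- and offset-invariant.

    ``left_profiles`` and ``right_profiles`` are (neurons x value bins) mean
    rates. Each side's profile is z-scored with that side's own mean and SD;
    the index is the mean over value bins of the z-profile difference.
    Neurons with zero variance on either side are excluded (NaN) and listed.
    """
    L = np.asarray(left_profiles, float)
    R = np.asarray(right_profiles, float)
    if L.shape != R.shape or L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need matching (neurons x >=2 value bins) profiles")
    sdL = L.std(axis=1)
    sdR = R.std(axis=1)
    ok = (sdL > 0) & (sdR > 0)
    idx = np.full(L.shape[0], np.nan)
    zL = (L[ok] - L[ok].mean(axis=1, keepdims=True)) / sdL[ok, None]
    zR = (R[ok] - R[ok].mean(axis=1, keepdims=True)) / sdR[ok, None]
    idx[ok] = (zL - zR).mean(axis=1)
    excluded = list(np.where(~ok)[0])
    return idx, excluded


@dataclass
class SensitivityDistribution:
    values: np.ndarray
    dip: float
    p: float


@lru_cache(maxsize=8)
def _uniform_null_dips(n: int, n_boot: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    return tuple(hartigan_dip(rng.random(n)) for _ in range(n_boot))


def dip_test(values: np.ndarray, n_boot: int = 1000, seed: int | None = 0) -> SensitivityDistribution:
    """Hartigan dip with a bootstrap p-value against the uniform null.

    The uniform distribution is the classical calibration null for the dip;
    p = (#(dip_null >= dip_obs) + 1) / (n_boot + 1).
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) < 10:
        raise ValueError("need a sample of at least 10 indices")
    if np.ptp(values) == 0:
        return SensitivityDistribution(values=values, dip=0.0, p=1.0)
    d = hartigan_dip(values)
    null = np.array(_uniform_null_dips(len(values), n_boot, int(seed or 0)))
    p = (np.sum(null >= d) + 1.0) / (n_boot + 1.0)
    return SensitivityDistribution(values=values, dip=float(d), p=float(p))


def subspace_contribution(v: np.ndarray) -> np.ndarray:
    """Normalized fourth-power share of each neuron in a subspace vector.

    contribution(n) = v(n)^4 / sum_j v(j)^4 — the participation-ratio style
    approximation to each neuron's variance share of the subspace.
    """
    v = np.asarray(v, float).ravel()
    p4 = v ** 4
    total = p4.sum()
    if total == 0:
        raise ValueError("zero vector has no subspace contributions")
    return p4 / total


def retained_neurons(v: np.ndarray, cumulative: float = 0.95,
                     mode: str = "cumulative") -> np.ndarray:
    """Neurons kept by the top-95% contribution rule.

    ``mode="cumulative"`` (default) keeps the smallest set whose summed
    contribution reaches the threshold; ``mode="count"`` keeps the top 95% of
    neurons by contribution rank.
    """
    c = subspace_contribution(v)
    order = np.argsort(c)[::-1]
    if mode == "cumulative":
        k = int(np.searchsorted(np.cumsum(c[order]), cumulative) + 1)
    elif mode == "count":
        k = max(1, int(np.floor(cumulative * len(c))))
    else:
        raise ValueError("mode must be 'cumulative' or 'count'")
    return np.sort(order[:k])


@dataclass
class NeuronClassification:
    neuron: int
    label: str                       # gain / heterogeneous / single_subspace / excluded
    p_shift: float = np.nan
    peak_left: float = np.nan
    peak_right: float = np.nan
    extra: dict = field(default_factory=dict)


def classify_gain_vs_heterogeneous(left_rates: np.ndarray, left_levels: np.ndarray,
                                   right_rates: np.ndarray, right_levels: np.ndarray,
                                   n_boot: int = 1000, seed: int | None = None,
                                   n_levels: int = 7, alpha: float = 0.05,
                                   in_both_subspaces: bool = True,
                                   neuron: int = -1) -> NeuronClassification:
    """Bootstrap test of a preferred-value shift between side subspaces.

    Per side, trial rates are resampled ``n_boot`` times; each resample's
    mean tuning curve over ``n_levels`` value levels yields a peak level.
    The paired per-resample peak differences give a bootstrap distribution
    of the preferred-value shift; the two-sided sign test on that
    distribution (does it cover zero?) decides significance. A significant
    shift labels the neuron heterogeneous, otherwise gain-modulated.
    Neurons not in both subspaces are labelled single_subspace and not
    tested.
    """
    if not in_both_subspaces:
        return NeuronClassification(neuron=neuron, label="single_subspace")
    rng = np.random.default_rng(seed)

    def boot_peaks(rates, levels):
        rates = np.asarray(rates, float)
        levels = np.asarray(levels)
        groups = [np.where(levels == lv)[0] for lv in range(n_levels)]
        if any(len(g) == 0 for g in groups):
            raise ValueError("every value level needs at least one trial")
        curve = np.array([rates[g].mean() for g in groups])
        if np.ptp(curve) == 0:
            return None
        peaks = np.empty(n_boot)
        for b in range(n_boot):
            m = np.array([rates[rng.choice(g, size=len(g))].mean() for g in groups])
            peaks[b] = np.argmax(m)
        return peaks

    pk_l = boot_peaks(left_rates, left_levels)
    pk_r = boot_peaks(right_rates, right_levels)
    if pk_l is None or pk_r is None:
        return NeuronClassification(neuron=neuron, label="excluded")

    diff = pk_l - pk_r
    p_low = (np.sum(diff <= 0) + 1.0) / (n_boot + 1.0)
    p_high = (np.sum(diff >= 0) + 1.0) / (n_boot + 1.0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    label = "heterogeneous" if p < alpha else "gain"
    return NeuronClassification(neuron=neuron, label=label, p_shift=float(p),
                                peak_left=float(pk_l.mean()), peak_right=float(pk_r.mean()))
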