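"""Orchestration, configuration, serialization, and reproducibility.

A full synthetic run proceeds: task generation -> choice simulation ->
trial filtering -> behavior model fit -> neural simulation -> window rates ->
per-neuron models -> subspace / geometry / decoding / population-structure
stages, each seeded from the run config. The manifest records config and
output hashes so a re-run with identical configuration is verifiably
identical.

Behavioral sessions round-trip through CSV, neural sessions through HDF5
(datasets ``rates``, ``bin_starts_ms``, label columns, JSON metadata attr).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior, decode, geometry, neuronfit, popstruct, subspace, syndata

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "write_session",
    "read_session",
    "write_neural",
    "read_neural",
]

_TRIAL_COLUMNS = ["p1", "stakes1", "kind1", "side1", "p2", "stakes2", "kind2",
                  "side2", "order", "duration_s", "t_offer1_ms", "t_offer2_ms",
                  "t_choice_ms", "choice", "reward_ml"]


@dataclass
class PipelineConfig:
    """All knobs of a synthetic end-to-end run; every stage has its own seed."""

    n_trials: int = 2000
    n_neurons: int = 60
    d_lv: float = 1.0
    d_la: float = 1.0
    d_n: float = 1.0
    sigma: float = 0.5
    sv_alpha: float = 0.7
    sv_gamma: float = 0.5
    sv_beta: float = 1.0
    sv_tau: float = 0.03
    min_trials_per_neuron: int = 300
    min_trials_broad: int = 160
    min_trials_narrow: int = 80
    min_simultaneous_neurons: int = 30
    n_boot_ceiling: int = 1000
    n_boot_link: int = 500
    n_value_levels: int = 7
    pca_variance: float = 0.99
    holdout_frac: float = 0.10
    stages: tuple = ("syndata", "behavior", "neuronfit", "subspace", "geometry",
                     "decode", "popstruct")
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        required = ("task", "choices", "neural", "subspace", "geometry",
                    "decode", "popstruct")
        missing = [k for k in required if k not in self.seeds]
        if missing:
            raise ValueError(f"config is missing seeds for stages: {missing}")
        for name in ("n_trials", "n_neurons", "min_trials_per_neuron",
                     "min_trials_broad", "min_trials_narrow",
                     "min_simultaneous_neurons", "n_boot_ceiling", "n_boot_link"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def with_master_seed(cls, seed: int, **kw) -> "PipelineConfig":
        names = ("task", "choices", "neural", "subspace", "geometry", "decode",
                 "popstruct")
        ss = np.random.SeedSequence(seed).spawn(len(names))
        seeds = {n: int(s.generate_state(1)[0] % (2 ** 31)) for n, s in zip(names, ss)}
        return cls(seeds=seeds, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    config_hash: str
    output_hashes: dict
    stage_summaries: dict
    out_dir: str


def _hash_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()


def _hash_file(path: Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_session(path, session: syndata.BehavioralSession) -> None:
    t = session.trials
    cols = [c for c in _TRIAL_COLUMNS if c in t.columns] + \
        [c for c in ("sv1", "sv2") if c in t.columns]
    df = t[cols].copy()
    df.insert(0, "subject_id", session.subject_id)
    df.to_csv(path, index=False, float_format="%.10g")


def read_session(path) -> syndata.BehavioralSession:
    df = pd.read_csv(path)
    for row, p in enumerate(np.concatenate([df["p1"], df["p2"]])):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0, 1] at trial row {row % len(df)}: {p}")
    bad = df.index[df["t_offer2_ms"] - df["t_offer1_ms"] <= 0]
    if len(bad):
        raise ValueError(f"non-increasing offer onsets at rows {list(bad[:5])}")
    subject = str(df["subject_id"].iloc[0])
    return syndata.BehavioralSession(trials=df.drop(columns=["subject_id"]),
                                     subject_id=subject)


def write_neural(path, neural: syndata.NeuralSession) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=neural.rates)
        f.create_dataset("bin_starts_ms", data=neural.bin_starts_ms)
        g = f.create_group("labels")
        for col in neural.labels.columns:
            data = neural.labels[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        f.attrs["bin_width_ms"] = neural.bin_width_ms
        f.attrs["alignment"] = neural.alignment
        f.attrs["meta"] = json.dumps(neural.meta, default=float)


def read_neural(path) -> syndata.NeuralSession:
    with h5py.File(path, "r") as f:
        rates = f["rates"][...]
        bins = f["bin_starts_ms"][...]
        labels = {}
        for col in f["labels"]:
            data = f["labels"][col][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            labels[col] = data
        labels = pd.DataFrame(labels)
        if len(labels) != rates.shape[0]:
            raise ValueError(
                f"label rows ({len(labels)}) do not match rate trials ({rates.shape[0]})")
        return syndata.NeuralSession(
            rates=rates, bin_starts_ms=bins, labels=labels,
            bin_width_ms=float(f.attrs["bin_width_ms"]),
            alignment=str(f.attrs["alignment"]), meta=json.loads(f.attrs["meta"]))


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Run the enabled stages in dependency order and write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = {}
    files = {}

    sv_true = behavior.SubjectiveValueParams(
        alpha=config.sv_alpha, gamma=config.sv_gamma, beta=config.sv_beta,
        tau=config.sv_tau, model_id="pow-prelec")

    session = syndata.generate_task_session(config.n_trials, seed=config.seeds["task"])
    session = syndata.simulate_choices(session, sv_true, seed=config.seeds["choices"])
    if "syndata" in config.stages:
        write_session(out / "trials.csv", session)
        files["trials.csv"] = out / "trials.csv"
        summaries["syndata"] = {"n_trials": session.n_trials}

    filtered, filter_log = behavior.filter_trials(session)
    if "behavior" in config.stages:
        fit = behavior.fit_choice_model(filtered, seed=config.seeds["choices"])
        subopt = behavior.suboptimal_choice_rate(filtered)
        summaries["behavior"] = {
            "selected_model": fit.selected, "accuracy": fit.accuracy,
            "suboptimal_rate": subopt, "filter": filter_log,
            "params": dataclasses.asdict(fit.params)}
        (out / "behavior.json").write_text(json.dumps(summaries["behavior"], indent=2))
        files["behavior.json"] = out / "behavior.json"

    spec = syndata.PopulationCodeSpec.create(
        config.n_neurons, config.d_lv, config.d_la, config.d_n, config.sigma,
        seed=config.seeds["neural"])
    neural = syndata.simulate_session_rates(spec, filtered, seed=config.seeds["neural"])
    if "syndata" in config.stages:
        write_neural(out / "neural.h5", neural)
        files["neural.h5"] = out / "neural.h5"

    value01, side = _epoch_design(neural)
    results = {}
    if "neuronfit" in config.stages:
        wr = neuronfit.compute_window_rates(
            neural, min_trials=min(config.min_trials_per_neuron, neural.n_trials))
        rates = wr.windows["offer1"]
        weights = []
        for n in range(rates.shape[1]):
            fits = neuronfit.fit_neuron_models(rates[:, n], value01, side, "offer1")
            weights.append(neuronfit.stack_models(fits).family_weights)
        results["neuronfit"] = {
            "n_neurons": rates.shape[1],
            "mean_family_weights": {k: float(np.mean([w[k] for w in weights]))
                                    for k in weights[0]}}
        summaries["neuronfit"] = results["neuronfit"]

    if "subspace" in config.stages:
        wr = neuronfit.compute_window_rates(
            neural, min_trials=min(config.min_trials_per_neuron, neural.n_trials))
        res = subspace.noise_ceiling_test(
            wr.windows["offer1"], value01, side,
            n_boot=config.n_boot_ceiling, seed=config.seeds["subspace"])
        summaries["subspace"] = {"observed_mean": res.observed_mean,
                                 "ceiling_mean": res.ceiling_mean, "p": res.p}

    if "geometry" in config.stages:
        feats, labels = _condition_features(neural)
        est = geometry.estimate_geometry(feats, labels, seed=config.seeds["geometry"])
        pred = geometry.predict_error_rates(est)
        summaries["geometry"] = {
            "d_lv": est.d_lv, "d_la": est.d_la, "d_n": est.d_n,
            "sigma": est.sigma, "epsilon": est.epsilon, "rho": est.rho,
            "binding_error": pred.binding_error, "ccgp_error": pred.ccgp_error}
        np.savetxt(out / "distance_matrix.csv", est.distance_matrix, delimiter=",")
        files["distance_matrix.csv"] = out / "distance_matrix.csv"

    if "decode" in config.stages:
        min_tr = min(config.min_trials_broad, _min_condition_count(neural))
        pseudo = decode.build_pseudopopulation(
            [neural], _condition_of, min_trials=min_tr, seed=config.seeds["decode"])
        report = decode.decode_and_generalize(
            pseudo, seed=config.seeds["decode"], holdout_frac=config.holdout_frac,
            pca_variance=config.pca_variance)
        summaries["decode"] = dataclasses.asdict(report)

    if "popstruct" in config.stages:
        wr = neuronfit.compute_window_rates(
            neural, min_trials=min(config.min_trials_per_neuron, neural.n_trials))
        profiles = _value_profiles(wr.windows["offer1"], value01, side,
                                   config.n_value_levels)
        idx, _excl = popstruct.sensitivity_index(*profiles)
        dip = popstruct.dip_test(idx[np.isfinite(idx)], n_boot=500,
                                 seed=config.seeds["popstruct"])
        summaries["popstruct"] = {"dip": dip.dip, "p": dip.p}

    (out / "summary.json").write_text(json.dumps(summaries, indent=2, default=float))
    files["summary.json"] = out / "summary.json"

    cfg_hash = _hash_bytes(json.dumps(config.to_dict(), sort_keys=True).encode())
    manifest = RunManifest(
        config_hash=cfg_hash,
        output_hashes={name: _hash_file(p) for name, p in files.items()},
        stage_summaries=summaries, out_dir=str(out))
    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest


def _epoch_design(neural: syndata.NeuralSession):
    """Offer-1 design: value min-max normalized to [0,1], side {-1,+1}."""
    sv = neural.labels["sv1"].to_numpy()
    value01 = (sv - sv.min()) / np.ptp(sv)
    side = np.where(neural.labels["side1"].to_numpy() == "L", 1.0, -1.0)
    return value01, side


def _condition_features(neural: syndata.NeuralSession):
    """Offer-1 window means and (value level, side level) grid labels."""
    bins = neural.window_bins(0.0, 400.0)
    feats = neural.rates[:, :, bins].mean(axis=2)
    labels = np.column_stack([neural.labels["value_level_offer1"].to_numpy(),
                              neural.labels["side_level_offer1"].to_numpy()])
    return feats, labels


def _condition_of(neural: syndata.NeuralSession):
    sv = neural.labels["sv1"].to_numpy()
    value = decode.binarize_value(sv)
    context = neural.labels["side_level_offer1"].to_numpy()
    return value, context


def _min_condition_count(neural: syndata.NeuralSession) -> int:
    value, context = _condition_of(neural)
    counts = [np.sum((value == v) & (context == c))
              for v in ("low", "high") for c in (1, 2)]
    return int(min(counts))


def _value_profiles(rates: np.ndarray, value01: np.ndarray, side: np.ndarray,
                    n_levels: int = 7):
    """Per-neuron mean rate per value level, separately for each side."""
    levels = neuronfit.discretize_value(value01, n_levels)
    out = []
    for s in (1.0, -1.0):
        prof = np.stack([rates[(levels == lv) & (side == s)].mean(axis=0)
                         for lv in range(n_levels)], axis=1)  # (neurons, levels)
        out.append(prof)
    return out  # [left_profiles, right_profiles]
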