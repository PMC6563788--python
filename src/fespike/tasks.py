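"""End-to-end experiment protocols.

Single-neuron sequence-learning sweeps (duration, afferent count, firing
rates, tolerance width / scaling rate), noise-robustness evaluation of a
trained neuron, spatiotemporal pattern classification by template
matching, and the dynamic-target population decoding strategy for
multi-neuron readouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NeuronParams, PspCache, SpikePattern, SpikeTrain, simulate
from .learn import (
    LearnConfig,
    _first_error_online,
    _increment,
    tolerance_windows,
    train,
    weight_decrement,
)
from .metrics import DEFAULT_SIGMA, correlation_c
from .synth import (
    JitterSpec,
    ClassificationDataset,
    desired_poisson_train,
    jitter_pattern,
    make_classification_dataset,
    poisson_pattern,
)

__all__ = [
    "DynamicDecodeConfig",
    "Readout",
    "classify_by_template",
    "dynamic_targets",
    "population_predict",
    "run_classification",
    "train_dynamic_population",
    "run_experiment",
    "EXPERIMENTS",
]


# ---------------------------------------------------------------------------
# template-matching classification


def classify_by_template(
    actual: SpikeTrain,
    templates: Sequence[SpikeTrain],
    sigma: float = DEFAULT_SIGMA,
    duration: float | None = None,
    dt: float = 1.0,
) -> int:
    """Class whose desired train the output resembles most (max C; ties -> lowest)."""
    if not templates:
        raise ValueError("need at least one template")
    scores = [
        correlation_c(actual, t, sigma=sigma, duration=duration, dt=dt)
        for t in templates
    ]
    return int(np.argmax(scores))


@dataclass
class ClassificationResult:
    weights: np.ndarray  # (n_classes, n_afferents)
    train_accuracy: float
    test_accuracy: float


def run_classification(
    dataset: ClassificationDataset,
    config: LearnConfig,
    params: NeuronParams | None = None,
    epochs: int = 300,
    shuffle: bool = True,
) -> ClassificationResult:
    """One learning neuron per class, trained on every sample each epoch.

    A neuron's desired train is its class template for samples of its own
    class and the empty train otherwise, so any spike elicited by a
    foreign sample is a stray (type a) and triggers a decrement — the
    neuron learns to stay silent.  Each (sample, neuron) presentation
    applies at most one first-error update.  A sample is classified by
    the neuron whose output matches its own template best (max C; ties ->
    lowest class index).
    """
    if params is None:
        params = NeuronParams()
    half = (config.epsilon - 1) // 2
    for t in dataset.templates:
        tolerance_windows(t, config.epsilon, params.dt)  # validate disjointness
    caches = [PspCache(p, params) for p, _ in dataset.train_samples]
    labels = np.array([lab for _, lab in dataset.train_samples])
    d_idx = [t.indices(params.dt) for t in dataset.templates]
    empty_idx = np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    G = dataset.n_classes
    weights = rng.normal(
        config.init_mean, config.init_sd, (G, dataset.bases[0].n_afferents)
    )

    n_samples = len(dataset.train_samples)
    for _ in range(epochs):
        order = rng.permutation(n_samples) if shuffle else np.arange(n_samples)
        for si in order:
            cache, label = caches[si], labels[si]
            for c in range(G):
                target = d_idx[c] if c == label else empty_idx
                err, n_matched = _first_error_online(
                    cache, weights[c], params, target, half
                )
                if err is None:
                    continue
                if err.kind == "c":
                    weights[c] += _increment(
                        cache, weights[c], target[:n_matched],
                        params.to_index(err.t_err), config, params,
                    )
                else:
                    weights[c] -= config.lambda2 * cache.psp[:, params.to_index(err.t_err)]

    def accuracy(samples, sample_caches=None) -> float:
        hits = 0
        for i, (pattern, label) in enumerate(samples):
            cache = (
                sample_caches[i] if sample_caches else PspCache(pattern, params)
            )
            scores = []
            for c in range(G):
                trace = simulate(pattern, weights[c], params, cache=cache)
                scores.append(
                    correlation_c(
                        trace.output_spikes,
                        dataset.templates[c],
                        duration=dataset.duration,
                        dt=params.dt,
                    )
                )
            hits += int(np.argmax(scores)) == label
        return hits / len(samples)

    return ClassificationResult(
        weights=weights,
        train_accuracy=accuracy(dataset.train_samples, caches),
        test_accuracy=accuracy(dataset.test_samples),
    )


# ---------------------------------------------------------------------------
# dynamic target determination and population readout


@dataclass(frozen=True)
class DynamicDecodeConfig:
    """Parameters of the dynamic-target population readout.

    theta_e is the encoding threshold a target neuron's subthreshold
    maximum must exceed before an extra desired spike is scheduled there;
    margin optionally biases the detection threshold during training;
    group_count x neurons_per_group is the readout layout.
    """

    theta_e: float = 0.6
    margin: float = 0.0
    group_count: int = 1
    neurons_per_group: int = 1

    def __post_init__(self) -> None:
        if self.theta_e <= 0:
            raise ValueError("theta_e must be positive")
        if self.group_count < 1 or self.neurons_per_group < 1:
            raise ValueError("need at least one group and one neuron per group")


def _subthreshold_max(trace) -> tuple[float, float]:
    """(V_max, t_max) over grid steps at which no spike was emitted."""
    v = trace.values.copy()
    idx = np.round(trace.output_spikes.times / trace.dt).astype(np.int64)
    v[idx] = -np.inf
    k = int(np.argmax(v))  # earliest grid time on ties
    return float(v[k]), k * trace.dt


def dynamic_targets(
    is_target: bool, trace, config: DynamicDecodeConfig
) -> tuple[SpikeTrain, float | None, str | None]:
    """Per-presentation desired train and update for one readout neuron.

    Non-target neurons must stay silent: no spikes means no learning, any
    spike is treated as the first wrong time and triggers a decrement.
    Target neurons grow their own target train: with no output the desired
    train is the time of the subthreshold voltage maximum; with output and
    a subthreshold maximum above the encoding threshold, that time is
    appended to the emitted train; otherwise the emitted train is accepted
    as-is.  An increment and a decrement are never scheduled together.
    """
    out = trace.output_spikes
    if not is_target:
        if len(out) == 0:
            return SpikeTrain.empty(), None, None
        return SpikeTrain.empty(), float(out.times[0]), "decrement"
    v_max, t_max = _subthreshold_max(trace)
    if len(out) == 0:
        return SpikeTrain(np.array([t_max])), t_max, "increment"
    if v_max > config.theta_e:
        td = SpikeTrain(np.sort(np.append(out.times, t_max)))
        return td, t_max, "increment"
    return out, None, None


@dataclass(frozen=True)
class Readout:
    """Spike counts of a G x M readout layer and the decoded group."""

    counts: np.ndarray
    activated: np.ndarray
    predicted_group: int


def population_predict(counts) -> Readout:
    """Decode the category from per-(group, index) output spike counts.

    At each index position the neuron with the strictly largest count
    among the groups is 'activated' (a tie activates no one).  The
    predicted group has the most activated neurons; remaining ties go to
    the larger total spike count, then the lowest group index.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a (group, index) table")
    G, M = counts.shape
    activated = np.zeros(G, dtype=int)
    for m in range(M):
        col = counts[:, m]
        top = col.max()
        winners = np.nonzero(col == top)[0]
        if winners.size == 1:
            activated[winners[0]] += 1
    totals = counts.sum(axis=1)
    best = min(range(G), key=lambda g: (-activated[g], -totals[g], g))
    return Readout(counts=counts, activated=activated, predicted_group=int(best))


@dataclass
class PopulationResult:
    weights: np.ndarray  # (groups, neurons_per_group, n_afferents)
    train_accuracy: float
    test_accuracy: float


def train_dynamic_population(
    dataset: ClassificationDataset,
    decode: DynamicDecodeConfig,
    config: LearnConfig,
    params: NeuronParams | None = None,
    epochs: int = 50,
) -> PopulationResult:
    """Train a group-per-class readout with dynamically determined targets.

    Each class owns a group of ``decode.neurons_per_group`` neurons.  On
    every presentation each neuron derives its own desired train and
    update from its voltage trace via :func:`dynamic_targets` (target
    neurons chase their subthreshold maximum; non-target neurons are
    decremented at their first stray spike).  With ``decode.margin`` > 0
    the trace used during training is computed with threshold
    theta*(1-margin) for non-target neurons and theta*(1+margin) for
    target neurons, which trains in a safety margin; evaluation always
    uses the true threshold.  Prediction counts activated neurons per
    group (:func:`population_predict`).
    """
    if params is None:
        params = NeuronParams()
    G, M = dataset.n_classes, decode.neurons_per_group
    N = dataset.bases[0].n_afferents
    rng = np.random.default_rng(config.seed)
    weights = rng.normal(config.init_mean, config.init_sd, (G, M, N))
    caches = [PspCache(p, params) for p, _ in dataset.train_samples]
    train_params = {
        True: params if decode.margin == 0 else NeuronParams(
            params.tau_m, params.tau_s, params.theta * (1 + decode.margin), params.dt
        ),
        False: params if decode.margin == 0 else NeuronParams(
            params.tau_m, params.tau_s, params.theta * (1 - decode.margin), params.dt
        ),
    }
    n_samples = len(dataset.train_samples)
    for _ in range(epochs):
        for si in rng.permutation(n_samples):
            cache, label = caches[si], dataset.train_samples[si][1]
            pattern = dataset.train_samples[si][0]
            for g in range(G):
                is_target = g == label
                p = train_params[is_target]
                for m in range(M):
                    trace = simulate(pattern, weights[g, m], p, cache=cache)
                    td, t_err, kind = dynamic_targets(is_target, trace, decode)
                    if kind is None:
                        continue
                    k_err = p.to_index(t_err)
                    if kind == "increment":
                        before = td.times[td.times < t_err]
                        weights[g, m] += _increment(
                            cache, weights[g, m],
                            np.round(before / p.dt).astype(np.int64),
                            k_err, config, p,
                        )
                    else:
                        weights[g, m] -= config.lambda2 * cache.psp[:, k_err]

    def accuracy(samples, sample_caches=None) -> float:
        hits = 0
        for i, (pattern, label) in enumerate(samples):
            cache = sample_caches[i] if sample_caches else PspCache(pattern, params)
            counts = np.empty((G, M), dtype=int)
            for g in range(G):
                for m in range(M):
                    trace = simulate(pattern, weights[g, m], params, cache=cache)
                    counts[g, m] = len(trace.output_spikes)
            hits += population_predict(counts).predicted_group == label
        return hits / len(samples)

    return PopulationResult(
        weights=weights,
        train_accuracy=accuracy(dataset.train_samples, caches),
        test_accuracy=accuracy(dataset.test_samples),
    )


# ---------------------------------------------------------------------------
# experiment runner

_PAPER = dict(n_afferents=400, rate_in=10.0, rate_out=100.0)


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _learning_trial(
    seed: int,
    n_afferents: int,
    duration: float,
    rate_in: float,
    rate_out: float,
    eps: int,
    s_r: float = 0.0,
    max_epochs: int = 60_000,
    lambda1: float = 0.005,
    lambda2: float = 0.005,
    params: NeuronParams | None = None,
    return_state: bool = False,
):
    """One input/target pair and one FE-Learn run; returns summary metrics.

    The sweep protocols default to s_r=0: window-matched training with
    the chain term active can enter increment/decrement limit cycles at
    wide windows, and convergence is fastest without it (see the methods
    note); the eps x S_r sweep scans nonzero values explicitly.
    """
    if params is None:
        params = NeuronParams()
    s_pat, s_des, s_init = _derive_seeds(seed, 3)
    pattern = poisson_pattern(n_afferents, rate_in, duration, params.dt, s_pat)
    desired = desired_poisson_train(
        rate_out, duration, params.dt, min_gap=eps * params.dt, seed=s_des
    )
    config = LearnConfig(
        epsilon=eps, s_r=s_r, lambda1=lambda1, lambda2=lambda2,
        max_epochs=max_epochs, seed=s_init,
    )
    rec = train(pattern, desired, config, params)
    row = dict(
        best_C=rec.best_c,
        best_epoch=rec.best_epoch,
        converged=rec.converged,
        epochs=rec.epochs_to_converge,
        n_desired=len(desired),
    )
    if return_state:
        return row, (pattern, desired, rec, params)
    return row


def _eps_for_duration(duration: float) -> int:
    if duration <= 1000:
        return 1
    if duration <= 2000:
        return 3
    return 5


def _eps_for_afferents(n: int) -> int:
    if n < 150:
        return 5
    if n < 300:
        return 3
    return 1


def experiment_duration_sweep(
    durations=tuple(range(200, 3001, 200)), trials=20, eps=None, seed=0, **kw
):
    rows = []
    for d in durations:
        e = eps if eps is not None else _eps_for_duration(d)
        for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:], ):
            row = _learning_trial(s, duration=float(d), eps=e, **{**_PAPER, **kw})
            rows.append(dict(duration=d, eps=e, trial=i, **row))
    return pd.DataFrame(rows)


def experiment_afferent_sweep(
    n_list=tuple(range(100, 501, 50)), trials=20, duration=800.0, seed=0, **kw
):
    rows = []
    base = {k: v for k, v in _PAPER.items() if k != "n_afferents"}
    for n in n_list:
        e = _eps_for_afferents(n)
        for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
            row = _learning_trial(
                s, n_afferents=n, duration=duration, eps=e, **{**base, **kw}
            )
            rows.append(dict(n_afferents=n, eps=e, trial=i, **row))
    return pd.DataFrame(rows)


def experiment_rate_grid(
    rates_in=(6.0, 10.0, 14.0, 18.0),
    rates_out=tuple(range(20, 161, 20)),
    trials=20,
    duration=800.0,
    eps=1,
    seed=0,
    **kw,
):
    rows = []
    n_afferents = kw.pop("n_afferents", 400)
    for r_in in rates_in:
        for r_out in rates_out:
            for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
                row = _learning_trial(
                    s, n_afferents=n_afferents, duration=duration,
                    rate_in=r_in, rate_out=float(r_out), eps=eps, **kw,
                )
                rows.append(dict(rate_in=r_in, rate_out=r_out, trial=i, **row))
    return pd.DataFrame(rows)


def experiment_background_noise(
    sigmas=tuple(np.round(np.arange(0.03, 0.331, 0.03), 2)),
    trials=20,
    duration=500.0,
    eps=1,
    n_eval=1,
    seed=0,
    **kw,
):
    """Train deterministically, then evaluate with Gaussian membrane noise."""
    rows = []
    for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
        _, (pattern, desired, rec, params) = _learning_trial(
            s, duration=duration, eps=eps, return_state=True, **{**_PAPER, **kw}
        )
        rng = np.random.default_rng(_derive_seeds(s, 4)[3])
        cache = PspCache(pattern, params)
        for sb in sigmas:
            for k in range(n_eval):
                trace = simulate(
                    pattern, rec.weights, params,
                    voltage_noise_sd=float(sb), rng=rng, cache=cache,
                )
                c = correlation_c(
                    trace.output_spikes, desired, duration=duration, dt=params.dt
                )
                rows.append(dict(sigma_b=float(sb), trial=i, eval=k, C=c))
    return pd.DataFrame(rows)


def experiment_jitter_noise(
    sigmas=tuple(np.round(np.arange(0.2, 2.01, 0.2), 2)),
    p_delete=0.05,
    add_rate=1.0,
    trials=20,
    duration=500.0,
    eps=1,
    seed=0,
    **kw,
):
    """Train deterministically, then evaluate on jittered input patterns."""
    rows = []
    for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
        _, (pattern, desired, rec, params) = _learning_trial(
            s, duration=duration, eps=eps, return_state=True, **{**_PAPER, **kw}
        )
        noise_seed = _derive_seeds(s, 4)[3]
        for sj in sigmas:
            spec = JitterSpec(sigma_j=float(sj), p_delete=p_delete, add_rate=add_rate)
            noisy = jitter_pattern(pattern, spec, noise_seed)
            trace = simulate(noisy, rec.weights, params)
            c = correlation_c(
                trace.output_spikes, desired, duration=duration, dt=params.dt
            )
            rows.append(dict(sigma_j=float(sj), trial=i, C=c))
    return pd.DataFrame(rows)


def experiment_eps_sr_sweep(
    eps_list=(1, 3, 5, 7),
    sr_list=tuple(np.round(np.arange(0.0, 2.01, 0.2), 1)),
    trials=20,
    duration=800.0,
    seed=0,
    **kw,
):
    rows = []
    for e in eps_list:
        for sr in sr_list:
            for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
                row = _learning_trial(
                    s, duration=duration, eps=int(e), s_r=float(sr),
                    **{**_PAPER, **kw},
                )
                rows.append(dict(eps=e, s_r=sr, trial=i, **row))
    return pd.DataFrame(rows)


def experiment_classification(
    trials=20, eps=7, epochs=300, seed=0, dataset_kw=None, **kw
):
    """Three-class spatiotemporal recognition with per-class templates.

    Like the sequence-learning sweeps, the protocol defaults to s_r=0:
    with the chain term active a rare shallow-slope crossing can blow a
    chain coefficient up and send one neuron's weights into runaway
    growth, collapsing the readout (see the methods note).
    """
    rows = []
    dataset_kw = dataset_kw or {}
    kw.setdefault("s_r", 0.0)
    for i, s in enumerate(_derive_seeds(seed, trials + 1)[1:]):
        s_data, s_init = _derive_seeds(s, 2)
        dataset = make_classification_dataset(seed=s_data, **dataset_kw)
        config = LearnConfig(epsilon=int(eps), seed=s_init, **kw)
        res = run_classification(dataset, config, epochs=epochs)
        rows.append(
            dict(
                trial=i,
                eps=eps,
                train_accuracy=res.train_accuracy,
                test_accuracy=res.test_accuracy,
            )
        )
    return pd.DataFrame(rows)


def experiment_overfit_sweep(eps_list=(1, 3, 5, 7, 9), trials=20, seed=0, **kw):
    """Test accuracy of the recognition task as the window width varies."""
    frames = []
    for e in eps_list:
        frames.append(experiment_classification(trials=trials, eps=int(e), seed=seed, **kw))
    return pd.concat(frames, ignore_index=True)


EXPERIMENTS = {
    "duration_sweep": experiment_duration_sweep,
    "afferent_sweep": experiment_afferent_sweep,
    "rate_grid": experiment_rate_grid,
    "background_noise": experiment_background_noise,
    "jitter_noise": experiment_jitter_noise,
    "eps_sr_sweep": experiment_eps_sr_sweep,
    "overfit_sweep": experiment_overfit_sweep,
    "classification": experiment_classification,
}


def run_experiment(name: str, out_dir: str | Path | None = None, **overrides):
    """Execute a named protocol; returns (per-trial table, aggregate summary).

    With ``out_dir`` the table is written as CSV and the summary as JSON.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    df = EXPERIMENTS[name](**overrides)
    group_cols = [
        c for c in ("duration", "n_afferents", "rate_in", "rate_out",
                    "sigma_b", "sigma_j", "eps", "s_r")
        if c in df.columns and df[c].nunique() > 1 or c == "eps" and c in df.columns
    ]
    value_cols = [c for c in ("best_C", "C", "train_accuracy", "test_accuracy", "epochs")
                  if c in df.columns]
    if group_cols:
        agg = df.groupby(group_cols)[value_cols].mean().reset_index()
    else:
        agg = df[value_cols].mean().to_frame().T
    summary = {"experiment": name, "aggregate": agg.to_dict(orient="records")}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}_trials.csv", index=False)
        (out / f"{name}_summary.json").write_text(json.dumps(summary, default=float))
    return df, summary
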