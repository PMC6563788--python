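"""Generators for synthetic spike data.

All experimental inputs are homogeneous Poisson spike trains on the
simulation grid (Bernoulli per 1-ms bin with probability rate*dt/1000),
optionally perturbed by Gaussian timing jitter, random deletion and
Poisson insertion.  Every generator is a pure function of its parameters
and seed: identical arguments give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import SpikePattern, SpikeTrain, read_pattern, write_pattern

__all__ = [
    "JitterSpec",
    "ClassificationDataset",
    "poisson_train",
    "poisson_pattern",
    "desired_poisson_train",
    "jitter_pattern",
    "make_classification_dataset",
    "template_train",
    "write_classification_dataset",
    "read_classification_dataset",
    "DEFAULT_TEMPLATES",
]

# desired output trains of the three-class recognition task, written
# start:step:stop in ms
DEFAULT_TEMPLATES = ((5, 15, 170), (15, 15, 180), (25, 15, 190))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def poisson_train(
    rate: float, duration: float, dt: float = 1.0, seed=0
) -> SpikeTrain:
    """Homogeneous Poisson train: at most one spike per grid step.

    Spikes occupy the grid times dt..duration, so the expected count is
    exactly rate * duration / 1000.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = rate * dt / 1000.0
    if p > 1:
        raise ValueError("rate * dt / 1000 exceeds 1: grid too coarse for this rate")
    rng = _rng(seed)
    n_bins = int(round(duration / dt))
    hits = rng.random(n_bins) < p
    return SpikeTrain((np.nonzero(hits)[0] + 1) * dt)


def desired_poisson_train(
    rate: float,
    duration: float,
    dt: float = 1.0,
    min_gap: float = 0.0,
    seed=0,
) -> SpikeTrain:
    """Poisson train with spikes closer than ``min_gap`` rejected.

    Used for desired output trains: a minimum inter-spike gap of
    epsilon * dt keeps the tolerance windows disjoint.  Spikes are drawn
    per bin and a spike is rejected when it falls within ``min_gap`` of
    the previously accepted one.  Times earlier than 2*dt are excluded:
    a target spike must be preceded by at least one grid step at which an
    input spike can raise the membrane potential, so the earliest
    reachable firing time is 2*dt.
    """
    base = poisson_train(rate, duration, dt, seed)
    times = base.times[base.times >= 2 * dt]
    if min_gap <= dt:
        return SpikeTrain(times)
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(t)
    return SpikeTrain(np.asarray(kept))


def poisson_pattern(
    n_afferents: int, rate: float, duration: float, dt: float = 1.0, seed=0
) -> SpikePattern:
    """N independent Poisson trains with per-afferent derived sub-seeds.

    Afferent i is drawn from the i-th spawn of the seed sequence, so its
    train does not depend on ``n_afferents``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_afferents)
    trains = [
        poisson_train(rate, duration, dt, np.random.default_rng(c))
        for c in children
    ]
    return SpikePattern(tuple(trains), duration)


@dataclass(frozen=True)
class JitterSpec:
    """Input-noise model: timing jitter, deletion and insertion.

    sigma_j is the SD of the zero-mean Gaussian added to each spike time
    (ms); each spike is independently deleted with probability p_delete;
    extra spikes are merged in from an independent Poisson process at
    add_rate (Hz) per afferent.
    """

    sigma_j: float = 0.0
    p_delete: float = 0.0
    add_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_j < 0 or self.add_rate < 0 or not 0 <= self.p_delete <= 1:
            raise ValueError("invalid jitter specification")


def jitter_pattern(pattern: SpikePattern, spec: JitterSpec, seed=0) -> SpikePattern:
    """Apply deletion, Gaussian jitter and Poisson insertion to every train.

    Jittered times are rounded to the grid and clipped to [0, duration];
    coincident spikes merge into one.
    """
    rng = _rng(seed)
    dt = 1.0  # grid inferred from rounding; patterns in this package use 1 ms
    out = []
    for train in pattern.trains:
        t = train.times
        if spec.p_delete > 0 and t.size:
            t = t[rng.random(t.size) >= spec.p_delete]
        if spec.sigma_j > 0 and t.size:
            t = t + rng.normal(0.0, spec.sigma_j, t.size)
        t = np.clip(np.round(t / dt) * dt, 0.0, pattern.duration)
        if spec.add_rate > 0:
            extra = poisson_train(spec.add_rate, pattern.duration, dt, rng)
            t = np.concatenate([t, extra.times])
        out.append(SpikeTrain(np.unique(t)))
    return SpikePattern(tuple(out), pattern.duration)


def template_train(start: float, step: float, stop: float) -> SpikeTrain:
    """Arithmetic spike sequence start, start+step, ..., <= stop."""
    return SpikeTrain(np.arange(start, stop + step / 2, step, dtype=float))


@dataclass(frozen=True)
class ClassificationDataset:
    """Multi-class spatiotemporal recognition fixture.

    Each class has one base Poisson pattern; train/test samples are
    independent jittered copies of it, labelled by class.  Templates are
    the desired output trains the learner must emit per class.
    """

    bases: tuple
    templates: tuple
    train_samples: tuple  # of (SpikePattern, label)
    test_samples: tuple
    duration: float = field(default=200.0)

    @property
    def n_classes(self) -> int:
        return len(self.bases)


def make_classification_dataset(
    n_classes: int = 3,
    n_afferents: int = 400,
    base_rate: float = 5.0,
    duration: float = 200.0,
    n_train: int = 25,
    n_test: int = 25,
    jitter_sd: float = 3.0,
    templates=DEFAULT_TEMPLATES,
    dt: float = 1.0,
    seed=0,
) -> ClassificationDataset:
    """Random multi-class task: jittered variants of per-class base patterns.

    Defaults follow the three-pattern recognition study: 400 afferents
    firing at 5 Hz for 200 ms, 25 training and 25 test samples per class
    obtained by 3-ms Gaussian jitter, and arithmetic desired trains.
    """
    if len(templates) != n_classes:
        raise ValueError("need one desired template per class")
    ss = np.random.SeedSequence(seed)
    base_ss, sample_ss = ss.spawn(2)
    bases = [
        poisson_pattern(n_afferents, base_rate, duration, dt, s)
        for s in base_ss.spawn(n_classes)
    ]
    rng = np.random.default_rng(sample_ss)
    spec = JitterSpec(sigma_j=jitter_sd)
    tmpl = tuple(
        t if isinstance(t, SpikeTrain) else template_train(*t) for t in templates
    )
    train_samples = tuple(
        (jitter_pattern(bases[c], spec, rng), c)
        for c in range(n_classes)
        for _ in range(n_train)
    )
    test_samples = tuple(
        (jitter_pattern(bases[c], spec, rng), c)
        for c in range(n_classes)
        for _ in range(n_test)
    )
    return ClassificationDataset(
        bases=tuple(bases),
        templates=tmpl,
        train_samples=train_samples,
        test_samples=test_samples,
        duration=duration,
    )


def write_classification_dataset(
    dataset: ClassificationDataset, out_dir: str | Path, dt: float = 1.0
) -> None:
    """Write every pattern as CSV/JSON plus a manifest of files and labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "duration_ms": dataset.duration,
        "templates": [list(t.times) for t in dataset.templates],
        "bases": [],
        "train": [],
        "test": [],
    }
    for c, base in enumerate(dataset.bases):
        name = f"base_{c}.csv"
        write_pattern(out / name, base, dt)
        manifest["bases"].append(name)
    for split in ("train", "test"):
        samples = getattr(dataset, f"{split}_samples")
        for i, (pattern, label) in enumerate(samples):
            name = f"{split}_{i:03d}.csv"
            write_pattern(out / name, pattern, dt)
            manifest[split].append({"file": name, "label": int(label)})
    (out / "manifest.json").write_text(json.dumps(manifest))


def read_classification_dataset(out_dir: str | Path) -> ClassificationDataset:
    """Load a dataset written by :func:`write_classification_dataset`."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bases = tuple(read_pattern(out / n)[0] for n in manifest["bases"])
    templates = tuple(SpikeTrain(np.asarray(t, float)) for t in manifest["templates"])

    def load(split):
        return tuple(
            (read_pattern(out / item["file"])[0], item["label"])
            for item in manifest[split]
        )

    return ClassificationDataset(
        bases=bases,
        templates=templates,
        train_samples=load("train"),
        test_samples=load("test"),
        duration=float(manifest["duration_ms"]),
    )
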