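"""Leaky integrate-and-fire dynamics on a discrete time grid.

The neuron accumulates a weighted sum of double-exponential postsynaptic
potentials (PSPs) from its afferents and is reset by an exponentially
decaying hyperpolarisation each time it fires:

    V(t) = sum_i w_i sum_{t_i^j < t} K(t - t_i^j)
           - theta * sum_{t_s^j < t} exp(-(t - t_s^j) / tau_m)

with the unit-peak kernel K(x) = V_norm (exp(-x/tau_m) - exp(-x/tau_s)).

All spike times live on the simulation grid (integer multiples of ``dt``);
a spike at exactly time t contributes to the potential from t + dt onward
(strict inequality above).  Kernel values for every grid lag are computed
once per pattern and reused by the simulator and by the learning rule
(:class:`PspCache`), so a training run evaluates each exponential only once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronParams",
    "SpikeTrain",
    "SpikePattern",
    "VoltageTrace",
    "PspCache",
    "v_norm",
    "psp_kernel",
    "kernel_peak_time",
    "psp_matrix",
    "simulate",
    "write_pattern",
    "read_pattern",
]


def v_norm(tau_m: float, tau_s: float) -> float:
    """Normalisation constant giving the PSP kernel a unit peak.

    With beta = tau_m / tau_s the kernel maximum equals
    (beta^(beta/(beta-1)) / (beta - 1))^-1, so this factor stretches
    the peak of K to 1.

    Raises
    ------
    ValueError
        If ``tau_m <= tau_s`` or either constant is non-positive.
    """
    if not (tau_m > tau_s > 0):
        raise ValueError(
            f"require tau_m > tau_s > 0, got tau_m={tau_m}, tau_s={tau_s}"
        )
    beta = tau_m / tau_s
    return beta ** (beta / (beta - 1.0)) / (beta - 1.0)


def kernel_peak_time(tau_m: float, tau_s: float) -> float:
    """Lag at which the PSP kernel attains its (unit) maximum."""
    return tau_m * tau_s / (tau_m - tau_s) * np.log(tau_m / tau_s)


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants of the current-based LIF neuron.

    Parameters
    ----------
    tau_m : float
        Membrane time constant in ms.
    tau_s : float
        Synaptic current time constant in ms; must be smaller than ``tau_m``.
    theta : float
        Firing threshold in mV.
    dt : float
        Simulation grid step in ms.
    """

    tau_m: float = 10.0
    tau_s: float = 2.5
    theta: float = 1.0
    dt: float = 1.0
    v_norm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "v_norm", v_norm(self.tau_m, self.tau_s))

    def n_steps(self, duration: float) -> int:
        """Number of grid points in [0, duration], endpoints included."""
        return int(round(duration / self.dt)) + 1

    def to_index(self, t: float | np.ndarray) -> int | np.ndarray:
        idx = np.round(np.asarray(t) / self.dt).astype(np.int64)
        return int(idx) if idx.ndim == 0 else idx


def psp_kernel(x, params: NeuronParams):
    """Unit-peak PSP kernel K(x); zero for negative lags (causality)."""
    x = np.asarray(x, dtype=float)
    out = params.v_norm * (np.exp(-x / params.tau_m) - np.exp(-x / params.tau_s))
    out = np.where(x < 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in ms."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be strictly increasing and >= 0")
        object.__setattr__(self, "times", t)

    @classmethod
    def empty(cls) -> "SpikeTrain":
        return cls(np.empty(0))

    def __len__(self) -> int:
        return self.times.size

    def indices(self, dt: float) -> np.ndarray:
        return np.round(self.times / dt).astype(np.int64)

    def on_grid(self, dt: float, atol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.times - np.round(self.times / dt) * dt) < atol))


@dataclass(frozen=True)
class SpikePattern:
    """A multi-afferent input: one spike train per synapse, shared duration."""

    trains: tuple
    duration: float

    def __post_init__(self) -> None:
        trains = tuple(
            tr if isinstance(tr, SpikeTrain) else SpikeTrain(np.asarray(tr, float))
            for tr in self.trains
        )
        for tr in trains:
            if len(tr) and tr.times[-1] > self.duration:
                raise ValueError("spike time beyond pattern duration")
        object.__setattr__(self, "trains", trains)

    @property
    def n_afferents(self) -> int:
        return len(self.trains)


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane potential sampled at every grid time, plus emitted spikes.

    ``values[k]`` is the potential at t = k*dt including the reset
    contributions of all *earlier* output spikes; a grid time appears in
    ``output_spikes`` iff this pre-reset value reached the threshold.
    """

    values: np.ndarray
    output_spikes: SpikeTrain
    dt: float = 1.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


class PspCache:
    """Per-pattern tables of kernel and exponential sums at every grid time.

    ``psp[i, k]`` = sum over spikes t_i^j < k*dt of K(k*dt - t_i^j); the two
    exponential tables carry the tau_m / tau_s parts separately so that the
    voltage time-derivative needed by the learning rule is also a table read.
    Storage is N * T/dt per table.
    """

    def __init__(self, pattern: SpikePattern, params: NeuronParams):
        self.pattern = pattern
        self.params = params
        n = params.n_steps(pattern.duration)
        self.n_steps = n
        lags = np.arange(n) * params.dt
        self.decay_m = np.exp(-lags / params.tau_m)
        decay_s = np.exp(-lags / params.tau_s)
        N = pattern.n_afferents
        self.exp_m = np.zeros((N, n))
        self.exp_s = np.zeros((N, n))
        for i, train in enumerate(pattern.trains):
            for s in train.indices(params.dt):
                if s + 1 < n:
                    self.exp_m[i, s + 1 :] += self.decay_m[1 : n - s]
                    self.exp_s[i, s + 1 :] += decay_s[1 : n - s]
        self.psp = params.v_norm * (self.exp_m - self.exp_s)

    def free_potential(self, weights: np.ndarray) -> np.ndarray:
        """Reset-free weighted PSP superposition at every grid time."""
        return weights @ self.psp


def psp_matrix(pattern: SpikePattern, params: NeuronParams) -> np.ndarray:
    """Accumulated-PSP table with entry (i, k) = sum_{t_i^j < k dt} K(k dt - t_i^j)."""
    return PspCache(pattern, params).psp


def _threshold_spikes(
    v_free: np.ndarray, params: NeuronParams, decay_m: np.ndarray
) -> np.ndarray:
    """Grid indices where the reset-corrected potential reaches threshold."""
    from ._kernels import spike_scan

    return spike_scan(np.ascontiguousarray(v_free), params.theta, float(decay_m[1]))


def simulate(
    pattern: SpikePattern,
    weights: Sequence[float],
    params: NeuronParams,
    stop_at: float | None = None,
    voltage_noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
    cache: PspCache | None = None,
) -> VoltageTrace:
    """Integrate the LIF neuron over the grid and return its voltage trace.

    A spike is emitted whenever the potential reaches ``theta`` (at most one
    per grid step); each spike subtracts a theta-sized exponential from all
    later times.  ``stop_at`` truncates the simulation (the trace covers
    [0, stop_at] only), which the learning loop uses to avoid integrating
    past the first error.  ``voltage_noise_sd`` adds an independent
    zero-mean Gaussian draw to the potential at every step before the
    threshold comparison; it models background membrane noise at evaluation
    time and requires ``rng``.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (pattern.n_afferents,):
        raise ValueError(
            f"expected {pattern.n_afferents} weights, got shape {weights.shape}"
        )
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    if cache is None:
        cache = PspCache(pattern, params)
    n = cache.n_steps
    if stop_at is not None:
        if stop_at > pattern.duration:
            raise ValueError("stop_at beyond pattern duration")
        n = params.to_index(stop_at) + 1
    v = cache.free_potential(weights)[:n].copy()
    if voltage_noise_sd:
        if rng is None:
            raise ValueError("voltage noise requires an rng")
        v += rng.normal(0.0, voltage_noise_sd, size=n)
    spike_idx = _threshold_spikes(v, params, cache.decay_m)
    for s in spike_idx:
        if s + 1 < n:
            v[s + 1 :] -= params.theta * cache.decay_m[1 : n - s]
    times = np.asarray(spike_idx, dtype=float) * params.dt
    return VoltageTrace(values=v, output_spikes=SpikeTrain(times), dt=params.dt)


# ---------------------------------------------------------------------------
# Pattern file format: CSV of (channel, time_ms) plus a JSON sidecar with the
# pattern geometry.  Round-trips exactly for grid-aligned integer-ms times.


def write_pattern(
    path: str | Path, pattern: SpikePattern, dt: float = 1.0
) -> None:
    path = Path(path)
    rows = [
        (i, t)
        for i, train in enumerate(pattern.trains)
        for t in train.times
    ]
    df = pd.DataFrame(rows, columns=["channel", "time_ms"])
    df.to_csv(path, index=False)
    meta = {
        "n_afferents": pattern.n_afferents,
        "duration_ms": pattern.duration,
        "dt_ms": dt,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_pattern(path: str | Path) -> tuple[SpikePattern, float]:
    """Read a pattern written by :func:`write_pattern`; returns (pattern, dt)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    trains = []
    for i in range(int(meta["n_afferents"])):
        t = np.sort(df.loc[df["channel"] == i, "time_ms"].to_numpy(float))
        trains.append(SpikeTrain(t))
    pattern = SpikePattern(tuple(trains), float(meta["duration_ms"]))
    return pattern, float(meta["dt_ms"])
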