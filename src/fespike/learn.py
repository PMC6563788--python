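"""First-error learning (FE-Learn) for precisely timed output spikes.

The neuron is trained to emit one spike inside a small tolerance window
centred on each desired spike time, in chronological order, and to stay
silent elsewhere.  Each training epoch the output is scanned for the
*first* wrong spike time t_err, which falls in one of three categories:

  a — a spike outside every tolerance window;
  b — a second spike inside an already-satisfied window;
  c — a window whose upper edge passed without any spike (t_err is the
      desired time itself).

Exactly one weight update is applied per epoch, at t_err.  For a missed
window (type c) the weights are incremented along the gradient of the
potential at t_err, including chain-rule terms through the earlier output
spikes — evaluated, for stability, at the earlier *desired* times and
scaled by a factor S_r:

    dw_i = lambda1 * [ sum_{t_i^j < t_err} K(t_err - t_i^j)
           + S_r * sum_j  dV(t_err)/dt_j * dt_j/dV(t_j) * dV(t_j)/dw_i ]

where dV(t_err)/dt_j = -(theta/tau_m) exp(-(t_err - t_j)/tau_m) is the
sensitivity of the reset term to the j-th earlier spike, and
dt_j/dV(t_j) = -1 / (dV/dt at t_j) follows from a linear-crossing
approximation of the threshold passage.  For a stray spike (type a/b) the
update is a plain decrement dw_i = -lambda2 * sum K(t_err - t_i^j); the
chain terms are deliberately omitted so that correctly placed earlier
spikes are not disturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NeuronParams, PspCache, SpikePattern, SpikeTrain, _threshold_spikes

__all__ = [
    "LearnConfig",
    "ErrorEvent",
    "TrainRecord",
    "tolerance_windows",
    "find_first_error",
    "voltage_time_derivative",
    "weight_increment",
    "weight_decrement",
    "train",
    "save_train_record",
    "DEGENERATE_VDOT_TOL",
]

# below this |dV/dt| a threshold crossing is treated as degenerate and the
# corresponding chain-rule term is skipped (linear-crossing assumption invalid)
DEGENERATE_VDOT_TOL = 1e-6


@dataclass(frozen=True)
class LearnConfig:
    """Hyper-parameters of one FE-Learn training run.

    epsilon is the tolerance-window width in grid steps and must be odd
    (an even width spans the same grid points as the next odd one);
    s_r scales the chain-rule contributions of earlier desired spikes to a
    weight increment; lambda1/lambda2 are the increment/decrement learning
    rates.  Weights are initialised from N(init_mean, init_sd^2).
    """

    epsilon: int = 1
    s_r: float = 1.0
    lambda1: float = 0.005
    lambda2: float = 0.005
    max_epochs: int = 10_000
    seed: int = 0
    init_mean: float = 0.01
    init_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.epsilon < 1 or self.epsilon % 2 == 0:
            raise ValueError("epsilon must be a positive odd number of grid steps")
        if self.s_r < 0:
            raise ValueError("s_r must be >= 0")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")


@dataclass(frozen=True)
class ErrorEvent:
    """The first wrong output spike time of a trial and its category."""

    t_err: float
    kind: str  # 'a' | 'b' | 'c'


@dataclass
class TrainRecord:
    converged: bool
    epochs_to_converge: int | None
    weights: np.ndarray
    c_history: np.ndarray
    best_c: float
    best_epoch: int
    error_log: list[tuple[str, float]] = field(default_factory=list)


def tolerance_windows(
    desired: SpikeTrain, epsilon: int, dt: float = 1.0
) -> np.ndarray:
    """Closed intervals [t_d - h, t_d + h], h = (epsilon-1)/2 * dt.

    Raises ValueError if any two windows overlap (the window width must be
    smaller than the gap between consecutive desired spikes).
    """
    if epsilon < 1 or epsilon % 2 == 0:
        raise ValueError("epsilon must be a positive odd number of grid steps")
    h = (epsilon - 1) / 2 * dt
    td = desired.times
    win = np.column_stack([td - h, td + h])
    if len(td) > 1 and np.any(win[1:, 0] <= win[:-1, 1]):
        raise ValueError("tolerance windows overlap: desired spikes too close")
    return win


def find_first_error(
    actual: SpikeTrain,
    desired: SpikeTrain,
    epsilon: int,
    dt: float = 1.0,
) -> ErrorEvent | None:
    """Scan time forward, matching output spikes to windows chronologically.

    Each window accepts at most its first in-window spike.  The earliest
    violation is returned: a stray spike (a), a duplicate within a matched
    window (b), or a window closing unmatched (c, reported at the desired
    time itself).  A window closing and a later stray spike never compete;
    when both would be detected while processing one output spike, the
    missed window (type c) takes precedence.  Returns None iff every window
    matched exactly once and no stray spikes exist.
    """
    win = tolerance_windows(desired, epsilon, dt)
    td = desired.times
    m = len(td)
    j = 0
    for t in actual.times:
        while j < m and win[j, 1] < t:
            return ErrorEvent(t_err=float(td[j]), kind="c")
        if j < m and win[j, 0] <= t <= win[j, 1]:
            j += 1
        elif j > 0 and t <= win[j - 1, 1]:
            return ErrorEvent(t_err=float(t), kind="b")
        else:
            return ErrorEvent(t_err=float(t), kind="a")
    if j < m:
        return ErrorEvent(t_err=float(td[j]), kind="c")
    return None


_KINDS = {0: "a", 1: "b", 2: "c"}


def _first_error_online(
    cache: PspCache,
    weights: np.ndarray,
    params: NeuronParams,
    desired_idx: np.ndarray,
    half_width: int,
    v_free: np.ndarray | None = None,
) -> tuple[ErrorEvent | None, int]:
    """Simulate and detect the first error in one pass, stopping at t_err.

    The potential after t_err is never evaluated.  Returns the error (or
    None at convergence) and the number of windows matched before it.
    """
    from ._kernels import first_error_scan

    if v_free is None:
        v_free = cache.free_potential(weights)
    code, idx, j = first_error_scan(
        v_free,
        params.theta,
        float(cache.decay_m[1]),
        desired_idx - half_width,
        desired_idx + half_width,
        desired_idx,
    )
    if code < 0:
        return None, j
    return ErrorEvent(float(idx * params.dt), _KINDS[code]), j


def voltage_time_derivative(
    t_spike: float,
    pattern: SpikePattern,
    weights: Sequence[float],
    prior_output: SpikeTrain,
    params: NeuronParams,
    cache: PspCache | None = None,
) -> float:
    """Left-sided dV/dt at an output spike time (mV/ms).

    Three terms: the synaptic-current rise over tau_s, the membrane decay
    over tau_m, and the recovery of the resets caused by earlier output
    spikes.  A value near zero signals a degenerate (grazing) crossing.
    """
    if cache is None:
        cache = PspCache(pattern, params)
    w = np.asarray(weights, float)
    k = params.to_index(t_spike)
    if len(prior_output) and prior_output.times[-1] >= t_spike:
        raise ValueError("prior_output must precede t_spike")
    rise = params.v_norm * (w @ cache.exp_s[:, k]) / params.tau_s
    decay = params.v_norm * (w @ cache.exp_m[:, k]) / params.tau_m
    reset = (
        params.theta
        / params.tau_m
        * np.sum(np.exp(-(t_spike - prior_output.times) / params.tau_m))
    )
    return float(rise - decay + reset)


def _increment(
    cache: PspCache,
    weights: np.ndarray,
    desired_before_idx: np.ndarray,
    k_err: int,
    config: LearnConfig,
    params: NeuronParams,
) -> np.ndarray:
    """Type-c weight increment, chain terms evaluated at the desired times."""
    dw = cache.psp[:, k_err].copy()
    d = desired_before_idx
    if config.s_r > 0 and d.size:
        es = weights @ cache.exp_s[:, d]
        em = weights @ cache.exp_m[:, d]
        # pairwise reset-recovery term between earlier desired times
        lag = d[:, None] - d[None, :]
        lower = np.tril(cache.decay_m[np.abs(lag)], k=-1)
        reset = params.theta / params.tau_m * lower.sum(axis=1)
        vdot = (
            params.v_norm * (es / params.tau_s - em / params.tau_m) + reset
        )
        # a true threshold crossing has positive slope; a vanishing or
        # negative slope at the substituted time invalidates the
        # linear-crossing inverse, so that term is skipped
        coeff = np.zeros(d.size)
        ok = vdot >= DEGENERATE_VDOT_TOL
        coeff[ok] = (
            params.theta / params.tau_m * cache.decay_m[k_err - d[ok]] / vdot[ok]
        )
        dw += config.s_r * (cache.psp[:, d] @ coeff)
    return config.lambda1 * dw


def weight_increment(
    pattern: SpikePattern,
    weights: Sequence[float],
    desired_before: SpikeTrain,
    t_err: float,
    config: LearnConfig,
    params: NeuronParams,
    cache: PspCache | None = None,
) -> np.ndarray:
    """Per-afferent weight change for a missed window (error type c).

    ``desired_before`` holds the desired spike times earlier than t_err;
    the chain-rule factors use these in place of the matched output times,
    scaled by ``config.s_r``.
    """
    if cache is None:
        cache = PspCache(pattern, params)
    w = np.asarray(weights, float)
    d_idx = desired_before.indices(params.dt)
    if d_idx.size and desired_before.times[-1] >= t_err:
        raise ValueError("desired_before must precede t_err")
    return _increment(cache, w, d_idx, params.to_index(t_err), config, params)


def weight_decrement(
    pattern: SpikePattern,
    t_err: float,
    config: LearnConfig,
    params: NeuronParams,
    cache: PspCache | None = None,
) -> np.ndarray:
    """Per-afferent weight change for a stray spike (error type a/b)."""
    if cache is None:
        cache = PspCache(pattern, params)
    return -config.lambda2 * cache.psp[:, params.to_index(t_err)]


def train(
    pattern: SpikePattern,
    desired: SpikeTrain,
    config: LearnConfig,
    params: NeuronParams | None = None,
    track_c: bool = True,
    cache: PspCache | None = None,
) -> TrainRecord:
    """Run FE-Learn until the output matches every window or the epoch budget ends.

    Each epoch: simulate, locate the first wrong spike time, apply exactly
    one increment (type c) or decrement (type a/b).  With ``track_c`` the
    correlation C of the full output against the desired train is recorded
    every epoch (this requires integrating past t_err); without it the
    simulation stops at the first error and C is computed only for the
    final weights.  Non-convergence within ``max_epochs`` is reported, not
    raised.
    """
    if params is None:
        params = NeuronParams()
    win = tolerance_windows(desired, config.epsilon, params.dt)  # validates
    del win
    half = (config.epsilon - 1) // 2
    if cache is None:
        cache = PspCache(pattern, params)
    rng = np.random.default_rng(config.seed)
    weights = rng.normal(config.init_mean, config.init_sd, pattern.n_afferents)
    d_idx = desired.indices(params.dt)

    c_hist: list[float] = []
    err_log: list[tuple[str, float]] = []
    converged = False
    epochs = None

    # the filtered desired train is fixed; cache it for per-epoch C values
    from .metrics import DEFAULT_SIGMA, gaussian_filter_train

    vd = gaussian_filter_train(desired, DEFAULT_SIGMA, pattern.duration, params.dt)
    norm_d = float(np.linalg.norm(vd))

    def full_c(v_free: np.ndarray) -> float:
        spikes = _threshold_spikes(v_free, params, cache.decay_m)
        if spikes.size == 0 or len(desired) == 0:
            return 1.0 if spikes.size == 0 and len(desired) == 0 else 0.0
        if np.array_equal(spikes * params.dt, desired.times):
            return 1.0
        va = gaussian_filter_train(
            spikes * params.dt, DEFAULT_SIGMA, pattern.duration, params.dt
        )
        return float(min(va @ vd / (np.linalg.norm(va) * norm_d), 1.0))

    for epoch in range(config.max_epochs):
        v_free = cache.free_potential(weights)
        err, n_matched = _first_error_online(
            cache, weights, params, d_idx, half, v_free=v_free
        )
        if track_c:
            c_hist.append(full_c(v_free))
        if err is None:
            converged = True
            epochs = epoch
            break
        err_log.append((err.kind, err.t_err))
        if err.kind == "c":
            weights += _increment(
                cache, weights, d_idx[:n_matched], params.to_index(err.t_err),
                config, params,
            )
        else:
            weights += weight_decrement(pattern, err.t_err, config, params, cache)

    if not converged and track_c:
        c_hist.append(full_c(cache.free_potential(weights)))
    if not c_hist:
        c_hist.append(full_c(cache.free_potential(weights)))
    c_arr = np.asarray(c_hist)
    best_epoch = int(np.argmax(c_arr))
    return TrainRecord(
        converged=converged,
        epochs_to_converge=epochs,
        weights=weights,
        c_history=c_arr,
        best_c=float(c_arr[best_epoch]),
        best_epoch=best_epoch,
        error_log=err_log,
    )


def save_train_record(record: TrainRecord, out_dir: str | Path, prefix: str = "run") -> None:
    """Write the per-epoch log, summary JSON and final weights as text files."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(record.c_history)
    kinds = [k for k, _ in record.error_log] + [""] * (n - len(record.error_log))
    terrs = [t for _, t in record.error_log] + [np.nan] * (n - len(record.error_log))
    pd.DataFrame(
        {
            "epoch": np.arange(n),
            "C": record.c_history,
            "error_type": kinds[:n],
            "t_err": terrs[:n],
        }
    ).to_csv(out / f"{prefix}_log.csv", index=False)
    (out / f"{prefix}_result.json").write_text(
        json.dumps(
            {
                "converged": record.converged,
                "epochs": record.epochs_to_converge,
                "best_C": record.best_c,
                "best_epoch": record.best_epoch,
            }
        )
    )
    pd.DataFrame(
        {"afferent": np.arange(record.weights.size), "weight": record.weights}
    ).to_csv(out / f"{prefix}_weights.csv", index=False)
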