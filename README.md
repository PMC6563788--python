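# fespike

Supervised learning of precisely timed spikes in a leaky integrate-and-fire
(LIF) neuron by **first-error learning**: in every training epoch the
neuron's output is scanned chronologically against tolerance windows around
the desired spike times, and the synaptic weights are adjusted exactly once,
at the first wrong output spike time.

The package is aimed at computational-neuroscience work on spike-timing
based learning rules: it provides the neuron simulator, the learning rule,
Poisson pattern generators with noise models, the correlation accuracy
metric, a spatiotemporal-pattern classification harness, and a
dynamic-target population decoding strategy, plus a small CLI.

## Model

The membrane potential of a current-based LIF neuron with N afferents is

```
V(t) = Σ_i w_i Σ_{t_i^j < t} K(t − t_i^j) − ϑ Σ_{t_s^j < t} exp(−(t − t_s^j)/τ_m)
K(x) = V_norm [exp(−x/τ_m) − exp(−x/τ_s)],   V_norm = β^{β/(β−1)}/(β−1),  β = τ_m/τ_s
```

with τ_m = 10 ms, τ_s = 2.5 ms, ϑ = 1 mV, dt = 1 ms by default; a spike is
emitted when V reaches ϑ and the reset term applies to all later times.

Training places a tolerance window of width ε grid steps around each desired
spike time. The first violation of chronological window matching is one of

* **a** — a spike outside every window,
* **b** — a second spike inside an already-matched window,
* **c** — a window that closed without a spike (reported at the desired time).

For a type-c error at `t_err` the weights are incremented along
`λ₁ · dV(t_err)/dw_i`, including chain-rule terms through the earlier desired
times scaled by a factor `S_r`; for a/b errors they are decremented by
`λ₂ · Σ K(t_err − t_i^j)`. Learning accuracy is the correlation metric
`C = v_d·v_o / (|v_d||v_o|)` of the Gaussian-filtered (σ = 2 ms) desired and
actual trains.

## Worked example

```python
import numpy as np
from fespike import (NeuronParams, LearnConfig, poisson_pattern,
                     desired_poisson_train, train)

params = NeuronParams()                       # tau_m=10, tau_s=2.5, theta=1, dt=1
pattern = poisson_pattern(400, 10.0, 800.0, seed=1)          # 400 x 10 Hz inputs
desired = desired_poisson_train(100.0, 800.0, min_gap=1.0, seed=2)  # 100 Hz target
config = LearnConfig(epsilon=1, s_r=0.0, max_epochs=60_000, seed=3)
record = train(pattern, desired, config, params)
print(f"converged={record.converged} epochs={record.epochs_to_converge} "
      f"best_C={record.best_c:.4f}")
```

prints

```
converged=True epochs=10049 best_C=1.0000
```

i.e. after 10 049 single-update epochs the neuron reproduces all ~80 target
spike times exactly (at ε = 1 and dt = 1, convergence forces C = 1).

The same protocols are available from the shell:

```
fespike experiment duration_sweep --trials 5 --seed 0 --out results/
fespike generate --n-afferents 400 --duration 800 --out patterns/
```

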