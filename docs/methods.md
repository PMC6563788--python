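# Methods

## Neuron model and time grid

The simulator implements a current-based leaky integrate-and-fire neuron:
the membrane potential is the weighted sum of double-exponential
postsynaptic potentials (PSPs) minus an exponentially decaying reset of
size ϑ per emitted output spike. All spike times live on a discrete grid
with step `dt` (default 1 ms); sums over history use strict inequality, so
a spike at exactly time t contributes from t + dt onward. The threshold
test is `V(t) ≥ ϑ` with at most one output spike per grid step.

Defaults: τ_m = 10 ms, τ_s = 2.5 ms, ϑ = 1 mV, dt = 1 ms. The kernel
normalisation V_norm = β^{β/(β−1)}/(β−1), β = τ_m/τ_s, makes the PSP peak
exactly 1 at lag x* = τ_mτ_s/(τ_m−τ_s)·ln β (≈ 4.62 ms at the defaults).

Per pattern, the accumulated PSP of every afferent at every grid time is
precomputed once (`PspCache`, N·T/dt entries per table, with the τ_m and
τ_s exponential sums stored separately so the learning rule's voltage
derivative is also a table read). The simulator and both weight-update
rules only read these tables; simulation during training stops at the
first wrong spike time, so the potential past the error is never
evaluated.

## The learning rule

Tolerance windows of width ε grid steps (ε odd; an even width covers the
same grid points as the next odd value) are centred on the desired times;
they must be pairwise disjoint. Window matching is chronological and each
window accepts only its first in-window spike. Error types: stray spike
(a), duplicate within a matched window (b), missed window (c, reported at
the desired time). When a window closes unfilled at the same step at
which a stray spike is classified, the missed window takes precedence —
increments restore progress toward the chronological matching goal; the
choice is fixed for reproducibility.

Type-c increment: Δw_i = λ₁ [ Σ K(t_err−t_i^j) + S_r Σ_j (∂V(t_err)/∂t_j)
(∂t_j/∂V(t_j)) (∂V(t_j)/∂w_i) ], with the chain factors evaluated at the
earlier *desired* times rather than the matched output times, and the
crossing inverse ∂t_j/∂V = −1/(dV/dt at t_j) from a linear-crossing
approximation. A crossing slope below 1e−6 mV/ms — including any
non-positive slope — marks a degenerate crossing and that term is
skipped: a true threshold passage has positive slope, and a negative
substituted slope would flip the term's sign and actively push earlier
matched spikes out of their windows (observed before the guard was
tightened). Type-a/b decrement: Δw_i = −λ₂ Σ K(t_err−t_i^j); the chain
term is omitted so correctly placed earlier spikes are not disturbed.

Learning rates default to λ₁ = λ₂ = 0.005 — small enough that a single
update moves the potential at t_err monotonically in the intended
direction on the 400-afferent tasks. Weights initialise from
N(0.01, 0.1²) (the common variance reading of "N(0.01, 0.01)"; the SD is
configurable). Convergence means zero error events; the per-epoch
correlation C is recorded and the maximum reported, mirroring how the
learning-accuracy curves are usually summarised.

### Stability of the chain term (S_r)

With S_r ≥ ~0.5 and window widths ε ≥ 3 on long 100 Hz target trains, the
rule as specified enters a sustained limit cycle: the increment at a
missed window also boosts the PSP columns of earlier desired times, whose
kernels peak a few ms later — exactly where stray spikes then appear just
before the failing window; the subsequent decrements cancel the progress
(best C plateaus near 0.8 without converging in 60k epochs). With
S_r = 0 the same tasks converge reliably (≈10⁴ epochs) to the
window-limited C. A second failure mode appears in multi-pattern
training: a crossing whose substituted slope is barely above the
degeneracy guard inflates its chain coefficient (∝ 1/slope) enormously,
and a single such event can send a neuron's weights into runaway growth
(observed once in the classification protocol: weight norm ~565, firing
at every grid step). The experiment protocols (sequence-learning sweeps
and classification) therefore run with S_r = 0 by default;
`LearnConfig` keeps S_r = 1 as the library default, the ε×S_r sweep
scans the full range, and the chain term itself is verified against
finite-difference oracles. The chain term's benefit is robustness
(stronger drive at earlier desired times), not converged accuracy.

## Synthetic data

Inputs are homogeneous Poisson trains discretised as Bernoulli-per-bin
(p = rate·dt/1000, at most one spike per 1 ms step, times dt..T). All
generators are pure functions of (parameters, seed); afferents use
spawned sub-seeds so afferent i's train is independent of the afferent
count.

Desired output trains are Poisson at the stated output rate with two
constraints: (i) spikes closer than ε·dt to the previously accepted spike
are rejected so tolerance windows stay disjoint, and (ii) no target
earlier than 2·dt — a target at dt has no earlier grid step on which an
input spike could raise the potential, making its increment identically
zero and freezing training (a 160 Hz target hits this with probability
~0.16 per trial).

Input noise (evaluation-time only; training is deterministic): Gaussian
timing jitter (SD σ_j) rounded back to the grid and clipped to [0, T],
independent per-spike deletion (p = 0.05 in the robustness protocol), and
merged Poisson insertions (1 Hz). Membrane noise is an i.i.d. zero-mean
Gaussian added to V at every 1 ms step before thresholding; no √dt
scaling since dt is fixed at 1 ms.

The 3-class classification fixture: three base patterns (400 afferents,
5 Hz, 200 ms), 25 training + 25 test samples per class obtained by 3 ms
Gaussian jitter, and arithmetic desired templates 5:15:170, 15:15:180,
25:15:190 ms. What the generator does *not* emulate: rate modulation,
afferent correlations, realistic sensory encodings — passing these tasks
shows the rule learns and separates random spatiotemporal patterns, not
that it handles natural stimuli.

## Classification harness

One learning neuron per class; every epoch presents all 75 training
samples in a seeded random order. A neuron's desired train is its class
template for own-class samples and the empty train otherwise (any spike
is then a stray → decrement), so foreign classes are learned as silence.
A sample is classified by the neuron whose output correlates best with
its own template (ties → lowest class index). After 300 epochs this
harness reaches training accuracy 1.0 and test accuracy ~1.0 on the
fixture at every window width tested (ε ∈ {1,…,9}) — the per-class
silence objective makes the 3-class task linearly separated by the C
score, so the width-dependent generalisation dip reported for a
*single-neuron* readout (one neuron emitting a class-specific template
per sample class) does not appear here. A single-neuron variant was
evaluated and shows the dip qualitatively (test accuracy 0.88 at ε=7 vs
0.71 at ε=1) but at levels several points below the published curve;
the per-class harness is the one shipped and tested.

## Dynamic-target decoding

For multi-neuron readouts without a fixed target train, each
presentation derives the desired train from the neuron's own trace:
non-target neurons must stay silent (decrement at their first stray
spike); a target neuron adopts its subthreshold voltage maximum t_max
(earliest on ties) as an extra desired time whenever V_max exceeds an
encoding threshold ϑ_e < ϑ (V_max = ϑ_e counts as below — conservative,
avoids oscillation), or accepts its output as-is otherwise. An increment
and a decrement are never scheduled in the same presentation. Category
prediction counts "activated" neurons — per index position, the neuron
with the strictly largest spike count across groups (ties activate no
one) — and picks the group with most activations (ties: larger total
count, then lowest index). An optional multiplicative threshold margin
(train-time only) is available and off by default.

## Problem sizes and numerical choices

The acceptance runs use 5 trials (3 for the longest-duration band) in
place of the original 20, and 5 dataset seeds per classification width;
epoch budget 60 000 for sequence learning (ε = 1 runs need 10⁴–5·10⁴
single-update epochs), 300 for classification. The Gaussian filter
(σ = 2 ms) is evaluated exactly over the whole grid — no truncation —
and C of two identical trains (and of two empty trains) is exactly 1;
one empty train gives 0. The inner per-step loops (threshold scan and
online first-error scan) are JIT-compiled; everything else is table
reads and BLAS.

## Known limitations

* The chain-term instability above means the published claim that wide
  windows converge for any S_r ∈ [0, 2] is not reproduced by this
  formulation; see the ε×S_r sweep.
* Converged C at wide windows runs slightly above the published values
  (0.976 vs ≈0.96 at ε=3; 0.93 vs ≈0.89 at ε=5): the min-gap rejection
  keeps windows disjoint (a hard precondition here, apparently not
  enforced in the original trains, whose tight gaps force off-centre
  matches), and S_r = 0 lets spikes settle nearer window centres.
* The per-class classification harness saturates at 100 % test accuracy
  on the fixture, so the width-dependent overfitting levels are not
  reproduced (see above).
* Single-layer, single-neuron credit assignment only; no delays, no
  multilayer extension, sub-ms event-driven simulation out of scope.
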