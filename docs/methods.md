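# Methods

This note documents the modelling choices behind `snnlab`: the equations as
implemented, the parameters that matter, what the synthetic data does and
does not emulate, and the numerical decisions a user should know before
trusting (or extending) a result.

## Membrane model and integration

Neurons are leaky integrate-and-fire units,
`τ_m du/dt = −(u − E_L) + R·I(t)`, with threshold `V_th`, instantaneous
reset to `V_reset` and an absolute refractory clamp of `t_ref` at
`V_reset`. Defaults (all configurable, NEST-style key aliases accepted):

| parameter | default | unit | meaning |
|---|---|---|---|
| τ_m | 10 | ms | membrane time constant |
| C_m | 250 | pF | capacitance (R = τ_m/C_m = 40 MΩ) |
| E_L | −70 | mV | resting potential |
| V_th | −55 | mV | spike threshold |
| V_reset | −70 | mV | reset potential |
| t_ref | 2 | ms | refractory period (NEST `iaf` default) |
| dt | 0.1 | ms | simulation resolution |

Each step applies the exact solution for piecewise-constant input. We
implement it in the increment form

    u ← u + (u_∞ − u) · (1 − e^(−dt/τ_m)),    u_∞ = E_L + R·I,

computed with `expm1`. This is algebraically identical to
`u_∞ + (u − u_∞)e^(−dt/τ)` but numerically better behaved at the rheobase
fixed point: the increment form approaches `u_∞` strictly monotonically from
below in float64, whereas the textbook form rounds onto `u_∞` after a few
hundred milliseconds of exactly-rheobase drive and would produce a spurious
threshold crossing. Consequently the rheobase current
`C_m(V_th − E_L)/τ_m = 375 pA` never fires at any simulation length, while
376 pA fires at `τ_m·ln(15.04/0.04) ≈ 59.3 ms`; the firing boundary is
exact and dt-independent.

Threshold is tested as `u ≥ V_th` at step boundaries; spike times are the
end of the crossing step (no within-step interpolation). Spike trains
therefore live on the dt grid, and interspike intervals are never below
`t_ref`.

## Noise model

A noise generator injects `I_k = μ + σ·η_k` pA with `η_k` i.i.d. standard
normal, one draw per refresh interval (default: the simulation step), held
constant within it. Two deliberate conventions:

- Draws are **not** scaled by `1/√dt`. This copies the NEST
  `noise_generator` device semantics, so the effective variance of the
  injected charge depends on dt. It is not a consistent discretisation of a
  white-noise (Wiener) process; anyone changing dt should re-calibrate σ.
- Each attached neuron owns an independent child stream spawned from the
  experiment seed, so per-neuron noise is uncorrelated and the whole
  simulation is reproducible from `(config, seed)`.

With σ = 0 the generator degenerates to a constant μ and the stochastic
simulation reduces *exactly* (bitwise) to the deterministic one.

## Latency encoding and preprocessing

Pixel values map to single spike latencies through the quadratic law
`S = (V/255 − 1)²·(T_stop − T_start) + T_start` on a default window of
[0, 10] ms with a 5 ms silent gap between presentations. The law is a
strictly decreasing bijection: brighter ⇒ earlier, with the finest temporal
resolution at the bright end where most stimulus information lives.

Background tailoring: pixels below `cutoff_value` (default 1, i.e. exact
zeros) emit no spike when an image drives a network. Without this, the
hundreds of background pixels all spike simultaneously at `T_stop` and that
synchronous burst dominates every output neuron, erasing the rank-order
structure of the foreground. The pure value→latency map stays total; the
tailoring is applied at the network input stage.

The three-layer experiments preprocess 28×28 images with fixed 4×4 kernels
(uniform average, horizontal-, vertical- and diagonal-edge detectors;
positive coefficients sum to 1), stride 1, valid — giving 25×25 — then 2×2
stride-2 pooling with floor truncation to 12×12 (max pooling by default,
mean available). Negative conv responses are rectified before pooling.
Kernels are deliberately parameter-free; the weights of such a fixed
front end are not part of the learning problem.

## Plasticity

The pair-based STDP window

    f(Δt) =  A₊ e^(−Δt/τ₊)   Δt > 0     (LTP)
          = −A₋ e^(Δt/τ₋)    Δt < 0     (LTD)
          =  0               Δt = 0

is accumulated over **all** pre/post spike pairs of one presentation
(presentations are independent trials; no cross-presentation pairing).
`f(0) = 0` because exactly simultaneous spikes carry no causal order.
Module defaults are the canonical pair-based values A₊ = 0.005,
A₋ = 1.05·A₊, τ₊ = τ₋ = 20 ms; weights are hard-clipped to [0, 1] and
initialised i.i.d. uniform on [0.3, 0.7] from the experiment seed.

Supervision: after each presentation, synapses onto the true-label output
receive the raw pair sum (so anticausal background input is still
depressed), and synapses onto every *other* output that spiked receive
minus the magnitude of its pair sum. The mismatch penalty keeps timing
sensitivity rather than using a flat penalty.

Two training-loop choices matter and are easy to miss:

- **Teacher spike.** During training a supervising spike is forced on the
  true-label output neuron at 1 ms into the presentation (disable with
  `teacher_latency=None`). A pair-based rule cannot re-potentiate a neuron
  that never spikes; without the teacher, early mismatch depression
  silences output columns irreversibly and the network collapses to
  chance. With it, each column keeps receiving causal potentiation from
  its class's early (bright) pixels regardless of its momentary
  excitability — the classic teaching-signal construction for supervised
  STDP.
- **Desk-scale amplitudes.** The scripted classification experiments use
  A₊ = 0.02 (A₋ = 1.05·A₊). The canonical 0.005 assumes an asymptotic
  training regime; at ~10³ total presentations the larger amplitude reaches
  a comparable weight structure within five passes.

## Networks and decoding

Input (two-layer) and memory (three-layer) neurons are *relay* neurons for
the image code: an encoded pixel forces a spike at its latency regardless
of membrane state, which keeps the timing of layer-1 spikes exactly equal
to the encoding law. Relay spikes respect refractoriness. The same neurons
still integrate their noise current, so noise can add spikes — but only by
genuinely crossing threshold.

Synapses deliver delta-current pulses: a presynaptic spike injects
`w·I_syn` pA into each target for one step. Default `I_syn` = 1200 pA
(≈ 0.48 mV per unit-weight pulse), chosen so a few tens of coincident
mid-weight afferents reach threshold from rest — the regime in which
first-spike timing actually discriminates stimuli. Much smaller pulses
leave the output layer silent; much larger ones make every column fire on
the first step and reduce decoding to tie-breaking.

Decoding is rank-order: earliest output spike wins; ties break to the
larger spike count, then the lowest index; if nothing fires the prediction
falls back to label 0 and is flagged.

A provable consequence of this architecture: with σ = 0 and μ below
rheobase, an attached noise generator cannot change any spike anywhere in
the pipeline (relay spikes are forced, noise alone cannot cross threshold,
outputs receive no noise). The accuracy-vs-μ sweep over (0, 30] pA is
therefore exactly flat at matched seeds, and the "best grid point ≥
baseline" property holds with equality. The simulator exploits this as an
exact fast path (input membranes are not stepped when noise provably cannot
fire them); enabling σ > 0 or μ ≥ 375 pA switches to full input-layer
simulation automatically.

## Structural growth

Growth is a minimal temporal-Hebbian coincidence rule: for each ordered
pair (i, j) of memory neurons within Chebyshev distance 3 on the 12×12 grid
(the four feature channels are spatially co-located), a synapse i→j is
created at weight 0.5 when at least `coincidence_threshold` spike pairs
with `0 < t_j − t_i ≤ 10 ms` occur within one presentation window. Synapses
are never removed, and grown synapses are structural records only — they do
not inject current during the growth run, because feeding them back would
add a positive-feedback loop the experiment is not designed to control.

The default threshold is 1 coincidence. Under the experiment's drive
(μ = 400 pA, σ = 0) a neuron spikes at most once per 15 ms window (its
interspike interval is `t_ref + τ_m·ln(16) ≈ 29.7 ms`), so any
per-window threshold above 1 can never be met and all conditions would
trivially grow nothing.

The growth runs simulate continuous time (membrane state persists across
presentation windows) and initialise memory membranes uniformly on
[E_L, V_th) from the experiment seed. Both choices are load-bearing for
condition (b): without persistence a 400 pA drive never reaches threshold
inside a single 15 ms window, and without heterogeneous initial states all
noise-driven neurons fire in perfect synchrony, making every spike-time
difference exactly zero — which the strictly causal rule correctly refuses
to count.

Conditions: (a) images only, (b) noise only on a seeded random subset of
120 memory neurons (~20% of 576), (c) both. At matched seeds, (c) grows
strictly more synapses than (a) (noise spikes add causal pairs that image
latencies alone do not produce), (b) grows a nonzero set, and subthreshold
noise (300 pA < 375 pA) in (b) grows exactly zero — the membrane fixed
point −58 mV never reaches threshold.

## Synthetic data

`generate_digits` renders the ten digits from fixed handwriting-like stroke
paths (loops, arcs, diagonals) with antialiased edges, applies ±1 px
translation jitter and 2% salt noise, and balances labels round-robin. Two
properties were designed in deliberately, because the downstream code
depends on them the way it depends on real handwritten digits:

- *graded intensities* — stroke edges take intermediate values, so spike
  latencies spread across the window instead of collapsing onto one
  instant (a binary rendering degenerates rank-order coding into
  simultaneous ties);
- *partial, non-nested class overlap* — every class keeps a region no
  other class covers. Schematic renderings such as seven-segment digits
  are pixel-subsets of the digit 8 and are provably inseparable under the
  match/mismatch rule.

What the generator does **not** emulate: within-class shape variability
(every "3" is the same glyph up to translation and salt noise), stroke
thickness/slant variation, and the long-tailed intensity statistics of real
scans. Passing tests therefore demonstrate that the pipeline learns and
generalises over translation and pixel noise at desk scale — not that it
reaches any particular accuracy on real handwritten data. Real MNIST files
can be swapped in through the IDX reader (`read_idx`), which round-trips
the standard big-endian ubyte format bit-exactly.

## Problem sizes and determinism

The scripted experiments default to 200 training / 100 test images, five
training passes, a μ grid of {2, 4, …, 30} pA with five seeds, and 10–30
presentation windows per growth run over ten seeds — sizes chosen so the
full suite reruns comfortably on a laptop core. Every experiment writes a
manifest (config snapshot + seeds); deterministic runs regenerate their
tables bit for bit, and stochastic runs are reproducible given the recorded
seeds. All randomness flows from `numpy.random.default_rng` seeded per
experiment, with per-neuron noise streams spawned as child seed sequences.

## Known limitations

- The noise convention ties σ's meaning to dt (see above).
- Delta-current synapses have no rise/decay kinetics; `I_syn` is a free
  amplitude, not a biophysical conductance.
- The supervised rule with teacher forcing is a design completion: it is
  one defensible reading of "strengthen on match, weaken on mismatch", not
  a published algorithm with reference accuracies.
- The growth rule's window/threshold/radius are artifact-defined defaults;
  absolute synapse counts (and ratios such as "how much more growth with
  noise") depend on them and should be read qualitatively.
- Multiplicative and 1/f (pink) noise are out of scope.
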