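# snnlab

Desk-scale simulations of how background noise currents interact with a
spiking neural network's learning — for computational neuroscientists and
students who want a small, fully reproducible stack rather than a full
simulator deployment.

The package models persistent background brain activity (of the kind
attributed to the default mode network) as an additive Gaussian white-noise
current injected into leaky integrate-and-fire neurons, and asks two
questions:

1. does a small subthreshold noise mean help a latency-coded, STDP-trained
   network classify digit images? (accuracy-vs-noise-mean sweep)
2. does suprathreshold noise drive extra structural growth of lateral
   synapses in a memory layer? (three-condition growth experiment)

## The model

**Membrane.** Each neuron follows the leaky integrate-and-fire equation

    τ_m du/dt = −[u(t) − u_rest] + R·I(t),       τ_m = R·C

with threshold `V_th`, instantaneous reset to `V_reset`, and refractory
period `t_ref`. Defaults are the standard NEST values: τ_m = 10 ms,
C_m = 250 pF (so R = 40 MΩ), u_rest = V_reset = −70 mV, V_th = −55 mV.
Integration uses the exact exponential solution per step, so the rheobase
C_m(V_th − u_rest)/τ_m = 375 pA is analytically clean: 375 pA never fires,
376 pA always does.

**Noise.** A generator attached to a neuron injects `I_k = μ + σ·η_k` pA,
one independent Gaussian draw per simulation step, held constant within the
step (the NEST `noise_generator` convention — *not* a √dt-scaled Wiener
discretisation).

**Latency code.** A pixel value `V ∈ [0, 255]` becomes one spike at

    S = (V/255 − 1)² · (T_stop − T_start) + T_start

— brighter pixels fire earlier (rank-order coding). Exact-zero background
pixels are tailored away and never spike.

**Learning.** All-pairs pair-based STDP,
`Δw = Σ_a Σ_b f(t_post − t_pre)` with the usual exponential window
(LTP for causal pairs, LTD for anticausal), supervised by a match/mismatch
rule: synapses onto the true-label output get the raw pair sum, synapses
onto any other output that spiked get −|pair sum|. A teacher spike forced on
the true output during training keeps silent columns learnable.

**Structural growth.** Memory-layer neurons within a Chebyshev
neighbourhood grow a directed synapse i→j when spikes occur in causal order
(0 < t_j − t_i ≤ window) during a presentation. Synapses are only added,
never removed.

## Worked example

```python
from snnlab import SNNClassifier, generate_digits

ds = generate_digits(300, seed=0)          # synthetic handwritten-style digits
train, test = ds.split(200)
clf = SNNClassifier(n_iterations=5, random_state=0).fit(train.images, train.labels)
for row in clf.history_:
    print(row)
print("held-out accuracy:", clf.score(test.images, test.labels))
```

prints

```
{'iteration': 1, 'train_acc': 0.38}
{'iteration': 2, 'train_acc': 0.65}
{'iteration': 3, 'train_acc': 0.755}
{'iteration': 4, 'train_acc': 0.81}
{'iteration': 5, 'train_acc': 0.825}
held-out accuracy: 0.64
```

i.e. five supervised-STDP passes over 200 images take the 784→10 network
from chance (10%) to 82.5% on the training set and 64% on 100 held-out
images — real learning from spike timing alone, at desk scale.

The same experiments are scriptable from the shell:

```
snnlab rheobase --mu-min 370 --mu-max 380        # locates the 375/376 pA boundary
snnlab sweep-mu --iters 5 --seeds 0,1,2,3,4 --out sweep
snnlab grow --presentations 30 --seeds 0..9 --out growth
snnlab make-digits --n 200 --seed 0 --out digits # IDX files, MNIST-compatible
```

Every experiment writes a JSON manifest (full config + seeds) from which its
tables regenerate bit for bit.

## Layout

- `snnlab.lif` — exact-update LIF stepper, closed-form oracle, rheobase
- `snnlab.noise` — seeded Gaussian current generators (per-neuron streams)
- `snnlab.encoding` — latency code + 4×4 conv / 2×2 pool preprocessing
- `snnlab.stdp` — pair-based STDP window, all-pairs sums, supervised update
- `snnlab.network` — two-/three-layer wiring, presentation loop, decoding
- `snnlab.growth` — coincidence-gated synapse growth, condition experiment
- `snnlab.data` — procedural digit generator, IDX reader/writer
- `snnlab.experiments` / `snnlab.cli` — scripted sweeps with manifests
- `snnlab.classifier` — scikit-learn estimator wrapper (`SNNClassifier`)

See `docs/methods.md` for modelling assumptions, parameter rationale and
known limitations.
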