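# wagernet

A computational model of the *uncertain-option* (post-decision
wagering) task: a monkey watches a random-dot-motion stimulus, must
later saccade left or right according to the perceived direction, and
on half of the trials is offered a third, *sure* target that pays a
smaller but guaranteed reward. The fraction of sure choices behaves
like a read-out of decision confidence.

`wagernet` implements a discrete three-choice attractor network that
solves this task as a perceptual decision among three alternatives
with a delayed stimulation protocol — no explicit confidence variable
anywhere:

* **Spiking tier** — 1000 conductance-based leaky integrate-and-fire
  neurons in five all-to-all connected populations: three selective
  pools (L, R, S; 160 cells each), a nonspecific excitatory pool (320)
  and one inhibitory pool (200). Synapses carry AMPA (external +
  recurrent), NMDA (voltage-gated, saturating) and GABA currents;
  recurrent weights follow the standard structured scheme (w₊ = 1.5
  within a selective pool, w₋ = 0.878 from any other excitatory pool
  onto a selective pool, 1 elsewhere). Each neuron receives
  independent Poisson background input (800 sources × 3 Hz).
* **Mean-field tier** — the stationary reduction of the same network:
  coupled self-consistency equations ν_x = φ(μ_x, σ_x) solved by
  relaxation (forward Euler, 0.1 ms), with attractor enumeration,
  bifurcation scans over the common stimulus intensity λ, and
  basin-boundary bisection in the (ν_L, ν_R) plane.
* **Behavioral tier** — trial ensembles with the published decision
  rule (population rate crossing ϑ = 28 Hz and staying above it for
  50 ms), psychometric functions, the conditional sure-choice map
  P(S | ν_L, ν_R), decision-time bimodality, the X-pattern of sure
  choices in correct vs error trials, and the reward trade-off
  P(correct) + P(S)·w_S.

The central claim the package reproduces: a *multistable* regime — two
decision attractors coexisting with a symmetric "mixed" attractor
during the stimulus — is what lets the network both decide and remain
flexible enough to take a later-offered third option.

## Worked example

Attractor landscape at λ = 50 Hz, balanced evidence (Δλ = 0):

```python
>>> from wagernet import MeanFieldParams, enumerate_attractors
>>> params = MeanFieldParams.from_network()
>>> land = enumerate_attractors(params, lam=50.0, dlam=0.0, condition="stimulus")
>>> for fp in land.fixed_points:
...     print(f"{fp.classification:12s} nu_L={fp.nu[0]:5.1f}  nu_R={fp.nu[1]:5.1f}")
mixed        nu_L= 26.1  nu_R= 26.1
decision_L   nu_L= 40.8  nu_R=  2.5
decision_R   nu_L=  2.5  nu_R= 40.8
```

Three stable states: a left-choice attractor, its mirror image, and
the symmetric mixed state whose basin straddles the diagonal — the
multistable regime. Scanning λ with the same machinery shows the
spontaneous state (≈ 2.8 Hz) destabilizing just above λ = 1 Hz, the
mixed state stabilizing in the low-20s, and the decision attractors
disappearing near λ = 60 Hz.

A reduced spiking ensemble from the shell:

```bash
wagernet simulate --preset smoke --n-trials 5 --seed 1 --out out/
wagernet analyze psychometrics out/trials.csv --out out/
wagernet meanfield --scan 0:70:1 --out out/
```

`out/trials.csv` holds one row per trial (condition, seed, early and
final choice, decision time from motion onset, the (ν_L, ν_R) snapshot
taken in the 50 ms before sure-target onset, change-of-mind flag).
The `multistable` preset (λ = 50 Hz, ϑ = 28 Hz) reproduces the
behavioral statistics; `bistable` (λ = 15 Hz, ϑ = 24 Hz) is the
control regime in which decision times lose their bimodality.

## Layout

| module | contents |
|---|---|
| `wagernet.params` | neuron/synapse/network parameter sets, YAML profiles |
| `wagernet.protocol` | per-pool input time courses (targets, motion, sure target, saccade signal) |
| `wagernet.network` | the spiking network and its numba integration kernel |
| `wagernet.meanfield` | self-consistency equations, fixed points, bifurcations, basins |
| `wagernet.trials` | trial ensembles, rate estimation, decision rule, classification |
| `wagernet.analysis` | psychometrics, sure-choice maps, decision-time and X-pattern analyses |
| `wagernet.presets`, `wagernet.cli` | named run configurations and the `wagernet` command |

`docs/methods.md` documents the model equations, the stimulation
protocol, every tunable parameter with its default and rationale, the
numerical choices, and the known limitations (in particular where the
finite-size spiking network and its mean-field reduction part ways).
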