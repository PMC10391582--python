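# engramsim

Spiking-network simulation of memory engrams in an impaired hippocampal
circuit: recall of stored memories, rescue of recall by slow-gamma
stimulation of interneurons, learning of a new memory under a composite
plasticity rule, and the bifurcation analysis that explains when persistent
activity can exist.

## Who this is for

Computational neuroscientists studying how synaptic impairment — reduced
connection probability *C*, neuronal loss, weakened synapses, or
excitation-inhibition imbalance — degrades memory function in
attractor-network models, and how interventions (duty-cycled interneuron
suppression at gamma frequencies, increased excitability) can partially
restore it.

## The model

A randomly connected conductance-based E-I network of leaky
integrate-and-fire neurons (default 2,000 excitatory + 400 inhibitory).
Each neuron obeys

    τ_k dV/dt = V_L − V + G_E(t)(E_E − V) + G_I(t)(E_I − V),

with conductances built from bi-exponential AMPA/NMDA/GABA kernels, 400
background Poisson trains per neuron, Tsodyks-Markram short-term plasticity
on excitatory presynapses, and — during learning — a long-term rule on all
E→E synapses combining triplet STDP, cubic heterosynaptic restraint toward
a preferred weight w̃, and a small transmitter-induced increment per
presynaptic spike (weights floored at 0.001):

    dw/dt = S_post·A·z_pre·z_post^slow − S_pre·B·z_post
            − S_post·β·z_post³((w − w̃)/w̃)³ + δ₁·S_pre.

Memories are engrams: disjoint groups of 200 excitatory neurons with
elevated mutual weights. A cued engram can enter a *persistent state*
(self-sustained firing above 5 spikes/s after the cue ends) — the model's
proxy for recall. Recall quality is quantified by the persistence score
(rectified closeness of each persistent duration to the ideal inter-cue
interval) and the overlapping proportion (intersection-over-union of all
engrams' persistent-state time sets — spurious co-activation of memories).
Integration is clock-driven RK2 at dt = 0.05 ms with linear spike-time
interpolation. See `docs/methods.md` for the full model account and the
desk-scale (600 E / 120 I) calibration used by tests and examples.

## Worked example

Recall of two engrams on the desk-scale circuit, with and without 40 Hz
rescue stimulation, at a strongly impaired connectivity (C = 0.16):

```python
from engramsim import (CueSchedule, RescueSpec, build_network,
                       recall_metrics, run_recall, run_rescue, scaled_config)

cfg = scaled_config(seed=1, C=0.16, n_engrams=2, g_EI=0.33)
graph = build_network(cfg)
schedule = CueSchedule(engrams=[0, 1], warmup_s=5.0, f_cue=3.5)

plain = recall_metrics(run_recall(graph, schedule, seed=1))
rescued = recall_metrics(run_rescue(graph, schedule, RescueSpec(), seed=1))

print(f"no rescue : score={plain['persistence_score']:.2f} "
      f"overlap={plain['overlapping_proportion']:.3f}")
print(f"40Hz/50%  : score={rescued['persistence_score']:.2f} "
      f"overlap={rescued['overlapping_proportion']:.3f}")
```

Output:

```
no rescue : score=0.93 overlap=0.022
40Hz/50%  : score=0.89 overlap=0.046
```

The persistence score is the mean over engrams of
ReLU(1 − |T_persist − 10 s| / 10 s): a score near 1 means each cued engram
stayed active from its cue's end until the next cue. The overlapping
proportion measures how much of the total persistent time both memories
were active simultaneously — the side effect of rescue stimulation. Across
seeds at this impaired connectivity, rescue raises the persistence score of
runs whose unaided recall fails early, at the cost of a higher overlap (see
`tests/test_acceptance.py::TestRescueSign`).

A single-engram hysteresis analysis:

```python
from engramsim import build_network, run_bifurcation, scaled_config

res = run_bifurcation(build_network(scaled_config(seed=1)), 2.5, seed=1)
print(res.ascending_switch, res.descending_switch, res.s_p, res.s_l)
```

Output: `2.9 1.7 0.8 0.4` — the engram ignites when the cue rate first
exceeds 2.9 Hz on the ascending branch and extinguishes at 1.7 Hz on the
descending branch; S_p = 0.8 Hz and S_l = 0.4 Hz are the distances from the
2.5 Hz background to the two switch points (the stability of the persistent
and the low-activity state).

## Command line

```sh
engramsim build --config cfg.yml --out graph.csv
engramsim recall|rescue|learn|bifurcation --config cfg.yml --out outdir/
engramsim pair --pre-rate 10 --post-rate 10 --ppick 0.3 --seed 1
engramsim fixtures --out raster.csv
engramsim metrics --raster raster.csv --n-neurons 40 --duration-ms 30000 \
    --engram-size 20 --n-engrams 2
```

Rasters are CSV (`time_ms,neuron_id`), configs YAML, run manifests JSON.

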