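# msp — homeostatic structural plasticity in spiking networks

`msp` simulates cortical rewiring after a focal loss of input. It is aimed
at computational neuroscientists studying how *homeostatic structural
plasticity* — neurons growing and retracting synaptic contacts to keep
their own activity near a set-point — reshapes network topology after
deafferentation, as in focal retinal lesions or the cortical consequences
of subcortical stroke.

## The model

A sheet of Izhikevich neurons (320 excitatory on a jittered 20×16 grid,
150 µm pitch, plus 80 interstitial inhibitory neurons) fires under noisy
external drive and recurrent synaptic input:

    dv/dt = 0.04 v² + 5 v + 140 − u + I_syn + I_ext
    du/dt = a (b v − u),      spike at v ≥ 30 mV → v ← c, u ← u + d

Each spike adds β = 0.001 to an intracellular calcium trace that decays
with τ = 10 s; calcium is the neuron's read-out of its own mean firing
rate. Synapses are not weights but *counts*: a synapse is a bound pair of
one axonal element (bouton) of the presynaptic and one dendritic element
(spine) of the postsynaptic neuron. Element counts z follow a Gaussian
growth rule of calcium,

    dz/dt = ν (2 exp(−((Ca − ξ)/ζ)²) − 1),   ν = 10⁻⁴ ms⁻¹,

whose zero crossings are pinned at a minimum calcium η (η_A for axonal,
η_D for dendritic elements) and at the homeostatic set-point ε = 0.7;
within the homeostatic range Ca ∈ [0.65, 0.75] the rate is clamped to
zero. When a neuron loses elements that are bound in synapses, synapses
break (multiplicity-proportional selection); vacant axonal and dendritic
elements recombine into new synapses with probability proportional to the
product of the vacancy counts and a Gaussian distance kernel
(σ = 150 µm), and unused vacant elements decay (τ_vac = 10 updates).

The experiment protocol grows a network from zero connectivity under
elevated input (8 mV/ms, ramping down to 5), then permanently silences
the external input of a rectangular *lesion projection zone* (LPZ) and
follows the rewiring for 12 000 connectivity updates (= 24 weeks at the
1000-updates-per-14-days calibration). Three growth-parameter regimes are
shipped: `physiological` (η_A = 0.4 > η_D = 0.1, repair by ingrowth from
the intact zone), `recurrent` (η_A = η_D = 0.1, repair by massive
recurrent wiring), and `no_repair` (η_D = 0.4 > η_A = 0.1).

Topology is analyzed on the excitatory→excitatory multiplicity graph with
edge length 1/W: weighted characteristic path length, Fagiolo clustering,
small-worldness S = γ/λ against Erdős–Rényi nulls with the same synapse
count, Brandes betweenness centrality (with tolerance-based tie
detection), local/global efficiency, and degree distributions — whole
network and split by LPZ/intact region.

## Worked example

```python
import pandas as pd
pd.set_option("display.precision", 3)
from msp import run_experiment

res = run_experiment("physiological", seed=1, scale="mini")
s = res.series
onset = res.config.schedule.lesion_onset
print(s.loc[s.t.isin([onset - 1, onset + 500, 4999]),
            ["t", "mean_ca_lpz", "mean_ca_intact", "w_lpz_lpz", "w_intact_lpz"]])
```

```
         t  mean_ca_lpz  mean_ca_intact  w_lpz_lpz  w_intact_lpz
1999  1999        0.664           0.662        219           107
2500  2500        0.292           0.672         58           180
4999  4999        0.299           0.675         61           182
```

Before the lesion (t = 1999) all neurons sit inside the homeostatic
calcium range [0.65, 0.75]. Silencing the LPZ input collapses LPZ
calcium; recurrent LPZ wiring (`w_lpz_lpz`) is pruned while new synapses
grow in from the intact zone (`w_intact_lpz`, 107 → 182) — the outside-in
repair signature. In this scaled-down run the repair is partial: border
LPZ neurons return to the homeostatic range while interior neurons remain
silent (see `docs/methods.md`, Known limitations). Topology over the same
run (via `msp.topology.topology_record`) shows the whole network becoming
more random, S = 1.75 at lesion onset → 1.16 at the end, with λ ≈ 0.89
staying near one.

A command-line interface mirrors the library:

```bash
msp run --preset physiological --scale mini --seed 1 --out out/
msp topology --edges out/snapshots/T5000.edges
```

`msp run` writes `series.csv` (per-update calcium and region-pair synapse
counts), `snapshots/T*.edges` (directed weighted edge lists), a
`topology.csv` of the metric battery on the snapshots, and the fully
resolved configuration as provenance.

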