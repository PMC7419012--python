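# olivenet

Simulation and analysis of electrically coupled inferior-olive (IO)
networks: how gap-junction coupling, modulated by GABAergic input onto the
coupled spines, controls the synchrony, dimensionality and chaotic character
of olivary spike trains.

IO neurons fire at ~1 spike/s and are the most densely electrically coupled
cells in the adult mammalian brain.  The package implements the full
computational chain used to study this system when only spike times are
observable:

- a conductance-based 3×3 network model — each neuron a soma/dendrite pair
  with four glomerular spine compartments carrying the gap junctions
  (conductance *g_c*, heterogeneous ±20% per junction) and a GABAergic
  conductance *g_i* that shunts the junctional path
  (`olivenet.model`);
- the effective coupling between neighbours,
  *g_eff = g_s·g_c / (2g_c + g_i + g_s)* with the spine axial conductance
  *g_s* = 0.1 mS/cm², and the current-injection coupling-coefficient
  protocol that validates it (`olivenet.inference`, `olivenet.model`);
- 67-dimensional spatiotemporal feature vectors (rate, local variation,
  auto-/cross-correlograms, minimal-distance fractions) with a 3-component
  PCA embedding (`olivenet.features`);
- segmental Bayesian inference of (*g_i*, *g_c*) on a 41×41 conductance
  grid with hierarchical pooling across 50-s segments and Bayesian model
  averaging over four synaptic-noise levels (`olivenet.inference`);
- population metrics: zero-lag 10-ms synchrony and participation-ratio
  dimensionality *d* = 1/Σλ̃² (`olivenet.population`);
- chaos metrics for spike trains: boundary-aware spike-train edit distance,
  shortest-path-repaired recurrence plots at a fixed 10% recurrence rate,
  and the complexity entropy 1/H of the diagonal-line-length distribution;
  plus Benettin/QR Lyapunov spectra and the Kaplan–Yorke dimension for the
  deterministic model (`olivenet.chaos`);
- surrogate generators with controllable shared-source synchrony, and an
  end-to-end pipeline with a CLI (`olivenet.synthetic`,
  `olivenet.pipeline`, the `olivenet` command).

The three pharmacological regimes studied throughout are tagged `CBX`
(carbenoxolone, gap-junction blocker), `CON` (control) and `PIX`
(picrotoxin, GABA-A blocker), with per-condition mean conductances
(*g_i*, *g_c*) = (1.02, 0.88), (1.15, 1.19) and (0.72, 1.16) mS/cm².

## Worked example

```python
from olivenet import (NeuronParams, NetworkConfig, build_network, simulate,
                      coupling_coefficient_protocol, effective_coupling)
from olivenet.population import dataset_synchrony

for cond, g_i, g_c in [("CBX", 1.02, 0.88), ("CON", 1.15, 1.19),
                       ("PIX", 0.72, 1.16)]:
    print(f"{cond}: g_eff = {effective_coupling(0.1, g_c, g_i):.3f} mS/cm^2")

net = build_network(NeuronParams(g_i=0.72), NetworkConfig(mean_g_c=1.16, seed=2))
ds = simulate(net, duration=150.0, seed=2, noise=True).dataset
print(f"PIX network: mean rate {ds.mean_rate():.2f} spikes/s, "
      f"10-ms synchrony {dataset_synchrony(ds):.3f}")

quiet = build_network(NeuronParams(g_i=1.15),
                      NetworkConfig(mean_g_c=1.19, heterogeneity=0.0,
                                    cal_heterogeneity=0.0, seed=0))
print(f"CON coupling coefficient: {coupling_coefficient_protocol(quiet):.4f}")
```

prints

```
CBX: g_eff = 0.031 mS/cm^2
CON: g_eff = 0.033 mS/cm^2
PIX: g_eff = 0.037 mS/cm^2
PIX network: mean rate 2.36 spikes/s, 10-ms synchrony 0.178
CON coupling coefficient: 0.0122
```

The effective coupling rises from the gap-junction-blocked to the
GABA-blocked condition; the simulated picrotoxin network fires at
~2.2 spikes/s with substantial 10-ms synchrony; and the noise-free
current-injection protocol yields a coupling coefficient of ~0.012 at the
control means — steady-state voltage deflections in a neighbour are ~1.2%
of the injected cell's.

A reduced end-to-end run (surrogate-backed, ~2 min):

```sh
olivenet reproduce-demo --out-dir demo_run --seed 0
```

which reports, per condition, rate / synchrony / normalized dimensionality /
g_eff / complexity, e.g. rates 0.44 / 1.39 / 2.17 spikes/s and synchrony
0.026 / 0.058 / 0.189 for CBX / CON / PIX.

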