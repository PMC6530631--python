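# cerescaffold

Scaffold reconstruction and spiking simulation of the cerebellar
microcircuit: density-driven 3-D cell placement, a geometry- and
ratio-based connectome, conductance-based leaky integrate-and-fire (LIF)
network simulation, and the spike-train analyses used to validate the
reconstruction. It is aimed at computational neuroscientists who want a
reproducible cerebellar cortex + deep-cerebellar-nuclei (DCN) network
whose wiring comes from convergence/divergence ratios and oriented
axonal/dendritic field geometries rather than detailed morphologies.

The reference network is a 400 × 400 µm² patch of mouse cerebellar cortex
(330 µm tall: granular, Purkinje and molecular layers) over a
200 × 200 × 600 µm³ DCN block — about 97k cells (Golgi, glomeruli,
granule, Purkinje, basket, stellate, DCN) and ~1.7M synapses. Cells are
placed by a bounded self-avoiding random walk (sublayers of height 1.5 ×
soma diameter; scatter term from the density-derived compound-sphere
radius ε = (3/(4πρ))^⅓ − r), Purkinje cells on a non-overlapping planar
grid. Candidate synapses come from intersecting fields (e.g. parallel
fibers bounded to 400 µm along the transversal axis) and are pruned to
configured ratios with anisotropic Gaussian distance-decay. Every
non-glomerulus cell is a conductance-based LIF neuron

    C_m dV/dt = −(C_m/τ_m)(V − E_L) + I_e + g_exc(E_exc − V) + g_inh(E_inh − V)

integrated at 0.1 ms with exponential synapses; glomeruli are parrot
relays for the imposed mossy-fiber trains. See `docs/methods.md` for the
full model description and its limitations.

## Worked example

```python
import numpy as np
from cerescaffold import (default_config, place_all, build_connectome,
                          assemble, simulate, default_protocol,
                          make_stimulus, analysis)

cfg = default_config(seed=1)
table = place_all(cfg, seed=1)            # ~8 s
print(table.counts())
conn = build_connectome(table, cfg, seed=1)
net = assemble(table, conn, cfg)
proto = default_protocol(cfg)             # 1 Hz background + 150 Hz burst
stim = make_stimulus(table, proto, seed=1)
spikes = simulate(net, stim, proto.T_sim)  # ~25 s for 1 s of activity

grc = table.ids_of("GrC")
labels = analysis.classify_population(spikes, grc, (0, 300), (300, 350),
                                      grc_rule=True)
exc = grc[labels == "excited"]
rate = spikes.count_in(exc, 300, 350) / len(exc) / 0.05
print(f"{len(exc)} excited granule cells at {rate:.1f} Hz during the burst")
```

prints (seed 1):

```
{'GoC': 216, 'Glom': 7200, 'GrC': 88218, 'PC': 72, 'BC': 600, 'SC': 600, 'DCNC': 12}
33576 excited granule cells at 114.8 Hz during the burst
```

i.e. the granule layer saturates just below its density target (the
packing limit), and the mossy-fiber burst drives the excited granule-cell
subgroup at ~115 Hz over a ~2 Hz background — the hallmark
sparse-baseline / high-frequency-burst regime of the granular layer. The
same run silences all DCN cells through convergent Purkinje inhibition
within ~2 ms of the first Purkinje volley.

The same pipeline is scriptable from the shell:

```bash
scaffold place --seed 1 --out placement.h5
scaffold connect --placement placement.h5 --seed 1 --out connectome.h5
scaffold simulate --placement placement.h5 --connectome connectome.h5 \
                  --protocol default --seed 1 --out spikes.h5
scaffold analyze --placement placement.h5 --spikes spikes.h5 \
                 --protocol default --report report.json
```

`scaffold simulate --switch-off stellate_to_purkinje ...` silences whole
connection types; protocols `cs_control`/`cs_inoff` and `oscillation`
cover the centre-surround and slow-oscillation experiments.

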