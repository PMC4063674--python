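# hcodb

Brute-force parameter screening and correlation analytics for a
conductance-based model of the leech heartbeat half-center oscillator
(HCO).

Central pattern generators keep producing functional rhythms even
though the underlying membrane and synaptic conductances vary severalfold
between animals.  One proposed explanation is that the conductances do
not vary freely: functional solutions live on low-dimensional, linearly
correlated subsets of parameter space.  `hcodb` is a toolkit for testing
that idea in a specific, well-studied circuit: two reciprocally
inhibitory leech heart interneurons modeled as single compartments with
eight Hodgkin-Huxley-type voltage-gated currents (I_Na, I_P, I_CaF,
I_CaS, I_h, I_K1, I_K2, I_KA), a leak, and both graded and
spike-mediated inhibitory synapses.

The package provides, as importable modules and a thin CLI:

- **`hcodb.model`** — the full model definition (gating kinetics,
  currents, synapse dynamics, the canonical parameter set) and the
  coupled ODE right-hand side; every current has the form
  `I = ḡ m^x h^y (V − E)`.
- **`hcodb.simulate`** — the screening protocol: a cached 200 s
  canonical warm-up supplies every instance's initial conditions, then
  100 s settle + 100 s record.  A numba exponential-Euler kernel
  (dt = 0.05 ms) drives sweeps; a scipy adaptive backend cross-checks it.
- **`hcodb.classify`** — spike/burst detection and the activity
  taxonomy: HCO, burster, and their *realistic* subgroups (period
  5–15 s, spike frequency 8–25 Hz, duty cycle 50–70%), plus
  silent/spiking/plateau/irregular sub-labels.
- **`hcodb.sweep`** — grid enumeration over the eight screened
  parameters (seven conductances at 0–175% of canonical, E_Leak at
  −70…−50 mV; 8⁷ × 5 = 10,485,760 points), resumable sweep
  orchestration, and a SQLite instance store with views for the four
  groups of interest.
- **`hcodb.stats`** — centered unscaled PCA with main-component
  selection (cumulative variance > 95%), 3D orthogonal-distance
  regression lines (centroid + first principal component), two-sample
  Kolmogorov–Smirnov tests, axis histograms and pairwise count maps.
- **`hcodb.families`** — one-parameter families (instances identical
  except in a single parameter), size censuses, and period-sensitivity
  deltas along ḡ_P, ḡ_K2, ḡ_Leak.
- **`hcodb.synth`** — seeded generators of parameter clouds with an
  embedded linear correlation, bursting voltage traces with exact known
  metrics, and family tables with a prescribed census, so every
  analysis stage is testable without a large sweep.

See `docs/methods.md` for the model equations, protocol, definitions,
and the package's design decisions.

## Worked example

Simulate single instances through the full protocol (the first call
also runs the 200 s canonical warm-up):

```text
$ hcodb simulate --params canonical
category: HCO  realistic: False
period: 8.781 s  duty: 49.9%  freq: 13.0 Hz  phase: 0.499

$ hcodb simulate --params "P=25,K2=25,Leak=50,E_Leak=-50"
category: HCO  realistic: True
period: 12.929 s  duty: 50.9%  freq: 12.7 Hz  phase: 0.511
```

The canonical pair bursts in exact antiphase (phase 0.50) with an
8.8 s period and 13 Hz spiking — the leech signature — but its duty
cycle sits just under the 50% floor of the realistic band, so only the
`HCO` label applies.  Scaling the persistent Na⁺ and persistent K
conductances down together (second call) slows the rhythm to 12.9 s and
lifts the duty cycle into the realistic range: an illustration of the
screen's central finding, that ḡ_P, ḡ_K2 and ḡ_Leak trade off along a
line rather than acting independently.

The same pipeline scales to grids.  A sweep plus analytics, in Python:

```python
from hcodb import (GridSpec, SweepStore, run_sweep, query_group,
                   build_analysis_matrix, pca_group)

grid = GridSpec(levels={"SynS": (100,), "SynG": (100,), "CaS": (100,),
                        "h": (100,), "P": (0, 50, 100, 150),
                        "K2": (0, 50, 100, 150), "Leak": (0, 50, 100, 150)})
store = SweepStore("screen.sqlite")
report = run_sweep(grid, store=store)        # resumable; n_jobs=... to parallelize
hcos = query_group(store, "hcos")
pca = pca_group(build_analysis_matrix(hcos, drop_synaptic=True))
print(report["counts"], pca.variance_pct.round(2), pca.n_main)
```

or from the shell: `hcodb sweep --db screen.sqlite ...`,
`hcodb analyze --db screen.sqlite --view realistic_bursters --what pca`,
`hcodb families --db screen.sqlite --vary K2`.

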