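# Methods

## The model

`hcodb` implements a two-cell half-center oscillator (HCO): two
identical single-compartment leech heart-interneuron models coupled by
reciprocal inhibition.  Each compartment carries eight voltage-gated
currents of Hodgkin-Huxley form

    I = gbar * m^x * h^y * (V - E_ion)

— fast Na (I_Na), persistent Na (I_P), fast and slow low-threshold Ca
(I_CaF, I_CaS), hyperpolarization-activated cation (I_h), delayed
rectifier (I_K1), persistent K (I_K2), fast transient K (I_KA) — plus an
ohmic leak.  Gate dynamics are first order,
`dx/dt = (x_inf(V) - x) / tau_x(V)`, with Boltzmann steady states
`x_inf = 1/(1 + exp(a(V + b)))` and sigmoid time constants
`tau = c + d/(1 + exp(A(V + b_tau)))`; I_h's steady state, I_Na's two
time constants and I_CaF's activation time constant take special forms.
All gating constants, reversal potentials (E_Na = 45 mV, E_Ca = 135 mV,
E_h = −21 mV, E_K = −70 mV, E_Syn = −62.5 mV), the membrane capacitance
(0.5 nF) and the synapse kinetics live in the packaged
`model_defs.json`; everything internal is SI (volts, seconds, siemens).

Two inhibitory synaptic pathways connect the cells:

- **Spike-mediated (SynS).**  Each presynaptic spike launches a
  difference-of-exponentials conductance waveform (rise 2 ms, decay
  11 ms, normalized to unit peak), scaled by a slow presynaptic
  modulation variable M (`M_inf = 0.1 + 0.9/(1 + exp(−1000(V + 0.04)))`,
  tau 200 ms).
- **Graded (SynG).**  A presynaptic "calcium pool" P integrates the
  inward part of I_CaF + I_CaS above a 10 pA threshold and is cleared at
  10 s⁻¹; the postsynaptic conductance is
  `gbar_SynG * P³/(10⁻³² + P³)`, a saturating, nondecreasing function of
  the pool.

The eleven maximal conductances and the leak reversal potential form
the free-parameter set; the canonical values are ḡ_Na = 200,
ḡ_P = 7, ḡ_CaF = 5, ḡ_CaS = 3.2, ḡ_h = 4, ḡ_K1 = 100, ḡ_K2 = 80,
ḡ_KA = 80, ḡ_Leak = 8, ḡ_SynS = 60, ḡ_SynG = 30 nS and
E_Leak = −60 mV.  The printed source for the synapse constants is partly
illegible in our working copy of the reference text, so those constants
were transcribed from the published model lineage and validated
behaviorally: with them, the canonical pair produces regular antiphase
bursting (period ≈ 8.8 s, spike frequency ≈ 13 Hz, duty cycle ≈ 50%,
relative phase 0.50) and the isolated canonical neuron fires tonically
at ≈ 7 Hz, both signatures of this model family.

## Simulation protocol

Every screened instance follows the same protocol:

1. **Warm-up.**  The canonical model runs for 200 s from a mildly
   asymmetric seed (one cell depolarized), ending with one cell bursting
   and the other inhibited.  This end state is cached and reused as the
   initial condition of *every* instance.
2. **Settle.**  After the parameters are changed, the instance runs
   100 s unrecorded to reach its attractor.
3. **Record.**  A further 100 s is recorded: spike times and peak
   potentials (logged during integration), the minimum membrane
   potential, and the longest continuous stretch above −20 mV.

The sweep integrator is a fixed-step exponential-Euler kernel
(dt = 0.05 ms, numba-compiled): gates relax exactly toward their
voltage-frozen steady states, and V relaxes toward the instantaneous
conductance-weighted reversal potential.  Gate steady states and
per-step decay factors are tabulated on a 10 µV grid from the exact
model functions and linearly interpolated.  The passive-membrane limit
is reproduced to machine precision, and the canonical period moves by
less than 1% when the step is varied over 0.025–0.1 ms (a tested
invariant).  An independent adaptive backend (scipy `solve_ivp`, RK45,
rtol 10⁻⁶/atol 10⁻⁹, max step 1 ms) with event-based synapse triggering
agrees with the fixed kernel to well under 0.5 mV RMS over one-second
segments from the shared initial conditions; it serves as the
cross-check, not the sweep engine.  Spike events trigger the partner
synapse at the upward −20 mV crossing; the recorded spike time is the
following local maximum.  Numerical blow-up flags the instance
`failed`; failed instances are stored, never dropped.

## Classification

The definitions used to label every instance:

- **Spike:** upward crossing of −20 mV, timed at the following local
  maximum of V.
- **Burst:** at least three spikes with internal gaps < 1 s; trains are
  split at gaps ≥ 1 s.
- **Cycle period:** interval between middle spikes of consecutive
  bursts (for even spike counts the middle spike is number ⌈n/2⌉,
  1-based).  Regularity is the CV (sample std / mean) of these
  intervals.
- **Duty cycle:** mean burst duration (first-to-last spike) over mean
  period, as a percentage.
- **Relative phase:** per cycle, the delay from a B-burst middle spike
  to the preceding A-burst middle spike divided by that A-to-A
  interval, averaged over cycles.
- **HCO:** both cells show ≥ 2 bursts in the trailing 40 s of the
  recorded window, every burst has uniform spikes (within-burst
  amplitude CV < 0.07), period CV < 0.05, mean phase in the *open*
  interval (0.45, 0.55), and at least one synaptic conductance is
  nonzero.  **Burster:** the same bursting/regularity rules with both
  synapses at zero.  **Realistic** instances additionally have period
  5–15 s, mean spike frequency 8–25 Hz and (HCOs only) duty cycle
  50–70%, all closed bounds.
- Non-bursting instances receive operational sub-labels: `silent` (no
  spikes), `plateau` (> 5 s continuously above −20 mV), `spiking`
  (spikes but < 2 bursts, e.g. tonic firing), `bistable-suspect`
  (isolated twins on different attractors), `irregular` (bursts that
  fail the regularity rules), `failed`.

Three points were genuinely open and were fixed as follows:

- **Spike amplitude** for the within-burst CV is the peak height above
  the −20 mV threshold.  Spike peaks straddle 0 V, so a CV of the raw
  peak potential is numerically meaningless (its mean can vanish); a
  positive height scale is the only reading under which the < 0.07
  criterion is usable.
- **Window edges.**  A burst whose first/last spike lies within 1 s of
  a recording-window edge may be truncated mid-burst; such bursts are
  excluded from all metrics (their spikes still count as activity).
  Without this rule the canonical instance itself misclassifies: a
  burst clipped at the window end corrupts the period and amplitude
  CVs.
- **Pair-level metrics** (period, frequency, duty) for the realistic
  test are the means of the two cells' values; the cells of an HCO are
  near-symmetric, so this choice is not load-bearing.

## The sweep database

The screen varies seven maximal conductances (SynS, SynG, P, K2, h,
CaS, Leak) over {0, 25, 50, 75, 100, 125, 150, 175}% of canonical and
E_Leak over {−70, −65, −60, −55, −50} mV: 8⁷ × 5 = 10,485,760 grid
points, of which 8⁵ × 5 = 163,840 (both synapses 0) are isolated twin
neurons.  Classified instances are stored in a single-file SQLite
database keyed by the parameter tuple, with SQL views for the four
groups of interest (HCOs, realistic HCOs, bursters, realistic
bursters).  Sweeps are resumable (stored points are never re-run) and
refuse to mix solver provenances.

## Analytics

- **PCA** is centered and *unscaled* (the convention of the classic
  `princomp`), applied to parameters in analysis units: conductances as
  fractions of canonical (0–1.75) and E_Leak in volts.  For isolated
  groups the two identically-zero synaptic columns are dropped (six
  columns).  *Main components* are the smallest leading set whose
  cumulative explained variance exceeds 95%.  Component signs follow a
  fixed convention (largest-magnitude coefficient negative).
- **3D ODR line** (total least squares): the line through the group
  centroid along the first principal component of the 3-D point set,
  which minimizes summed squared orthogonal distances; points may carry
  instance multiplicities as weights.
- **Two-sample KS test:** k = sup |ECDF difference| over the pooled
  sample (ties from the discrete level lattice are handled by the ECDF
  definition), with the asymptotic p-value using the classical
  small-sample correction and alpha = 0.05.
- **Families:** subsets of a group identical in all swept parameters
  but one; the census of family sizes measures robustness along that
  parameter, and the period change between a family's extreme members
  (last minus first, ascending in the varied value) measures the
  parameter's leverage on the period.

## Synthetic data

Three generators provide ground-truth inputs so every analysis stage is
testable without a large sweep; all are pure functions of (spec, seed):

- `gen_correlated_group`: a point cloud along an embedded unit
  direction with isotropic Gaussian noise, optionally snapped to the
  sweep lattice — the structure the PCA/ODR stage is meant to detect
  (noise σ = 0 puts all variance on the first component exactly).
- `gen_bursting_trace`: stereotyped two-neuron traces (triangular
  spikes above −20 mV on a −50 mV baseline) with exact prescribed
  period, duty cycle, spikes per burst, antiphase offset and within-
  burst amplitude CV; the classifier must recover each quantity to
  within one sampling interval (tested).
- `gen_family_table`: instance tables with a prescribed family-size
  census and optional per-family period sequences.

What these do *not* emulate: real conductance interactions, spike-shape
variability, multistability, or failure modes of integration.  Passing
the synthetic round-trips therefore validates the measurement and
analytics pipeline, not the biophysics; the biophysics is validated by
the canonical-instance signatures above and the sweep behavior.

## Problem sizes

The full screen (10.5 M instances) and full isolated screen (163,840)
are cluster-scale by construction.  The package's own test suite and
the acceptance script run desk-scale versions chosen once: the full
canonical protocol for single instances, toy grids (≤ 8 points) for
sweep-machinery tests, and a canonical-restricted sub-lattice sweep
(gP, gK2, gLeak ∈ {0, 50, 100, 150}%, all five E_Leak levels, CaS, h
and synapses at canonical; 320 coupled + 320 isolated instances) for
the acceptance summary.  Larger reproductions use the same entry points
with wider `GridSpec`s and are embarrassingly parallel across grid
points (`run_sweep(..., n_jobs=N)`).

## Known limitations

- The synapse constants rest on the published model lineage rather
  than a re-readable primary table (see above); the behavioral
  validation constrains them but cannot pin every digit.
- Exact group counts at boundary cases are sensitive to the spike
  amplitude convention and to integrator details at the 10⁻² level;
  boundary-sitting instances (e.g. duty cycle within a fraction of a
  percentage point of 50%) can flip the realistic flag.
- Isolated-neuron sub-labels (`spiking`, `plateau`, `bistable-suspect`,
  `irregular`) are operational conveniences, not validated taxonomy.
- Single compartment, fixed temperature, deterministic channels.
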