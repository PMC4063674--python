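"""Fixed-step exponential-Euler sweep kernel (numba).

The gate and membrane updates use the exponential-Euler scheme: each
gate relaxes exactly toward its (voltage-frozen) steady state, and the
membrane potential relaxes toward the instantaneous conductance-weighted
reversal potential.  Gate steady states and per-step decay factors
``exp(-dt / tau(V))`` are tabulated on a fine voltage grid (10 uV) from
the exact model functions and linearly interpolated, which keeps the
inner loop free of transcendental calls for the gates.

Spike events are logged during integration: an upward crossing of the
-20 mV threshold arms the detector and triggers the partner synapse's
waveform accumulators; the following local maximum is recorded as the
spike (time and peak potential).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import (CHANNEL_ORDER, IDX_CA, IDX_M, IDX_V, IDX_XD, IDX_XR,
                    NEURON_NVAR, HCOModel, ModelParameters, default_model,
                    gate_time_constant, steady_state_gate)

SPIKE_THRESHOLD = -0.02  # V

V_MIN, V_MAX, DV = -0.150, 0.100, 1e-5


@dataclass(frozen=True)
class KernelTables:
    """Voltage-indexed lookup tables for one step size ``dt``."""

    dt: float
    xinf: np.ndarray      # (n_gates, NV) steady states
    efac: np.ndarray      # (n_gates, NV) exp(-dt/tau)
    minf: np.ndarray      # (NV,) synaptic modulation steady state
    chan_E: np.ndarray    # (8,) reversal potential per channel
    chan_x: np.ndarray    # (8,) activation exponents
    chan_y: np.ndarray    # (8,) inactivation flags
    const: np.ndarray     # packed scalar constants, see build_tables


_TABLE_CACHE: dict[float, KernelTables] = {}


def build_tables(dt: float, model: HCOModel | None = None) -> KernelTables:
    """Tabulate gate kinetics for the given step size (cached per dt)."""
    if model is None and dt in _TABLE_CACHE:
        return _TABLE_CACHE[dt]
    m = model or default_model()
    V = np.arange(V_MIN, V_MAX + DV / 2, DV)
    gates = m.gate_specs()
    xinf = np.empty((len(gates), V.size))
    efac = np.empty_like(xinf)
    for i, (_, spec) in enumerate(gates):
        xinf[i] = steady_state_gate(spec, V)
        efac[i] = np.exp(-dt / gate_time_constant(spec, V))
    syn = m.synapse
    minf = np.asarray(syn.M_inf(V))
    chan_E = np.array([m.channels[c].E for c in CHANNEL_ORDER])
    chan_x = np.array([m.channels[c].x for c in CHANNEL_ORDER], dtype=np.int64)
    chan_y = np.array([m.channels[c].y for c in CHANNEL_ORDER], dtype=np.int64)
    const = np.array([
        m.canonical.C,                       # 0 membrane capacitance (F)
        syn.E,                               # 1 synaptic reversal (V)
        syn.norm_const,                      # 2 spike waveform normalization
        math.exp(-dt / syn.tau_decay),       # 3 Xd decay factor
        math.exp(-dt / syn.tau_rise),        # 4 Xr decay factor
        math.exp(-dt / syn.tau_M),           # 5 M decay factor
        syn.pool_buffer_rate,                # 6 Ca-pool buffering (1/s)
        syn.pool_saturation,                 # 7 Ca-pool saturation (A^3 s^3)
        syn.pool_threshold,                  # 8 Ca drive threshold (A)
        math.exp(-syn.pool_buffer_rate * dt),  # 9 Ca-pool decay factor
    ])
    tabs = KernelTables(dt=dt, xinf=xinf, efac=efac, minf=minf,
                        chan_E=chan_E, chan_x=chan_x, chan_y=chan_y, const=const)
    if model is None:
        _TABLE_CACHE[dt] = tabs
    return tabs


def gbar_vector(p: ModelParameters) -> np.ndarray:
    """Pack maximal conductances in kernel order (8 channels, Leak, SynS, SynG)."""
    return np.array([p.gbar[c] for c in CHANNEL_ORDER]
                    + [p.gbar["Leak"], p.gbar["SynS"], p.gbar["SynG"]])


@njit(cache=True, fastmath=True)
def _run(state, g, EL, I_inj, dt, nsteps, t0,
         xinf, efac, minf, chan_E, chan_x, chan_y, const,
         spk, amp, record_spikes, trace, trace_every):
    """Advance the two-neuron network ``nsteps`` steps of size ``dt``.

    ``state`` is the (2, 18) network state, modified in place.  Returns
    (n_spikes_A, n_spikes_B, minV_A, minV_B, max_above_A, max_above_B, ok).
    """
    C = const[0]; Esyn = const[1]; fnorm = const[2]
    dfac = const[3]; rfac = const[4]; mfac = const[5]
    Bpool = const[6]; Cpool = const[7]; Apool = const[8]; pfac = const[9]
    inv_dv = 1.0 / DV
    nv = xinf.shape[1]
    nspk = np.zeros(2, np.int64)
    minV = np.array([state[0, 0], state[1, 0]])
    prevV = np.array([state[0, 0], state[1, 0]])
    rising = np.zeros(2, np.bool_)
    armed = np.zeros(2, np.bool_)
    above = np.zeros(2)
    max_above = np.zeros(2)
    gch = np.zeros((2, 8))
    itr = 0
    ok = True
    for istep in range(nsteps):
        t = t0 + istep * dt
        if trace_every > 0 and istep % trace_every == 0:
            if itr < trace.shape[1]:
                trace[0, itr] = state[0, 0]
                trace[1, itr] = state[1, 0]
                itr += 1
        # gates, pools, M for both neurons
        for n in range(2):
            V = state[n, 0]
            fidx = (V - V_MIN) * inv_dv
            if fidx < 0.0:
                fidx = 0.0
            elif fidx > nv - 2:
                fidx = float(nv - 2)
            i0 = int(fidx)
            w = fidx - i0
            k = 1
            for c in range(8):
                xi = xinf[k - 1, i0] * (1.0 - w) + xinf[k - 1, i0 + 1] * w
                ef = efac[k - 1, i0] * (1.0 - w) + efac[k - 1, i0 + 1] * w
                m = xi + (state[n, k] - xi) * ef
                state[n, k] = m
                gc = g[c]
                if chan_x[c] == 1:
                    gc *= m
                elif chan_x[c] == 2:
                    gc *= m * m
                else:
                    gc *= m * m * m
                k += 1
                if chan_y[c] == 1:
                    xi = xinf[k - 1, i0] * (1.0 - w) + xinf[k - 1, i0 + 1] * w
                    ef = efac[k - 1, i0] * (1.0 - w) + efac[k - 1, i0 + 1] * w
                    h = xi + (state[n, k] - xi) * ef
                    state[n, k] = h
                    gc *= h
                    k += 1
                gch[n, c] = gc
            # presynaptic Ca pool from own Ca currents
            i_ca = gch[n, 2] * (V - chan_E[2]) + gch[n, 3] * (V - chan_E[3])
            drive = -i_ca - Apool
            if drive < 0.0:
                drive = 0.0
            pinf = drive / Bpool
            state[n, IDX_CA] = pinf + (state[n, IDX_CA] - pinf) * pfac
            # modulation variable
            mi = minf[i0] * (1.0 - w) + minf[i0 + 1] * w
            state[n, IDX_M] = mi + (state[n, IDX_M] - mi) * mfac
            # spike waveform accumulators
            state[n, IDX_XD] *= dfac
            state[n, IDX_XR] *= rfac
        # membrane update (synaptic conductances use partner's pre-state)
        for n in range(2):
            p = 1 - n
            V = state[n, 0]
            gs = g[9] * state[p, IDX_M] * fnorm * (state[p, IDX_XD] - state[p, IDX_XR])
            if gs < 0.0:
                gs = 0.0
            c3 = state[p, IDX_CA] ** 3
            gs += g[10] * c3 / (Cpool + c3)
            gtot = g[8] + gs
            num = g[8] * EL + gs * Esyn + I_inj
            for c in range(8):
                gtot += gch[n, c]
                num += gch[n, c] * chan_E[c]
            Veq = num / gtot
            state[n, 0] = Veq + (V - Veq) * math.exp(-gtot * dt / C)
        # spike logging + synapse triggering
        for n in range(2):
            V = state[n, 0]
            if V < minV[n]:
                minV[n] = V
            if V > SPIKE_THRESHOLD:
                above[n] += dt
                if above[n] > max_above[n]:
                    max_above[n] = above[n]
            else:
                above[n] = 0.0
            if prevV[n] <= SPIKE_THRESHOLD and V > SPIKE_THRESHOLD:
                # upward threshold crossing: trigger partner-bound synapse
                state[n, IDX_XD] += 1.0
                state[n, IDX_XR] += 1.0
                armed[n] = True
                rising[n] = True
            if armed[n]:
                if V > prevV[n]:
                    rising[n] = True
                elif rising[n] and V < prevV[n]:
                    # local maximum above threshold = the spike
                    if record_spikes and nspk[n] < spk.shape[1]:
                        spk[n, nspk[n]] = t
                        amp[n, nspk[n]] = prevV[n]
                        nspk[n] += 1
                    armed[n] = False
                    rising[n] = False
            if V <= SPIKE_THRESHOLD:
                armed[n] = False
                rising[n] = False
            prevV[n] = V
        if not (state[0, 0] == state[0, 0]) or not (state[1, 0] == state[1, 0]) \
                or abs(state[0, 0]) > 1.0 or abs(state[1, 0]) > 1.0:
            ok = False
            break
    return nspk[0], nspk[1], minV[0], minV[1], max_above[0], max_above[1], ok


def run_fixed(state: np.ndarray, p: ModelParameters, duration: float, dt: float,
              *, t0: float = 0.0, record_spikes: bool = True,
              trace_dt: float = 0.0, max_spikes: int = 60000,
              model: HCOModel | None = None):
    """Integrate the pair for ``duration`` seconds, mutating ``state`` (2, 18).

    Returns a dict with spike times/amplitudes per neuron, min V, the
    longest continuous supra-threshold stretch, the optional sampled
    trace, and an ``ok`` flag (False on numerical blow-up).
    """
    if not np.all(np.isfinite(state)):
        empty = np.empty(0)
        return {"spike_times": (empty, empty), "spike_amps": (empty, empty),
                "min_V": (np.nan, np.nan), "max_above_threshold": (0.0, 0.0),
                "trace_t": np.empty(0), "trace_V": np.empty((2, 0)), "ok": False}
    tabs = build_tables(dt, model)
    nsteps = int(round(duration / dt))
    trace_every = int(round(trace_dt / dt)) if trace_dt > 0 else 0
    ntr = (nsteps + trace_every - 1) // trace_every if trace_every else 0
    trace = np.empty((2, ntr)) if ntr else np.empty((2, 0))
    spk = np.empty((2, max_spikes if record_spikes else 1))
    amp = np.empty_like(spk)
    nA, nB, minVA, minVB, abA, abB, ok = _run(
        state, gbar_vector(p), p.E_Leak, p.I_inject, dt, nsteps, t0,
        tabs.xinf, tabs.efac, tabs.minf, tabs.chan_E, tabs.chan_x, tabs.chan_y,
        tabs.const, spk, amp, record_spikes, trace, trace_every)
    times = (np.arange(ntr) * trace_every * dt + t0) if ntr else np.empty(0)
    return {
        "spike_times": (spk[0, :nA].copy(), spk[1, :nB].copy()),
        "spike_amps": (amp[0, :nA].copy(), amp[1, :nB].copy()),
        "min_V": (minVA, minVB),
        "max_above_threshold": (abA, abB),
        "trace_t": times,
        "trace_V": trace[:, :ntr].copy() if ntr else trace,
        "ok": bool(ok),
    }
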