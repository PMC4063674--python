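"""Integration protocol for the parameter screen.

Every instance follows the same three-phase protocol: the canonical
model is run for 200 s once to produce asymmetric initial conditions
(one neuron bursting, the partner inhibited); each instance then starts
from that shared state, settles for 100 s, and is recorded for 100 s.

Two backends are provided:

- ``"fixed"`` -- the exponential-Euler sweep kernel (default dt 0.05 ms)
  with in-loop spike-event logging; this is the backend used for sweeps.
- ``"adaptive"`` -- scipy ``solve_ivp`` (RK45 by default) with event-based
  synapse triggering, used as an independent cross-check of the fixed
  kernel; spikes are detected from its sampled trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernel
from .model import (IDX_V, IDX_XD, IDX_XR, NEURON_NVAR, NET_NVAR, HCOModel,
                    ModelParameters, default_model, network_rhs, resting_state)

__all__ = ["SimulationProtocol", "InstanceTrace", "canonical_initial_conditions",
           "simulate_instance", "integrate", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when the integrator cannot advance the state."""


@dataclass(frozen=True)
class SimulationProtocol:
    """Timing and solver settings for one screened instance."""

    warmup: float = 200.0      # canonical warm-up producing the shared ICs (s)
    settle: float = 100.0      # unrecorded settling after parameter change (s)
    record: float = 100.0      # recorded window (s)
    dt: float = 5e-5           # fixed-step size (s)
    sample_dt: float = 1e-4    # stored-trace sampling interval (s)
    method: str = "fixed"      # "fixed" or "adaptive"
    rtol: float = 1e-6         # adaptive backend tolerances
    atol: float = 1e-9
    max_step: float = 1e-3

    def __post_init__(self):
        if self.record <= 0:
            raise ValueError("record duration must be positive")
        if self.sample_dt > 5e-4:
            raise ValueError("sampling interval too coarse to resolve spikes")


@dataclass
class InstanceTrace:
    """Recorded window of one simulated instance."""

    t: np.ndarray                 # sample times (s), empty if trace not stored
    V: np.ndarray                 # (2, n) sampled membrane potentials (V)
    spike_times: tuple            # per-neuron arrays (s), within the window
    spike_amps: tuple             # per-neuron peak potentials (V)
    min_V: tuple                  # per-neuron minimum over the window (V)
    max_above_threshold: tuple    # longest supra-threshold stretch (s)
    ok: bool = True               # False if integration blew up

    def __post_init__(self):
        for st in self.spike_times:
            if len(st) > 1 and np.any(np.diff(st) <= 0):
                raise ValueError("spike times must be strictly increasing")


_IC_CACHE: dict[tuple, np.ndarray] = {}

# pre-warm-up seeds: one neuron depolarized, the partner at rest, so the
# 200 s canonical run settles with a definite burster/inhibited assignment
_SEED_V = (-0.045, -0.060)


def canonical_initial_conditions(p: ModelParameters | None = None,
                                 proto: SimulationProtocol | None = None,
                                 model: HCOModel | None = None) -> np.ndarray:
    """Network state after running the canonical model for the warm-up time.

    The result is the shared starting state of every sweep instance; it
    is deterministic at fixed solver settings and cached per settings.
    """
    m = model or default_model()
    p = p or m.canonical
    proto = proto or SimulationProtocol()
    key = (id(model), tuple(sorted(p.gbar.items())), p.E_Leak,
           proto.warmup, proto.dt, proto.method)
    if key in _IC_CACHE:
        return _IC_CACHE[key].copy()
    state = np.vstack([resting_state(m, v, p) for v in _SEED_V])
    res = integrate(p, state, proto.warmup, proto, model=m)
    if not res["ok"]:
        raise IntegrationError("canonical warm-up failed to integrate")
    if abs(state[0, IDX_V] - state[1, IDX_V]) < 1e-6:
        raise IntegrationError("warm-up produced a symmetric state; "
                               "expected one bursting / one inhibited neuron")
    _IC_CACHE[key] = state.copy()
    return state


def simulate_instance(p: ModelParameters, ics: np.ndarray | None = None,
                      proto: SimulationProtocol | None = None, *,
                      store_trace: bool = False,
                      model: HCOModel | None = None) -> InstanceTrace:
    """Run the settle+record protocol for one instance from the shared ICs."""
    if hasattr(p, "to_model_parameters"):
        p = p.to_model_parameters()
    proto = proto or SimulationProtocol()
    if ics is None:
        ics = canonical_initial_conditions(proto=proto, model=model)
    state = np.array(ics, dtype=float, copy=True)
    if state.shape != (2, NEURON_NVAR):
        raise ValueError(f"initial state must have shape (2, {NEURON_NVAR})")
    res = integrate(p, state, proto.settle, proto, model=model, record=False)
    if not res["ok"]:
        return InstanceTrace(t=np.empty(0), V=np.empty((2, 0)),
                             spike_times=(np.empty(0), np.empty(0)),
                             spike_amps=(np.empty(0), np.empty(0)),
                             min_V=(np.nan, np.nan),
                             max_above_threshold=(0.0, 0.0), ok=False)
    res = integrate(p, state, proto.record, proto, model=model,
                    record=True, store_trace=store_trace, t0=0.0)
    return InstanceTrace(
        t=res["trace_t"], V=res["trace_V"],
        spike_times=res["spike_times"], spike_amps=res["spike_amps"],
        min_V=res["min_V"], max_above_threshold=res["max_above_threshold"],
        ok=res["ok"])


def integrate(p: ModelParameters, state: np.ndarray, duration: float,
              proto: SimulationProtocol | None = None, *, record: bool = True,
              store_trace: bool = False, t0: float = 0.0,
              model: HCOModel | None = None) -> dict:
    """Advance ``state`` (mutated in place) by ``duration`` seconds.

    Dispatches to the fixed-step kernel or the adaptive backend per the
    protocol.  Returns the kernel result dict (spikes, min V, trace, ok).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    proto = proto or SimulationProtocol()
    if proto.method == "fixed":
        return _kernel.run_fixed(
            state, p, duration, proto.dt, t0=t0, record_spikes=record,
            trace_dt=proto.sample_dt if store_trace else 0.0, model=model)
    if proto.method == "adaptive":
        return _integrate_adaptive(p, state, duration, proto, t0=t0,
                                   model=model, record=record)
    raise ValueError(f"unknown integration method {proto.method!r}")


def _integrate_adaptive(p: ModelParameters, state: np.ndarray, duration: float,
                        proto: SimulationProtocol, *, t0: float = 0.0,
                        model: HCOModel | None = None, record: bool = True) -> dict:
    """scipy solve_ivp backend with synapse triggering at threshold crossings."""
    from .classify import detect_spikes

    m = model or default_model()
    thr = _kernel.SPIKE_THRESHOLD

    def rhs(t, y):
        return network_rhs(t, y, p, m)

    def cross_a(t, y):
        return y[IDX_V] - thr

    def cross_b(t, y):
        return y[NEURON_NVAR + IDX_V] - thr

    cross_a.direction = cross_b.direction = 1.0
    cross_a.terminal = cross_b.terminal = True

    y = state.ravel().copy()
    t = 0.0
    ts_parts, ys_parts = [], []
    sample_t = np.arange(0.0, duration, proto.sample_dt)
    while t < duration - 1e-12:
        sol = solve_ivp(rhs, (t, duration), y, method="RK45",
                        rtol=proto.rtol, atol=proto.atol,
                        max_step=proto.max_step, dense_output=True,
                        events=[cross_a, cross_b])
        if sol.status == -1:
            state[:] = y.reshape(2, NEURON_NVAR)
            return _adaptive_result(None, None, t0, record, ok=False)
        seg = sample_t[(sample_t >= t - 1e-12) & (sample_t <= sol.t[-1])]
        if seg.size:
            ts_parts.append(seg)
            ys_parts.append(sol.sol(seg))
        y = sol.y[:, -1].copy()
        t = sol.t[-1]
        if sol.status == 1:  # threshold crossing: increment spike accumulators
            for n, ev in enumerate(sol.t_events):
                if len(ev):
                    y[n * NEURON_NVAR + IDX_XD] += 1.0
                    y[n * NEURON_NVAR + IDX_XR] += 1.0
            # nudge past the crossing so the terminal event cannot re-fire
            # at the restart point (Euler micro-step; error ~1e-7 s)
            eps = min(1e-7, duration - t)
            y = y + eps * rhs(t, y)
            t += eps
    state[:] = y.reshape(2, NEURON_NVAR)
    tgrid = np.concatenate(ts_parts) if ts_parts else np.empty(0)
    Y = np.concatenate(ys_parts, axis=1) if ys_parts else np.empty((NET_NVAR, 0))
    # de-duplicate segment joins
    if tgrid.size:
        keep = np.concatenate([[True], np.diff(tgrid) > 1e-12])
        tgrid, Y = tgrid[keep], Y[:, keep]
    V = np.vstack([Y[IDX_V], Y[NEURON_NVAR + IDX_V]]) if Y.size else np.empty((2, 0))
    return _adaptive_result(tgrid + t0, V, t0, record, ok=True)


def _adaptive_result(tgrid, V, t0, record, *, ok):
    from .classify import detect_spikes

    if not ok or tgrid is None or not len(tgrid):
        empty = np.empty(0)
        return {"spike_times": (empty, empty), "spike_amps": (empty, empty),
                "min_V": (np.nan, np.nan), "max_above_threshold": (0.0, 0.0),
                "trace_t": np.empty(0), "trace_V": np.empty((2, 0)), "ok": ok}
    spikes, amps, above = [], [], []
    for n in range(2):
        if record:
            st, am = detect_spikes(tgrid, V[n])
        else:
            st, am = np.empty(0), np.empty(0)
        spikes.append(st)
        amps.append(am)
        mask = V[n] > _kernel.SPIKE_THRESHOLD
        longest = 0.0
        run = 0
        for flag in mask:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        above.append(longest * (tgrid[1] - tgrid[0] if len(tgrid) > 1 else 0.0))
    return {"spike_times": tuple(spikes), "spike_amps": tuple(amps),
            "min_V": (float(V[0].min()), float(V[1].min())),
            "max_above_threshold": tuple(above),
            "trace_t": tgrid, "trace_V": V, "ok": True}
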