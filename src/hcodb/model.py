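"""Conductance-based two-cell half-center oscillator (HCO) model.

Two identical leech heart-interneuron compartments, each with eight
Hodgkin-Huxley-type voltage-gated currents (Na, P, CaF, CaS, h, K1, K2, KA)
plus leak, coupled by reciprocal inhibition with both graded (Ca-pool
driven) and spike-mediated synaptic transmission.

Everything is SI internally: volts, seconds, siemens, farads, amperes.
The printed literature values (nS, mV) are converted once, when the
packaged model definition is loaded.

State vector layout (used by :func:`network_rhs` and the integrators)
---------------------------------------------------------------------
Each neuron occupies ``NEURON_NVAR`` (= 18) consecutive slots::

    [V, mNa, hNa, mP, mCaF, hCaF, mCaS, hCaS, mh,
     mK1, hK1, mK2, mKA, hKA, Ca_pool, M, Xd, Xr]

``Xd``/``Xr`` are the decay/rise accumulators of the spike-mediated
synaptic waveform (incremented by 1 at each presynaptic spike event, so
that ``norm * (Xd - Xr)`` is the summed unit-peak synaptic function over
all past spikes).  Neuron A comes first, neuron B second (36 slots total).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "SynapseSpec",
    "ModelParameters",
    "HCOModel",
    "load_model",
    "canonical_parameters",
    "steady_state_gate",
    "gate_time_constant",
    "channel_current",
    "graded_conductance",
    "graded_synapse_current",
    "synaptic_waveform",
    "spike_synapse_current",
    "network_rhs",
    "resting_state",
    "NEURON_NVAR",
    "NET_NVAR",
    "GATE_NAMES",
    "SWEPT_CONDUCTANCES",
]

NEURON_NVAR = 18
NET_NVAR = 2 * NEURON_NVAR

#: gate state names in state-vector order (indices 1..13 within a neuron)
GATE_NAMES = (
    "mNa", "hNa", "mP", "mCaF", "hCaF", "mCaS", "hCaS",
    "mh", "mK1", "hK1", "mK2", "mKA", "hKA",
)

#: the seven maximal conductances varied in the parameter screen
SWEPT_CONDUCTANCES = ("SynS", "SynG", "P", "K2", "h", "CaS", "Leak")

IDX_V = 0
IDX_CA = 14
IDX_M = 15
IDX_XD = 16
IDX_XR = 17


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """Voltage dependence of one activation/inactivation variable.

    The steady state of the standard form is the Boltzmann sigmoid
    ``x_inf(V) = 1 / (1 + exp(a (V + b)))`` and its time constant is
    ``tau(V) = tau_c + tau_d / (1 + exp(tau_A (V + tau_b)))``.
    Three gates deviate from the standard form and are selected by
    ``form``/``tau_form``:

    - ``"h_double"``: the hyperpolarization-activated current's steady
      state, ``1 / (1 + 2 exp(a (V + b)) + exp(a2 (V + b)))``.
    - ``"const"``: a voltage-independent time constant (fast Na activation).
    - ``"na_inact"``: Na inactivation tau, a sigmoid term plus a sech term.
    - ``"cosh"``: CaF activation tau, ``tau_c + tau_d / cosh(tau_A (V + tau_b))``.
    """

    form: str = "sigmoid"
    a: float = 0.0
    b: float = 0.0
    a2: float = 0.0
    tau_form: str = "sigmoid"
    tau_A: float = 0.0
    tau_b: float = 0.0
    tau_c: float = 0.0
    tau_d: float = 0.0
    tau_e: float = 0.0
    tau_F: float = 0.0
    tau_g: float = 0.0

    def steady_state(self, V):
        return steady_state_gate(self, V)

    def time_constant(self, V):
        return gate_time_constant(self, V)


def steady_state_gate(spec: GateSpec, V):
    """Steady-state value of a gate at membrane potential ``V`` (volts).

    Vectorised over ``V``.  Returns values in [0, 1].
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    if spec.form == "sigmoid":
        return 1.0 / (1.0 + np.exp(spec.a * (V + spec.b)))
    if spec.form == "h_double":
        # hyperpolarization-activated current: double-exponential denominator
        return 1.0 / (1.0 + 2.0 * np.exp(spec.a * (V + spec.b))
                      + np.exp(spec.a2 * (V + spec.b)))
    raise ValueError(f"unknown gate form {spec.form!r}")


def gate_time_constant(spec: GateSpec, V):
    """Voltage-dependent time constant of a gate, in seconds (> 0)."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    if spec.tau_form == "sigmoid":
        tau = spec.tau_c + spec.tau_d / (1.0 + np.exp(spec.tau_A * (V + spec.tau_b)))
    elif spec.tau_form == "const":
        tau = np.full_like(V, spec.tau_c)
    elif spec.tau_form == "na_inact":
        tau = (spec.tau_c
               + spec.tau_d / (1.0 + np.exp(spec.tau_A * (V + spec.tau_b)))
               + spec.tau_e / np.cosh(spec.tau_F * (V + spec.tau_g)))
    elif spec.tau_form == "cosh":
        tau = spec.tau_c + spec.tau_d / np.cosh(spec.tau_A * (V + spec.tau_b))
    else:
        raise ValueError(f"unknown tau form {spec.tau_form!r}")
    if np.any(tau <= 0.0):
        raise ValueError("gate time constant must be strictly positive")
    return tau


# ---------------------------------------------------------------------------
# channels and synapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated current: I = gbar * m**x * h**y * (V - E)."""

    name: str
    x: int
    y: int
    E: float  # reversal potential, V
    activation: GateSpec
    inactivation: GateSpec | None = None

    def __post_init__(self):
        if self.x not in (1, 2, 3):
            raise ValueError(f"activation exponent x={self.x} not in {{1,2,3}}")
        if self.y not in (0, 1):
            raise ValueError(f"inactivation exponent y={self.y} not in {{0,1}}")
        if self.y == 1 and self.inactivation is None:
            raise ValueError(f"channel {self.name}: y=1 requires an inactivation gate")
        if self.y == 0 and self.inactivation is not None:
            raise ValueError(f"channel {self.name}: y=0 must not carry an inactivation gate")


def channel_current(chan: ChannelSpec, gbar: float, m, h, V):
    """Signed ionic current ``gbar * m**x * h**y * (V - E)``.

    Positive is outward under the (V - E) convention.
    """
    if gbar < 0:
        raise ValueError("maximal conductance must be nonnegative")
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("activation variable outside [0, 1]")
    cur = gbar * m ** chan.x * (np.asarray(V) - chan.E)
    if chan.y:
        h = np.asarray(h, dtype=float)
        if np.any((h < 0) | (h > 1)):
            raise ValueError("inactivation variable outside [0, 1]")
        cur = cur * h
    return cur


@dataclass(frozen=True)
class SynapseSpec:
    """Kinetics shared by the graded and spike-mediated synapses.

    The spike-mediated conductance waveform is a difference of
    exponentials ``f(t) = norm * (exp(-t/tau_decay) - exp(-t/tau_rise))``
    with ``norm`` chosen so the single-spike peak equals 1, scaled by the
    slow presynaptic modulation variable M.  The graded conductance is
    ``gbar_SynG * Ca**3 / (saturation + Ca**3)`` where Ca integrates the
    presynaptic low-threshold calcium current above a small threshold.
    """

    E: float                 # synaptic reversal potential, V
    tau_rise: float          # s
    tau_decay: float         # s
    M_base: float
    M_amp: float
    M_a: float
    M_b: float
    tau_M: float             # s
    pool_buffer_rate: float  # 1/s
    pool_saturation: float   # A^3 s^3
    pool_threshold: float    # A

    @property
    def norm_const(self) -> float:
        """Normalization making the unit synaptic waveform peak at 1."""
        t_peak = self.peak_time
        return 1.0 / (math.exp(-t_peak / self.tau_decay)
                      - math.exp(-t_peak / self.tau_rise))

    @property
    def peak_time(self) -> float:
        td, tr = self.tau_decay, self.tau_rise
        return td * tr / (td - tr) * math.log(td / tr)

    def M_inf(self, V):
        return self.M_base + self.M_amp / (1.0 + np.exp(self.M_a * (np.asarray(V) + self.M_b)))


def synaptic_waveform(syn: SynapseSpec, t):
    """Unit-peak spike-mediated conductance time course f(t), f(0) = 0."""
    t = np.asarray(t, dtype=float)
    f = syn.norm_const * (np.exp(-t / syn.tau_decay) - np.exp(-t / syn.tau_rise))
    return np.where(t >= 0, f, 0.0)


def graded_conductance(syn: SynapseSpec, gbar_SynG: float, ca_pool):
    """Graded synaptic conductance as a saturating function of the Ca pool."""
    ca = np.asarray(ca_pool, dtype=float)
    if np.any(ca < 0):
        raise ValueError("presynaptic Ca pool must be nonnegative")
    c3 = ca ** 3
    return gbar_SynG * c3 / (syn.pool_saturation + c3)


def graded_synapse_current(syn: SynapseSpec, ca_pool_pre, V_post, gbar_SynG: float):
    """Graded inhibitory current onto the postsynaptic neuron."""
    if gbar_SynG < 0:
        raise ValueError("maximal conductance must be nonnegative")
    return graded_conductance(syn, gbar_SynG, ca_pool_pre) * (np.asarray(V_post) - syn.E)


def spike_synapse_current(syn: SynapseSpec, spike_times: Sequence[float], M: float,
                          V_post: float, gbar_SynS: float, t: float,
                          cutoff: float = 1e-6) -> float:
    """Spike-mediated current: M * gbar * sum_spikes f(t - t_spike) * (V - E).

    ``spike_times`` must be sorted ascending; events whose waveform has
    decayed below ``cutoff`` of peak are skipped.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size and np.any(np.diff(st) < 0):
        raise ValueError("spike_times must be sorted ascending")
    if not 0.0 <= M <= 1.0:
        raise ValueError("modulation variable M must lie in [0, 1]")
    horizon = -syn.tau_decay * math.log(max(cutoff, 1e-300) / syn.norm_const)
    past = st[(st <= t) & (t - st <= horizon)]
    f = synaptic_waveform(syn, t - past)
    return float(M * gbar_SynS * f.sum() * (V_post - syn.E))


# ---------------------------------------------------------------------------
# full model definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Free parameters of one model instance.

    ``gbar`` maps channel/synapse names to maximal conductances in
    siemens; both neurons of a pair always share the same values.
    """

    gbar: Mapping[str, float]
    E_Leak: float            # V
    C: float                 # F
    I_inject: float = 0.0    # A

    def __post_init__(self):
        missing = {"Na", "P", "CaF", "CaS", "h", "K1", "K2", "KA",
                   "Leak", "SynS", "SynG"} - set(self.gbar)
        if missing:
            raise ValueError(f"missing maximal conductances: {sorted(missing)}")
        if any(v < 0 for v in self.gbar.values()):
            raise ValueError("maximal conductances must be nonnegative")
        if self.C <= 0:
            raise ValueError("membrane capacitance must be positive")

    @property
    def is_isolated(self) -> bool:
        return self.gbar["SynS"] == 0.0 and self.gbar["SynG"] == 0.0

    def with_gbar(self, **updates_nS) -> "ModelParameters":
        """Return a copy with the given conductances replaced (values in nS)."""
        g = dict(self.gbar)
        for k, v in updates_nS.items():
            if k not in g:
                raise KeyError(k)
            g[k] = v * 1e-9
        return replace(self, gbar=g)


#: channel order used throughout the package (gates appear in this order)
CHANNEL_ORDER = ("Na", "P", "CaF", "CaS", "h", "K1", "K2", "KA")


@dataclass(frozen=True)
class HCOModel:
    """Immutable model definition: channels, synapse kinetics, canonical set."""

    channels: Mapping[str, ChannelSpec]
    synapse: SynapseSpec
    canonical: ModelParameters
    version: int = 1

    def gate_specs(self) -> list[tuple[str, GateSpec]]:
        """(name, spec) for every gate in state-vector order."""
        out = []
        for name in CHANNEL_ORDER:
            ch = self.channels[name]
            out.append((f"m{name}", ch.activation))
            if ch.y:
                out.append((f"h{name}", ch.inactivation))
        return out


def _gate_from_json(d: dict) -> GateSpec:
    return GateSpec(
        form=d.get("form", "sigmoid"), a=d.get("a", 0.0), b=d.get("b", 0.0),
        a2=d.get("a2", 0.0), tau_form=d.get("tau_form", "sigmoid"),
        tau_A=d.get("tau_A", 0.0), tau_b=d.get("tau_b", 0.0),
        tau_c=d.get("tau_c", 0.0), tau_d=d.get("tau_d", 0.0),
        tau_e=d.get("tau_e", 0.0), tau_F=d.get("tau_F", 0.0),
        tau_g=d.get("tau_g", 0.0),
    )


def load_model() -> HCOModel:
    """Load the packaged canonical model definition."""
    text = resources.files("hcodb").joinpath("model_defs.json").read_text()
    d = json.loads(text)
    erev = d["reversal_potentials_V"]
    channels = {}
    for name, ch in d["channels"].items():
        inact = _gate_from_json(ch["inactivation"]) if "inactivation" in ch else None
        channels[name] = ChannelSpec(
            name=name, x=ch["x"], y=ch["y"], E=erev[ch["E"]],
            activation=_gate_from_json(ch["activation"]), inactivation=inact,
        )
    syn = d["synapse"]
    synapse = SynapseSpec(
        E=erev[syn["E"]], tau_rise=syn["tau_rise_s"], tau_decay=syn["tau_decay_s"],
        M_base=syn["M_inf"]["base"], M_amp=syn["M_inf"]["amp"],
        M_a=syn["M_inf"]["a"], M_b=syn["M_inf"]["b"], tau_M=syn["tau_M_s"],
        pool_buffer_rate=syn["graded_pool"]["buffer_rate_per_s"],
        pool_saturation=syn["graded_pool"]["saturation_C3"],
        pool_threshold=syn["graded_pool"]["threshold_A"],
    )
    canonical = ModelParameters(
        gbar={k: v * 1e-9 for k, v in d["canonical_gbar_nS"].items()},
        E_Leak=d["canonical_E_Leak_V"], C=d["capacitance_F"],
    )
    return HCOModel(channels=channels, synapse=synapse, canonical=canonical,
                    version=d["version"])


_MODEL: HCOModel | None = None


def default_model() -> HCOModel:
    """Cached singleton of the packaged model definition."""
    global _MODEL
    if _MODEL is None:
        _MODEL = load_model()
    return _MODEL


def canonical_parameters() -> ModelParameters:
    return default_model().canonical


# ---------------------------------------------------------------------------
# right-hand side of the coupled ODE system
# ---------------------------------------------------------------------------

def _neuron_conductances(model: HCOModel, p: ModelParameters, s: np.ndarray):
    """Per-channel instantaneous conductances g_i = gbar_i m^x h^y."""
    g = {}
    k = 1
    for name in CHANNEL_ORDER:
        ch = model.channels[name]
        gi = p.gbar[name] * s[k] ** ch.x
        k += 1
        if ch.y:
            gi = gi * s[k]
            k += 1
        g[name] = gi
    return g


def resting_state(model: HCOModel, V: float, p: ModelParameters | None = None) -> np.ndarray:
    """Single-neuron state with every gate at its steady state for ``V``."""
    s = np.zeros(NEURON_NVAR)
    s[IDX_V] = V
    for i, (_, spec) in enumerate(model.gate_specs(), start=1):
        s[i] = float(steady_state_gate(spec, V))
    s[IDX_M] = float(model.synapse.M_inf(V))
    return s


class _GateArrays:
    """Vectorized gate kinetics compiled from the GateSpecs.

    Evaluating all 13 gates with array arithmetic (special forms handled
    by masks) keeps :func:`network_rhs` fast enough for the adaptive
    reference integrator.
    """

    def __init__(self, model: HCOModel):
        specs = [spec for _, spec in model.gate_specs()]
        self.n = len(specs)
        self.a = np.array([s.a for s in specs])
        self.b = np.array([s.b for s in specs])
        self.a2 = np.array([s.a2 for s in specs])
        self.is_hdouble = np.array([s.form == "h_double" for s in specs])
        self.tau_A = np.array([s.tau_A for s in specs])
        self.tau_b = np.array([s.tau_b for s in specs])
        self.tau_c = np.array([s.tau_c for s in specs])
        self.tau_d = np.array([s.tau_d for s in specs])
        self.tau_e = np.array([s.tau_e for s in specs])
        self.tau_F = np.array([s.tau_F for s in specs])
        self.tau_g = np.array([s.tau_g for s in specs])
        self.tau_is_cosh = np.array([s.tau_form == "cosh" for s in specs])
        self.tau_is_const = np.array([s.tau_form == "const" for s in specs])
        self.tau_is_na = np.array([s.tau_form == "na_inact" for s in specs])
        # per-gate channel index and activation exponent
        act_pos, inact_pos, xexp = [], [], []
        gi = 0
        for name in CHANNEL_ORDER:
            ch = model.channels[name]
            act_pos.append(gi)
            xexp.append(ch.x)
            gi += 1
            if ch.y:
                inact_pos.append(gi)
                gi += 1
            else:
                inact_pos.append(-1)
        self.act_pos = np.array(act_pos)
        self.inact_pos = np.array(inact_pos)
        self.has_inact = self.inact_pos >= 0
        self.xexp = np.array(xexp)
        self.chan_E = np.array([model.channels[c].E for c in CHANNEL_ORDER])
        self.gbar_keys = list(CHANNEL_ORDER)

    def steady_state(self, V: float) -> np.ndarray:
        with np.errstate(over="ignore"):
            return self._steady_state(V)

    def _steady_state(self, V: float) -> np.ndarray:
        e1 = np.exp(self.a * (V + self.b))
        x = 1.0 / (1.0 + e1)
        xh = 1.0 / (1.0 + 2.0 * e1 + np.exp(self.a2 * (V + self.b)))
        return np.where(self.is_hdouble, xh, x)

    def time_constant(self, V: float) -> np.ndarray:
        with np.errstate(over="ignore"):
            return self._time_constant(V)

    def _time_constant(self, V: float) -> np.ndarray:
        tau = self.tau_c + self.tau_d / (1.0 + np.exp(self.tau_A * (V + self.tau_b)))
        tau = np.where(self.tau_is_const, self.tau_c, tau)
        tau = np.where(self.tau_is_cosh,
                       self.tau_c + self.tau_d / np.cosh(self.tau_A * (V + self.tau_b)),
                       tau)
        tau = np.where(self.tau_is_na,
                       tau + self.tau_e / np.cosh(self.tau_F * (V + self.tau_g)),
                       tau)
        return tau


_GATE_ARRAYS: dict[int, _GateArrays] = {}


def _gate_arrays(model: HCOModel) -> _GateArrays:
    key = id(model)
    if key not in _GATE_ARRAYS:
        _GATE_ARRAYS[key] = _GateArrays(model)
    return _GATE_ARRAYS[key]


def network_rhs(t: float, state: np.ndarray, p: ModelParameters,
                model: HCOModel | None = None) -> np.ndarray:
    """Time derivative of the full two-neuron state (36 variables).

    Synaptic terms use the *other* neuron as the presynaptic source; with
    both synaptic conductances zero the neurons are fully decoupled.  The
    spike accumulators Xd/Xr only decay here -- their unit increments at
    presynaptic spike events are applied by the integrator.
    """
    if model is None:
        model = default_model()
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to network_rhs")
    syn = model.synapse
    ga = _gate_arrays(model)
    gbar = np.array([p.gbar[k] for k in ga.gbar_keys])
    d = np.zeros_like(state)
    halves = (state[:NEURON_NVAR], state[NEURON_NVAR:])
    for i, s in enumerate(halves):
        pre = halves[1 - i]
        ds = d[i * NEURON_NVAR:(i + 1) * NEURON_NVAR]
        V = s[IDX_V]
        gates = s[1:1 + ga.n]
        ds[1:1 + ga.n] = (ga.steady_state(V) - gates) / ga.time_constant(V)
        # per-channel conductances: gbar times the product of gate factors
        gch = gbar * gates[ga.act_pos] ** ga.xexp
        gch[ga.has_inact] *= gates[ga.inact_pos[ga.has_inact]]
        ionic = float(np.sum(gch * (V - ga.chan_E)))
        leak = p.gbar["Leak"] * (V - p.E_Leak)
        # synaptic currents onto this neuron, driven by the partner
        g_spike = p.gbar["SynS"] * pre[IDX_M] * syn.norm_const \
            * max(pre[IDX_XD] - pre[IDX_XR], 0.0)
        i_syn_s = g_spike * (V - syn.E)
        c3 = pre[IDX_CA] ** 3
        i_syn_g = p.gbar["SynG"] * c3 / (syn.pool_saturation + c3) * (V - syn.E)
        ds[IDX_V] = -(ionic + leak + i_syn_s + i_syn_g - p.I_inject) / p.C
        # presynaptic Ca pool driven by this neuron's own Ca currents
        i_ca = gch[2] * (V - ga.chan_E[2]) + gch[3] * (V - ga.chan_E[3])
        drive = max(-i_ca - syn.pool_threshold, 0.0)
        ds[IDX_CA] = drive - syn.pool_buffer_rate * s[IDX_CA]
        # synaptic modulation variable
        m_inf = syn.M_base + syn.M_amp / (1.0 + math.exp(min(syn.M_a * (V + syn.M_b), 700.0)))
        ds[IDX_M] = (m_inf - s[IDX_M]) / syn.tau_M
        # spike accumulator decay
        ds[IDX_XD] = -s[IDX_XD] / syn.tau_decay
        ds[IDX_XR] = -s[IDX_XR] / syn.tau_rise
    return d
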