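"""Spike/burst detection, burst metrics, and activity classification.

Definitions implemented here:

- a *spike* is an upward crossing of the -20 mV threshold, timed at the
  local voltage maximum that follows the crossing;
- a *burst* has at least three spikes, with inter-burst intervals of at
  least 1 s (internal inter-spike gaps are all < 1 s);
- the *cycle period* is the interval between the middle spikes of two
  consecutive bursts; its regularity is the coefficient of variation
  (CV) of those intervals;
- the *duty cycle* is the percentage of the period occupied by a burst;
- the *relative phase* is computed per cycle as the delay from the middle
  spike of a burst of neuron B to the middle spike of the preceding burst
  of neuron A, divided by that A-to-A cycle interval, then averaged.

An instance is a half-center oscillator (HCO) when both neurons burst
(at least two bursts in the final 40 s), spikes within every burst are
uniform in amplitude (CV < 0.07), the period is regular (CV < 0.05), the
pair fires in antiphase (mean phase in the open interval 0.45-0.55), and
at least one synaptic conductance is nonzero.  A *burster* satisfies the
same bursting/regularity rules with both synapses absent.  *Realistic*
instances additionally match chronic leech heart-interneuron recordings:
period 5-15 s, mean spike frequency 8-25 Hz and, for HCOs, duty cycle
50-70% (closed bounds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Burst", "BurstMetrics", "ActivityLabel", "detect_spikes",
           "group_bursts", "burst_metrics", "classify_instance",
           "SPIKE_THRESHOLD", "MIN_INTERBURST_GAP", "MIN_SPIKES_PER_BURST"]

SPIKE_THRESHOLD = -0.02       # V
MIN_INTERBURST_GAP = 1.0      # s
MIN_SPIKES_PER_BURST = 3
BURST_COUNT_WINDOW = 40.0     # s, trailing window for the >= 2 bursts rule
PLATEAU_DURATION = 5.0        # s above threshold marks a plateau neuron

MAX_AMP_CV = 0.07
MAX_PERIOD_CV = 0.05
PHASE_RANGE = (0.45, 0.55)            # open interval
REALISTIC_PERIOD = (5.0, 15.0)        # s, closed
REALISTIC_FREQ = (8.0, 25.0)          # Hz, closed
REALISTIC_DUTY = (50.0, 70.0)         # %, closed, HCOs only

CATEGORIES = ("HCO", "burster", "spiking", "silent", "irregular",
              "plateau", "bistable-suspect", "failed")


def _finite_mean(values) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _finite_max(values) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(max(vals)) if vals else float("nan")


@dataclass(frozen=True)
class Burst:
    """One burst: >= 3 spikes separated by gaps < 1 s."""

    spike_times: np.ndarray
    spike_amps: np.ndarray

    def __post_init__(self):
        if len(self.spike_times) < MIN_SPIKES_PER_BURST:
            raise ValueError("a burst needs at least three spikes")
        gaps = np.diff(self.spike_times)
        if len(gaps) and gaps.max() >= MIN_INTERBURST_GAP:
            raise ValueError("internal inter-spike gap >= the burst-splitting gap")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def first(self) -> float:
        return float(self.spike_times[0])

    @property
    def last(self) -> float:
        return float(self.spike_times[-1])

    @property
    def middle(self) -> float:
        """Middle spike time; for even counts, spike ceil(n/2) (1-based)."""
        return float(self.spike_times[(self.n_spikes + 1) // 2 - 1])

    @property
    def duration(self) -> float:
        return self.last - self.first

    @property
    def spike_frequency(self) -> float:
        """(n - 1) / (last - first), Hz."""
        return (self.n_spikes - 1) / self.duration

    def amplitude_cv(self, baseline: float = SPIKE_THRESHOLD) -> float:
        """CV of spike heights measured above the detection threshold."""
        heights = self.spike_amps - baseline
        mean = heights.mean()
        if mean <= 0:
            return np.inf
        return float(heights.std(ddof=1) / mean) if len(heights) > 1 else 0.0


@dataclass
class BurstMetrics:
    """Per-instance burst statistics over the recorded window."""

    n_bursts: tuple              # per neuron
    n_bursts_tail: tuple         # per neuron, within the final 40 s
    period: tuple                # mean cycle period per neuron (s), nan if < 2 bursts
    period_cv: tuple             # CV of cycle periods per neuron
    spike_frequency: tuple       # mean intra-burst spike frequency (Hz)
    duty_cycle: tuple            # mean burst duration / mean period * 100
    max_amp_cv: tuple            # worst within-burst spike-amplitude CV
    min_V: tuple                 # minimum membrane potential (V)
    phase: float = np.nan        # mean per-cycle relative phase of B vs A
    n_stray_spikes: tuple = (0, 0)   # spikes outside any burst
    max_above_threshold: tuple = (0.0, 0.0)
    n_spikes: tuple = (0, 0)
    ok: bool = True

    @property
    def mean_period(self) -> float:
        return _finite_mean(self.period)

    @property
    def mean_duty_cycle(self) -> float:
        return _finite_mean(self.duty_cycle)

    @property
    def mean_spike_frequency(self) -> float:
        return _finite_mean(self.spike_frequency)


@dataclass(frozen=True)
class ActivityLabel:
    """Category plus the realistic flag (HCO/burster only)."""

    category: str
    realistic: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.realistic and self.category not in ("HCO", "burster"):
            raise ValueError("realistic flag only applies to HCO/burster")


def detect_spikes(t: np.ndarray, V: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD):
    """Spike times and peak potentials from a sampled voltage trace.

    One spike per upward threshold crossing, timed at the local maximum
    that follows the crossing.  Excursions that do not complete (the
    trace ends above threshold before peaking) are dropped.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if t.ndim != 1 or t.shape != V.shape:
        raise ValueError("t and V must be 1-D arrays of equal length")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    above = V > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, amps = [], []
    for c in crossings:
        # end of this supra-threshold excursion
        below = np.flatnonzero(~above[c:])
        end = c + below[0] if below.size else len(V)
        seg = V[c:end]
        if not seg.size:
            continue
        j = int(np.argmax(seg)) + c
        if j == len(V) - 1 and below.size == 0:
            continue  # still rising at the end of the trace
        times.append(t[j])
        amps.append(V[j])
    return np.asarray(times), np.asarray(amps)


def group_bursts(spike_times: Sequence[float], spike_amps: Sequence[float] | None = None):
    """Split a sorted spike train into bursts at gaps >= 1 s.

    Returns ``(bursts, stray_spike_times)``; clusters with fewer than
    three spikes are not bursts and are returned as strays.
    """
    st = np.asarray(spike_times, float)
    if len(st) > 1 and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted ascending")
    amps = np.asarray(spike_amps, float) if spike_amps is not None \
        else np.zeros_like(st)
    if amps.shape != st.shape:
        raise ValueError("spike_amps must match spike_times")
    if st.size == 0:
        return [], np.empty(0)
    cuts = np.flatnonzero(np.diff(st) >= MIN_INTERBURST_GAP) + 1
    bursts, strays = [], []
    for idx in np.split(np.arange(st.size), cuts):
        if idx.size >= MIN_SPIKES_PER_BURST:
            bursts.append(Burst(st[idx], amps[idx]))
        else:
            strays.extend(st[idx])
    return bursts, np.asarray(strays)


def _phase_per_cycle(bursts_a, bursts_b):
    """Mean of per-cycle phases of B's burst midpoints within A's cycles."""
    mids_a = np.array([b.middle for b in bursts_a])
    mids_b = np.array([b.middle for b in bursts_b])
    phases = []
    for k in range(len(mids_a) - 1):
        t0, t1 = mids_a[k], mids_a[k + 1]
        inside = mids_b[(mids_b > t0) & (mids_b <= t1)]
        if inside.size:
            phases.append((inside[0] - t0) / (t1 - t0))
    return float(np.mean(phases)) if phases else np.nan


def burst_metrics(bursts_a, bursts_b, *, window: tuple[float, float],
                  strays=(np.empty(0), np.empty(0)),
                  min_V=(np.nan, np.nan),
                  max_above_threshold=(0.0, 0.0)) -> BurstMetrics:
    """Assemble per-instance metrics from the two neurons' burst lists."""
    t_end = window[1]
    total_spikes = tuple(sum(b.n_spikes for b in bursts) + len(s)
                         for bursts, s in ((bursts_a, strays[0]),
                                           (bursts_b, strays[1])))
    # a burst touching a window edge may be truncated (its true extent and
    # middle spike are unknowable); only complete bursts enter the metrics
    bursts_a = [b for b in bursts_a
                if b.first - window[0] >= MIN_INTERBURST_GAP
                and t_end - b.last >= MIN_INTERBURST_GAP]
    bursts_b = [b for b in bursts_b
                if b.first - window[0] >= MIN_INTERBURST_GAP
                and t_end - b.last >= MIN_INTERBURST_GAP]
    per_neuron = {"n": [], "tail": [], "period": [], "cv": [], "freq": [],
                  "duty": [], "ampcv": [], "nspk": []}
    for bursts in (bursts_a, bursts_b):
        mids = np.array([b.middle for b in bursts])
        per_neuron["n"].append(len(bursts))
        per_neuron["tail"].append(int(np.sum(mids >= t_end - BURST_COUNT_WINDOW)))
        per_neuron["nspk"].append(int(sum(b.n_spikes for b in bursts)))
        if len(bursts) >= 2:
            periods = np.diff(mids)
            mean_p = periods.mean()
            cv = periods.std(ddof=1) / mean_p if len(periods) > 1 else 0.0
            duty = np.mean([b.duration for b in bursts]) / mean_p * 100.0
        else:
            mean_p = cv = duty = np.nan
        per_neuron["period"].append(mean_p)
        per_neuron["cv"].append(cv)
        per_neuron["duty"].append(duty)
        per_neuron["freq"].append(
            float(np.mean([b.spike_frequency for b in bursts])) if bursts else np.nan)
        per_neuron["ampcv"].append(
            float(max(b.amplitude_cv() for b in bursts)) if bursts else np.nan)
    return BurstMetrics(
        n_bursts=tuple(per_neuron["n"]), n_bursts_tail=tuple(per_neuron["tail"]),
        period=tuple(per_neuron["period"]), period_cv=tuple(per_neuron["cv"]),
        spike_frequency=tuple(per_neuron["freq"]),
        duty_cycle=tuple(per_neuron["duty"]),
        max_amp_cv=tuple(per_neuron["ampcv"]), min_V=tuple(min_V),
        phase=_phase_per_cycle(bursts_a, bursts_b),
        n_stray_spikes=(len(strays[0]), len(strays[1])),
        max_above_threshold=tuple(max_above_threshold),
        n_spikes=total_spikes)


def metrics_from_trace(trace, window: tuple[float, float] | None = None) -> BurstMetrics:
    """Convenience: bursts + metrics straight from an InstanceTrace."""
    if not trace.ok:
        m = burst_metrics([], [], window=(0.0, 0.0))
        m.ok = False
        return m
    if window is None:
        if len(trace.t):
            window = (float(trace.t[0]), float(trace.t[-1]))
        else:
            allt = np.concatenate([s for s in trace.spike_times if len(s)] or [np.zeros(1)])
            window = (0.0, float(max(allt.max(), 100.0)))
    ba, sa = group_bursts(trace.spike_times[0], trace.spike_amps[0])
    bb, sb = group_bursts(trace.spike_times[1], trace.spike_amps[1])
    return burst_metrics(ba, bb, window=window, strays=(sa, sb),
                         min_V=trace.min_V,
                         max_above_threshold=trace.max_above_threshold)


def instance_from_sampled(t: np.ndarray, V: np.ndarray):
    """Build an InstanceTrace from a sampled two-neuron voltage trace.

    Runs spike detection on both rows of ``V`` (shape (2, n)) and fills
    in the window statistics; the entry point for classifying traces
    that did not come from the sweep kernel (files, synthetic traces).
    """
    from .simulate import InstanceTrace

    t = np.asarray(t, float)
    V = np.atleast_2d(np.asarray(V, float))
    if V.shape[0] != 2:
        raise ValueError("V must have shape (2, n)")
    spikes, amps, above = [], [], []
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    for n in range(2):
        st, am = detect_spikes(t, V[n])
        spikes.append(st)
        amps.append(am)
        mask = V[n] > SPIKE_THRESHOLD
        longest = run = 0
        for flag in mask:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        above.append(longest * dt)
    return InstanceTrace(t=t, V=V, spike_times=tuple(spikes),
                         spike_amps=tuple(amps),
                         min_V=(float(V[0].min()), float(V[1].min())),
                         max_above_threshold=tuple(above))


def _bursting_ok(m: BurstMetrics) -> bool:
    """Both neurons burst regularly with uniform spikes."""
    return (all(n >= 2 for n in m.n_bursts_tail)
            and all(np.isfinite(cv) and cv < MAX_PERIOD_CV for cv in m.period_cv)
            and all(np.isfinite(a) and a < MAX_AMP_CV for a in m.max_amp_cv))


def _realistic(m: BurstMetrics, *, need_duty: bool) -> bool:
    if not (REALISTIC_PERIOD[0] <= m.mean_period <= REALISTIC_PERIOD[1]):
        return False
    if not (REALISTIC_FREQ[0] <= m.mean_spike_frequency <= REALISTIC_FREQ[1]):
        return False
    if need_duty and not (REALISTIC_DUTY[0] <= m.mean_duty_cycle <= REALISTIC_DUTY[1]):
        return False
    return True


def classify_instance(m: BurstMetrics, *, isolated: bool) -> ActivityLabel:
    """Assign exactly one activity category to an instance.

    ``isolated`` is True when both synaptic conductances are zero (the
    twin neurons are uncoupled).  Coupled instances can be HCOs; isolated
    instances can be bursters; everything else falls into operational
    sub-labels (silent / plateau / spiking / irregular / bistable-suspect).
    """
    if not m.ok:
        return ActivityLabel("failed")
    if any(a > PLATEAU_DURATION for a in m.max_above_threshold):
        return ActivityLabel("plateau")
    if all(n == 0 for n in m.n_spikes):
        return ActivityLabel("silent")
    if _bursting_ok(m):
        if isolated:
            return ActivityLabel("burster", _realistic(m, need_duty=False))
        if PHASE_RANGE[0] < m.phase < PHASE_RANGE[1]:
            return ActivityLabel("HCO", _realistic(m, need_duty=True))
    if isolated:
        # twin neurons on different attractors (one bursting, one not;
        # or one silent, one firing)
        burst_mismatch = (m.n_bursts[0] >= 2) != (m.n_bursts[1] >= 2)
        spike_mismatch = (m.n_spikes[0] == 0) != (m.n_spikes[1] == 0)
        if burst_mismatch or spike_mismatch:
            return ActivityLabel("bistable-suspect")
    if all(n < 2 for n in m.n_bursts):
        return ActivityLabel("spiking")
    return ActivityLabel("irregular")
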