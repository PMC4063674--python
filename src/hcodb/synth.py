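"""Synthetic inputs with known ground truth.

These generators build the statistical structures the analysis stages
assume -- parameter clouds with an embedded linear correlation, sampled
voltage traces with prescribed burst structure, and instance tables with
a prescribed family census -- so the classifier, PCA/ODR, KS and family
stages can be tested end-to-end without running any sweep.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SPIKE_THRESHOLD
from .sweep import DEFAULT_ELEAK_MV, DEFAULT_LEVELS, PARAM_COLUMNS

__all__ = ["SyntheticGroupSpec", "SyntheticTraceSpec", "gen_correlated_group",
           "gen_bursting_trace", "gen_family_table"]

#: the lattice in analysis units (fractions of canonical)
LEVEL_FRACTIONS = tuple(v / 100.0 for v in DEFAULT_LEVELS)


@dataclass(frozen=True)
class SyntheticGroupSpec:
    """Point cloud along an embedded line plus isotropic noise."""

    n: int = 500
    direction: tuple = (1.0, 1.0, 1.0)   # embedded direction (normalized internally)
    center: tuple | None = None          # defaults to mid-lattice
    spread: float = 0.5                  # sd of positions along the line
    sigma: float = 0.0                   # isotropic noise sd
    snap_to_grid: bool = False
    columns: tuple = ("P", "K2", "Leak")

    def __post_init__(self):
        if self.sigma < 0 or self.spread < 0:
            raise ValueError("spread and sigma must be nonnegative")
        if self.n < 1:
            raise ValueError("need at least one instance")
        if len(self.direction) != len(self.columns):
            raise ValueError("direction length must match column count")

    @property
    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("direction must be nonzero")
        return d / nrm


def gen_correlated_group(spec: SyntheticGroupSpec, seed: int = 0) -> pd.DataFrame:
    """Sample a group whose dominant variation lies along ``spec.direction``.

    With ``sigma = 0`` all points lie exactly on the embedded line; with
    ``snap_to_grid`` the coordinates are projected onto the sweep lattice
    fractions {0, 0.25, ..., 1.75}.
    """
    rng = np.random.default_rng(seed)
    u = spec.unit_direction
    d = len(u)
    center = (np.full(d, np.mean(LEVEL_FRACTIONS)) if spec.center is None
              else np.asarray(spec.center, float))
    t = rng.normal(0.0, spec.spread, size=spec.n)
    X = center + np.outer(t, u)
    if spec.sigma > 0:
        X = X + rng.normal(0.0, spec.sigma, size=X.shape)
    if spec.snap_to_grid:
        lattice = np.asarray(LEVEL_FRACTIONS)
        idx = np.abs(X[..., None] - lattice).argmin(axis=-1)
        X = lattice[idx]
    return pd.DataFrame(X, columns=list(spec.columns))


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Stereotyped two-neuron bursting trace with known metrics.

    Spikes are triangular excursions above the -20 mV detection
    threshold riding on a -50 mV baseline; the burst skeleton (period,
    duty cycle, spikes per burst, antiphase offset) is exact by
    construction, so the downstream classifier must recover it to within
    one sampling interval.
    """

    period: float = 10.0            # s
    spikes_per_burst: int = 12
    duty_cycle: float = 60.0        # %
    amp_mean: float = 0.030         # mean spike height above threshold (V)
    amp_cv: float = 0.02            # CV of spike heights within a burst
    phase: float = 0.5              # B's offset as a fraction of the period
    jitter: float = 0.0             # per-spike uniform time jitter (s)
    n_periods: int = 8
    dt: float = 1e-4                # sampling interval (s)
    baseline: float = -0.050        # V
    trough: float = -0.058          # interburst floor (V)
    spike_halfwidth: float = 0.003  # s

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 < self.duty_cycle < 100:
            raise ValueError("duty cycle must lie in (0, 100)")
        burst = self.duty_cycle / 100.0 * self.period
        if self.spikes_per_burst >= 2:
            spacing = burst / (self.spikes_per_burst - 1)
            if spacing <= 2.2 * self.spike_halfwidth:
                raise ValueError("infeasible: spikes would overlap "
                                 "(duty x period too small for spike count)")
            if spacing >= 1.0:
                raise ValueError("infeasible: intra-burst gaps would split the burst")
        if self.period - burst < 1.0 + 2 * self.spike_halfwidth:
            raise ValueError("infeasible: inter-burst interval below 1 s")


def _spike_heights(spec: SyntheticTraceSpec, n: int, rng) -> np.ndarray:
    """Heights above threshold with exact sample mean and CV (ddof=1)."""
    if n == 1 or spec.amp_cv == 0:
        return np.full(n, spec.amp_mean)
    z = rng.normal(size=n)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:
        return np.full(n, spec.amp_mean)
    return spec.amp_mean + z / sd * (spec.amp_cv * spec.amp_mean)


def gen_bursting_trace(spec: SyntheticTraceSpec, seed: int = 0):
    """Sampled (t, V) for two neurons; returns ``(t, V, truth)``.

    ``V`` has shape (2, n).  ``truth`` records the constructed period,
    duty cycle, phase, spike times and per-burst amplitude CV.
    """
    rng = np.random.default_rng(seed)
    total = spec.n_periods * spec.period + 1.0
    t = np.arange(0.0, total, spec.dt)
    burst_dur = spec.duty_cycle / 100.0 * spec.period
    offsets = (np.linspace(0.0, burst_dur, spec.spikes_per_burst)
               if spec.spikes_per_burst > 1 else np.array([burst_dur / 2]))
    truth_spikes = [[], []]
    V = np.full((2, t.size), spec.baseline)
    for neuron, t_shift in enumerate((0.0, spec.phase * spec.period)):
        for k in range(spec.n_periods):
            start = 0.3 + k * spec.period + t_shift
            times = start + offsets
            if spec.jitter > 0 and spec.spikes_per_burst > 2:
                # jitter interior spikes only, keeping first/mid/last anchors exact
                inner = slice(1, -1)
                times[inner] = times[inner] + rng.uniform(
                    -spec.jitter, spec.jitter, size=spec.spikes_per_burst - 2)
            times = np.round(times / spec.dt) * spec.dt  # snap peaks onto the grid
            if times[-1] > t[-1] - 2 * spec.spike_halfwidth:
                continue
            heights = _spike_heights(spec, len(times), rng)
            for ts, hgt in zip(times, heights):
                peak = SPIKE_THRESHOLD + hgt
                lo = max(0, int((ts - spec.spike_halfwidth) / spec.dt) - 1)
                hi = min(t.size, int((ts + spec.spike_halfwidth) / spec.dt) + 2)
                tri = peak - np.abs(t[lo:hi] - ts) / spec.spike_halfwidth \
                    * (peak - spec.baseline)
                np.maximum(V[neuron, lo:hi], tri, out=V[neuron, lo:hi])
            truth_spikes[neuron].append(times)
    truth = {
        "period": spec.period,
        "duty_cycle": spec.duty_cycle,
        "phase": spec.phase,
        "spike_frequency": ((spec.spikes_per_burst - 1) / burst_dur
                            if spec.spikes_per_burst > 1 else np.nan),
        "amp_cv": spec.amp_cv if spec.spikes_per_burst > 1 else 0.0,
        "spike_times": tuple(np.concatenate(s) if s else np.empty(0)
                             for s in truth_spikes),
    }
    return t, V, truth


def gen_family_table(census: dict[int, int], varied: str = "K2", *,
                     seed: int = 0, periods=None,
                     category: str = "burster") -> pd.DataFrame:
    """Instance table whose family partition has exactly the given census.

    ``census`` maps family size -> number of families.  Fixed-parameter
    tuples are drawn without replacement from the lattice; the varied
    parameter takes ``size`` distinct ascending levels per family.
    ``periods`` may be a list of per-family period sequences (ascending
    in the varied parameter) consumed in construction order; otherwise
    periods decrease linearly with the varied level.
    """
    if varied not in PARAM_COLUMNS:
        raise KeyError(f"{varied!r} is not a swept parameter")
    for size in census:
        if size > len(DEFAULT_LEVELS):
            raise ValueError(f"family size {size} exceeds the {len(DEFAULT_LEVELS)}-level lattice")
    rng = np.random.default_rng(seed)
    fixed_cols = [c for c in PARAM_COLUMNS if c != varied]
    rows = []
    used = set()
    period_iter = iter(periods) if periods is not None else None
    for size, count in sorted(census.items()):
        for _ in range(count):
            while True:
                fixed = tuple(
                    int(rng.choice(DEFAULT_ELEAK_MV)) if c == "E_Leak"
                    else int(rng.choice(DEFAULT_LEVELS)) for c in fixed_cols)
                if fixed not in used:
                    used.add(fixed)
                    break
            lev = np.sort(rng.choice(DEFAULT_LEVELS, size=size, replace=False))
            fam_periods = (list(next(period_iter)) if period_iter is not None
                           else [12.0 - 0.02 * v for v in lev])
            if len(fam_periods) != size:
                raise ValueError("period sequence length must equal family size")
            for v, per in zip(lev, fam_periods):
                row = dict(zip(fixed_cols, fixed))
                row[varied] = int(v)
                row["period"] = float(per)
                row["category"] = category
                row["realistic"] = 1
                rows.append(row)
    return pd.DataFrame(rows, columns=list(PARAM_COLUMNS)
                        + ["period", "category", "realistic"])
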