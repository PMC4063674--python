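"""Parameter-grid enumeration, sweep orchestration, and the instance store.

The screen varies seven maximal conductances (SynS, SynG, P, K2, h, CaS,
Leak) over percent-of-canonical levels {0, 25, 50, 75, 100, 125, 150,
175} and the leak reversal potential over {-70, -65, -60, -55, -50} mV,
in all combinations: 8**7 * 5 = 10,485,760 instances, of which the
163,840 with both synapses at 0% are isolated twin-neuron instances.

Classified instances live in a single-file SQLite store with one row per
grid point (the parameter tuple is the primary key) and SQL views for
the four groups of interest (HCOs, realistic HCOs, bursters, realistic
bursters).  Sweeps are resumable: already-stored grid points are never
re-simulated.
"""

from __future__ import annotations

import itertools
import json
import sqlite3
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .classify import _finite_max, classify_instance, metrics_from_trace
from .model import SWEPT_CONDUCTANCES, ModelParameters, canonical_parameters
from .simulate import SimulationProtocol, canonical_initial_conditions, simulate_instance

__all__ = ["ParameterVector", "GridSpec", "enumerate_grid", "SweepStore",
           "run_sweep", "query_group", "cross_reference_hco_components",
           "DEFAULT_LEVELS", "DEFAULT_ELEAK_MV", "PARAM_COLUMNS", "VIEWS"]

DEFAULT_LEVELS = (0, 25, 50, 75, 100, 125, 150, 175)      # % of canonical
DEFAULT_ELEAK_MV = (-70, -65, -60, -55, -50)

#: column order of the swept parameters, everywhere in the package
PARAM_COLUMNS = ("SynS", "SynG", "P", "K2", "h", "CaS", "Leak", "E_Leak")

#: intrinsic (non-synaptic) swept parameters
INTRINSIC_COLUMNS = ("P", "K2", "h", "CaS", "Leak", "E_Leak")


@dataclass(frozen=True)
class ParameterVector:
    """One grid point: integer percent levels plus E_Leak in integer mV."""

    SynS: int
    SynG: int
    P: int
    K2: int
    h: int
    CaS: int
    Leak: int
    E_Leak: int

    def __post_init__(self):
        for name in SWEPT_CONDUCTANCES:
            v = getattr(self, name)
            if not 0 <= v <= 1000:
                raise ValueError(f"{name} level {v}% out of range")
        if not -100 <= self.E_Leak <= 0:
            raise ValueError(f"E_Leak {self.E_Leak} mV out of range")

    @property
    def is_isolated(self) -> bool:
        return self.SynS == 0 and self.SynG == 0

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in PARAM_COLUMNS)

    def intrinsic_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in INTRINSIC_COLUMNS)

    def to_model_parameters(self, base: ModelParameters | None = None) -> ModelParameters:
        """Scale the canonical conductances by the percent levels (SI units)."""
        base = base or canonical_parameters()
        gbar = dict(base.gbar)
        for name in SWEPT_CONDUCTANCES:
            gbar[name] = base.gbar[name] * getattr(self, name) / 100.0
        return ModelParameters(gbar=gbar, E_Leak=self.E_Leak * 1e-3,
                               C=base.C, I_inject=base.I_inject)


# named grid restrictions; percent levels / mV as stored
RESTRICTIONS: dict[str, Callable[[ParameterVector], bool]] = {
    "full": lambda v: True,
    "isolated": lambda v: v.is_isolated,
    "coupled": lambda v: not v.is_isolated,
    # canonical-restricted subsets: CaS and h at 100%, synapses at 100% (coupled)
    # or absent (isolated); gP, gK2, gLeak and E_Leak vary
    "canonical_coupled": lambda v: (v.CaS == 100 and v.h == 100
                                    and v.SynS == 100 and v.SynG == 100),
    "canonical_isolated": lambda v: (v.CaS == 100 and v.h == 100
                                     and v.SynS == 0 and v.SynG == 0),
}


@dataclass(frozen=True)
class GridSpec:
    """Level lists per parameter plus an optional named restriction."""

    levels: dict = field(default_factory=lambda: {
        c: DEFAULT_LEVELS for c in SWEPT_CONDUCTANCES})
    eleak_mv: Sequence[int] = DEFAULT_ELEAK_MV
    restriction: str | None = None

    def __post_init__(self):
        for c in SWEPT_CONDUCTANCES:
            if c not in self.levels or not len(self.levels[c]):
                raise ValueError(f"empty level list for {c}")
        if not len(self.eleak_mv):
            raise ValueError("empty E_Leak level list")
        if self.restriction is not None and self.restriction not in RESTRICTIONS:
            raise ValueError(f"unknown restriction {self.restriction!r}")

    @property
    def unrestricted_size(self) -> int:
        n = len(self.eleak_mv)
        for c in SWEPT_CONDUCTANCES:
            n *= len(self.levels[c])
        return n


def enumerate_grid(g: GridSpec) -> Iterator[ParameterVector]:
    """Yield grid points in deterministic lexicographic order.

    The iteration order follows ``PARAM_COLUMNS`` with the last column
    varying fastest, restricted by the grid's named predicate.
    """
    pred = RESTRICTIONS[g.restriction] if g.restriction else None
    axes = [g.levels[c] for c in SWEPT_CONDUCTANCES] + [list(g.eleak_mv)]
    for combo in itertools.product(*axes):
        v = ParameterVector(*combo)
        if pred is None or pred(v):
            yield v


_SCHEMA = """
CREATE TABLE IF NOT EXISTS instances (
    SynS INTEGER NOT NULL, SynG INTEGER NOT NULL, P INTEGER NOT NULL,
    K2 INTEGER NOT NULL, h INTEGER NOT NULL, CaS INTEGER NOT NULL,
    Leak INTEGER NOT NULL, E_Leak INTEGER NOT NULL,
    category TEXT NOT NULL, realistic INTEGER NOT NULL,
    period REAL, period_cv REAL, spike_frequency REAL, duty_cycle REAL,
    phase REAL, max_amp_cv REAL, min_v_a REAL, min_v_b REAL,
    n_bursts_a INTEGER, n_bursts_b INTEGER,
    PRIMARY KEY (SynS, SynG, P, K2, h, CaS, Leak, E_Leak)
);
CREATE TABLE IF NOT EXISTS provenance (key TEXT PRIMARY KEY, value TEXT);
CREATE VIEW IF NOT EXISTS hcos AS
    SELECT * FROM instances WHERE category = 'HCO';
CREATE VIEW IF NOT EXISTS realistic_hcos AS
    SELECT * FROM instances WHERE category = 'HCO' AND realistic = 1;
CREATE VIEW IF NOT EXISTS bursters AS
    SELECT * FROM instances WHERE category = 'burster';
CREATE VIEW IF NOT EXISTS realistic_bursters AS
    SELECT * FROM instances WHERE category = 'burster' AND realistic = 1;
"""

VIEWS = ("hcos", "realistic_hcos", "bursters", "realistic_bursters")


class SweepStore:
    """SQLite-backed store of classified instances (one row per grid point)."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.con = sqlite3.connect(self.path)
        self.con.executescript(_SCHEMA)
        self.con.commit()

    def close(self):
        self.con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- provenance -------------------------------------------------------
    def set_provenance(self, **kv):
        """Record solver settings etc.; refuses to overwrite with different values."""
        for k, v in kv.items():
            txt = json.dumps(v, sort_keys=True)
            cur = self.con.execute("SELECT value FROM provenance WHERE key=?", (k,))
            row = cur.fetchone()
            if row is not None and row[0] != txt:
                raise ValueError(f"store provenance conflict for {k!r}: "
                                 f"{row[0]} != {txt}")
            self.con.execute(
                "INSERT OR REPLACE INTO provenance (key, value) VALUES (?, ?)",
                (k, txt))
        self.con.commit()

    def provenance(self) -> dict:
        cur = self.con.execute("SELECT key, value FROM provenance")
        return {k: json.loads(v) for k, v in cur.fetchall()}

    # -- records ----------------------------------------------------------
    def has(self, v: ParameterVector) -> bool:
        cur = self.con.execute(
            "SELECT 1 FROM instances WHERE SynS=? AND SynG=? AND P=? AND K2=? "
            "AND h=? AND CaS=? AND Leak=? AND E_Leak=?", v.as_tuple())
        return cur.fetchone() is not None

    def existing_keys(self) -> set[tuple]:
        cur = self.con.execute(
            f"SELECT {', '.join(PARAM_COLUMNS)} FROM instances")
        return set(cur.fetchall())

    def insert(self, v: ParameterVector, label, metrics):
        row = v.as_tuple() + (
            label.category, int(label.realistic),
            _f(metrics.mean_period), _f(_finite_max(metrics.period_cv)),
            _f(metrics.mean_spike_frequency), _f(metrics.mean_duty_cycle),
            _f(metrics.phase), _f(_finite_max(metrics.max_amp_cv)),
            _f(metrics.min_V[0]), _f(metrics.min_V[1]),
            metrics.n_bursts[0], metrics.n_bursts[1])
        self.con.execute(
            "INSERT OR REPLACE INTO instances VALUES "
            "(?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)", row)

    def commit(self):
        self.con.commit()

    def dataframe(self, query: str = "SELECT * FROM instances") -> pd.DataFrame:
        return pd.read_sql_query(query, self.con)

    def count(self, view_or_table: str = "instances") -> int:
        self._check_view(view_or_table)
        cur = self.con.execute(f"SELECT COUNT(*) FROM {view_or_table}")
        return cur.fetchone()[0]

    def _check_view(self, name: str):
        if name not in VIEWS + ("instances",):
            raise KeyError(f"unknown view {name!r}; have {VIEWS}")


def _f(x):
    return None if x is None or (isinstance(x, float) and not np.isfinite(x)) else float(x)


def run_sweep(g: GridSpec, proto: SimulationProtocol | None = None,
              store: SweepStore | None = None, *, n_jobs: int = 1,
              progress: bool = False, commit_every: int = 200) -> dict:
    """Simulate + classify every grid point exactly once (resumable).

    Grid points already present in the store are skipped, so re-running
    a completed sweep performs zero new simulations.  Returns a report
    with per-category counts over the grid and the number of newly run
    simulations.
    """
    proto = proto or SimulationProtocol()
    store = store if store is not None else SweepStore()
    store.set_provenance(protocol={
        "warmup": proto.warmup, "settle": proto.settle, "record": proto.record,
        "dt": proto.dt, "method": proto.method})
    ics = canonical_initial_conditions(proto=proto)
    done = store.existing_keys()
    todo, n_grid = [], 0
    for v in enumerate_grid(g):
        n_grid += 1
        if v.as_tuple() not in done:
            todo.append(v)

    def _one(v: ParameterVector):
        trace = simulate_instance(v.to_model_parameters(), ics, proto)
        m = metrics_from_trace(trace, window=(0.0, proto.record))
        return v, classify_instance(m, isolated=v.is_isolated), m

    iterator: Iterable = todo
    if progress:
        from tqdm import tqdm
        iterator = tqdm(todo, desc="sweep", unit="inst")
    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(delayed(_one)(v) for v in iterator)
        for v, label, m in results:
            store.insert(v, label, m)
    else:
        for i, v in enumerate(iterator):
            store.insert(v, *(_one(v)[1:]))
            if (i + 1) % commit_every == 0:
                store.commit()
    store.commit()
    df = store.dataframe()
    counts = df["category"].value_counts().to_dict()
    report = {"grid_points": n_grid, "new_simulations": len(todo),
              "counts": counts,
              "realistic_hco": int(((df.category == "HCO") & (df.realistic == 1)).sum()),
              "realistic_burster": int(((df.category == "burster")
                                        & (df.realistic == 1)).sum()),
              "failed": int((df.category == "failed").sum())}
    return report


def query_group(store: SweepStore, predicate: str) -> pd.DataFrame:
    """Instances of a named view, or of an arbitrary SQL WHERE predicate."""
    if predicate in VIEWS + ("instances",):
        return store.dataframe(f"SELECT * FROM {predicate}")
    return store.dataframe(f"SELECT * FROM instances WHERE {predicate}")


def cross_reference_hco_components(store: SweepStore, *,
                                   warn_on_partial: bool = True) -> pd.DataFrame:
    """For each isolated burster, count coupled HCOs sharing its intrinsic set.

    Returns one row per burster (intrinsic parameter tuple) with the
    number of coupled instances carrying any nonzero synaptic combination
    that classify as HCO / realistic HCO.
    """
    import warnings

    bursters = store.dataframe("SELECT * FROM bursters")
    coupled = store.dataframe(
        "SELECT * FROM instances WHERE SynS > 0 OR SynG > 0")
    rows = []
    key = list(INTRINSIC_COLUMNS)
    grouped = coupled.groupby(key) if len(coupled) else None
    for _, b in bursters.iterrows():
        k = tuple(int(b[c]) for c in key)
        try:
            sub = grouped.get_group(k) if grouped is not None else coupled.iloc[0:0]
        except KeyError:
            sub = coupled.iloc[0:0]
        if not len(sub) and warn_on_partial:
            warnings.warn(f"no coupled coverage for burster {k}", stacklevel=2)
        rows.append(dict(zip(key, k), realistic=int(b["realistic"]),
                         n_coupled=len(sub),
                         n_hco=int((sub.category == "HCO").sum()),
                         n_realistic_hco=int(((sub.category == "HCO")
                                              & (sub.realistic == 1)).sum())))
    return pd.DataFrame(rows, columns=key + ["realistic", "n_coupled",
                                             "n_hco", "n_realistic_hco"])
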