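"""One-parameter families and period sensitivity.

A *family* is a subset of a group whose members share every swept
parameter value except one.  Partitioning a group into families along a
chosen parameter measures how robust the group is to that parameter:
large families mean the behavior survives many levels; the period change
between the extreme members measures the parameter's leverage on the
cycle period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sweep import PARAM_COLUMNS

__all__ = ["Family", "partition_families", "family_size_census",
           "family_period_change", "period_change_table", "monotonicity_report"]


@dataclass
class Family:
    """Members identical in everything but ``varied``, sorted ascending by it."""

    varied: str
    members: pd.DataFrame
    fixed: tuple

    def __post_init__(self):
        if not len(self.members):
            raise ValueError("a family needs at least one member")
        vals = self.members[self.varied].to_numpy()
        if np.any(np.diff(vals) <= 0):
            raise ValueError("members must be strictly ascending in the varied parameter")

    @property
    def size(self) -> int:
        return len(self.members)


def partition_families(group: pd.DataFrame, varied: str) -> list[Family]:
    """Exact partition of a group into families along one parameter."""
    if varied not in PARAM_COLUMNS:
        raise KeyError(f"{varied!r} is not a swept parameter")
    fixed_cols = [c for c in PARAM_COLUMNS if c != varied]
    out = []
    for key, sub in group.groupby(fixed_cols, sort=True):
        sub = sub.sort_values(varied)
        out.append(Family(varied=varied, members=sub.reset_index(drop=True),
                          fixed=tuple(key)))
    return out


def family_size_census(group: pd.DataFrame, varied: str) -> dict[int, int]:
    """Histogram of family sizes; sum(size * count) equals the group size."""
    census: dict[int, int] = {}
    for fam in partition_families(group, varied):
        census[fam.size] = census.get(fam.size, 0) + 1
    return dict(sorted(census.items()))


def family_period_change(f: Family, period_col: str = "period") -> float:
    """period(last member) - period(first member), ascending in the varied value.

    Undefined (raises) for singleton families or missing periods.
    """
    if f.size < 2:
        raise ValueError("period change undefined for a singleton family")
    p = f.members[period_col].to_numpy(float)
    if np.isnan(p[[0, -1]]).any():
        raise ValueError("first/last member has no defined period")
    return float(p[-1] - p[0])


def period_change_table(group: pd.DataFrame, varied: str,
                        period_col: str = "period") -> pd.DataFrame:
    """Per-family period deltas for all non-singleton families."""
    rows = []
    for fam in partition_families(group, varied):
        if fam.size < 2:
            continue
        p = fam.members[period_col].to_numpy(float)
        if np.isnan(p).any():
            continue
        rows.append({"varied": varied, "size": fam.size,
                     "fixed": fam.fixed,
                     "delta_period": float(p[-1] - p[0]),
                     "monotone_decreasing": bool(np.all(np.diff(p) < 0))})
    return pd.DataFrame(rows, columns=["varied", "size", "fixed",
                                       "delta_period", "monotone_decreasing"])


def monotonicity_report(group: pd.DataFrame, varied: str,
                        period_col: str = "period") -> dict:
    """Fraction of multi-member families whose period decreases monotonically."""
    tab = period_change_table(group, varied, period_col)
    n = len(tab)
    mono = int(tab["monotone_decreasing"].sum()) if n else 0
    return {"families": n, "monotone_decreasing": mono,
            "fraction": mono / n if n else np.nan}
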