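"""Correlation analytics over classified instance groups.

The analyses that exposed the gP-gK2-gLeak relationship:

- principal component analysis of each group's parameter matrix
  (centered, unscaled), with the *main components* defined as the
  smallest leading set whose cumulative explained variance exceeds 95%;
- the 3D orthogonal-distance-regression (total-least-squares) line: the
  line through the centroid along the first principal component, which
  minimizes the summed squared perpendicular distances to the points;
- two-sided two-sample Kolmogorov-Smirnov tests on per-axis level
  distributions, with the asymptotic p-value at alpha = 0.05;
- per-axis level histograms and pairwise count maps (with the
  log point-size rule used for display).

Conductances enter the analysis space as fractions of canonical
(0-1.75) and the leak reversal potential in volts, so a level of 175%
maps to 1.75 and E_Leak = -70 mV maps to -0.070.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sweep import PARAM_COLUMNS

__all__ = ["AnalysisMatrix", "PCAResult", "ODRLine3D", "KSTestResult",
           "build_analysis_matrix", "pca_group", "select_main_components",
           "odr_line_3d", "ks_two_sample", "axis_distribution",
           "pairwise_count_map"]

#: columns dropped for isolated groups (identically zero there)
SYNAPTIC_COLUMNS = ("SynS", "SynG")


@dataclass(frozen=True)
class AnalysisMatrix:
    """Instances-by-parameters matrix in analysis units."""

    X: np.ndarray
    columns: tuple
    group: str = ""

    def __post_init__(self):
        if np.isnan(self.X).any():
            raise ValueError("analysis matrix must not contain missing values")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")


@dataclass(frozen=True)
class PCAResult:
    """Unit-norm component coefficients, variance fractions, main count."""

    coefficients: np.ndarray   # (n_params, n_components), columns = components
    variance_pct: np.ndarray   # explained variance per component, sums to 100
    n_main: int
    columns: tuple = ()

    @property
    def first_component(self) -> np.ndarray:
        return self.coefficients[:, 0]


@dataclass(frozen=True)
class ODRLine3D:
    """Total-least-squares line: centroid + unit direction."""

    centroid: np.ndarray
    direction: np.ndarray
    residual_ss: float         # summed squared orthogonal distances

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal distance of each point to the line."""
        d = np.atleast_2d(points) - self.centroid
        proj = d @ self.direction
        return np.linalg.norm(d - np.outer(proj, self.direction), axis=1)


@dataclass(frozen=True)
class KSTestResult:
    k: float      # sup |ECDF_x - ECDF_y|
    p: float      # asymptotic two-sided p-value
    h: bool       # reject the null at alpha


def build_analysis_matrix(group: pd.DataFrame, *, group_name: str = "",
                          drop_synaptic: bool | None = None) -> AnalysisMatrix:
    """Convert stored integer levels to analysis units.

    Percent levels become fractions of canonical; E_Leak (mV) becomes
    volts.  For isolated groups (bursters) the two identically-zero
    synaptic columns are dropped, leaving six columns; pass
    ``drop_synaptic`` to override the automatic choice.
    """
    if not len(group):
        raise ValueError("empty group")
    if drop_synaptic is None:
        drop_synaptic = bool((group["SynS"] == 0).all()
                             and (group["SynG"] == 0).all())
    cols = tuple(c for c in PARAM_COLUMNS
                 if not (drop_synaptic and c in SYNAPTIC_COLUMNS))
    X = np.empty((len(group), len(cols)))
    for j, c in enumerate(cols):
        X[:, j] = group[c].to_numpy(float) * (1e-3 if c == "E_Leak" else 1e-2)
    return AnalysisMatrix(X=X, columns=cols, group=group_name)


def pca_group(M: AnalysisMatrix | np.ndarray, threshold: float = 95.0) -> PCAResult:
    """Centered, unscaled PCA of a group's analysis matrix.

    Component signs are fixed so each component's largest-magnitude
    coefficient is negative (signs are arbitrary in PCA; a fixed
    convention makes coefficient tables comparable across groups).
    """
    X = M.X if isinstance(M, AnalysisMatrix) else np.asarray(M, float)
    cols = M.columns if isinstance(M, AnalysisMatrix) else tuple(range(X.shape[1]))
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} rows for {d} parameters, got {n}")
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coeff = Vt.T
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("degenerate group: all instances identical")
    pct = var / total * 100.0
    for j in range(coeff.shape[1]):
        i = np.argmax(np.abs(coeff[:, j]))
        if coeff[i, j] > 0:
            coeff[:, j] = -coeff[:, j]
    return PCAResult(coefficients=coeff, variance_pct=pct,
                     n_main=select_main_components(pct, threshold), columns=cols)


def select_main_components(variance_pct, threshold: float = 95.0) -> int:
    """Smallest k such that the top-k cumulative variance exceeds threshold."""
    v = np.asarray(variance_pct, float)
    if np.any(np.diff(v) > 1e-9):
        raise ValueError("variance fractions must be nonincreasing")
    cum = np.cumsum(v)
    above = np.flatnonzero(cum > threshold)
    return int(above[0]) + 1 if above.size else len(v)


def odr_line_3d(points: np.ndarray, weights=None) -> ODRLine3D:
    """Orthogonal-distance-regression line through a 3-D point cloud.

    The line passes through the (weighted) centroid with direction given
    by the first principal component; this minimizes the summed squared
    orthogonal distances over all lines.  ``weights`` are instance
    multiplicities for lattice points that represent several instances.
    """
    P = np.atleast_2d(np.asarray(points, float))
    if P.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if P.shape[0] < 2:
        raise ValueError("need at least two points")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, float)
    if np.ptp(P, axis=0).max() == 0:
        raise ValueError("all points identical: line direction undefined")
    centroid = (P * w[:, None]).sum(axis=0) / w.sum()
    D = (P - centroid) * np.sqrt(w)[:, None]
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    direction = Vt[0]
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    residual = float((s ** 2)[1:].sum())
    return ODRLine3D(centroid=centroid, direction=direction, residual_ss=residual)


def ks_two_sample(x, y, alpha: float = 0.05) -> KSTestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    k is the supremum of |ECDF_x - ECDF_y|; the p-value uses the
    asymptotic Kolmogorov distribution with the small-sample correction
    ``lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * k`` where
    ``ne = nx * ny / (nx + ny)``.  Ties (heavily present for lattice
    levels) are handled by the ECDF definition itself.
    """
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    k = float(np.abs(cdf_x - cdf_y).max())
    ne = x.size * y.size / (x.size + y.size)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * k
    j = np.arange(1, 102)
    p = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * lam ** 2 * j ** 2))
    p = float(min(max(p, 0.0), 1.0))
    return KSTestResult(k=k, p=p, h=bool(p < alpha))


def axis_distribution(group: pd.DataFrame, param: str,
                      levels=None) -> pd.Series:
    """Instance counts per grid level of one parameter (totals group size)."""
    if param not in PARAM_COLUMNS:
        raise KeyError(f"unknown parameter {param!r}")
    counts = group[param].value_counts().sort_index()
    if levels is not None:
        counts = counts.reindex(list(levels), fill_value=0)
    counts.name = f"n_{param}"
    return counts


def pairwise_count_map(group: pd.DataFrame, p1: str, p2: str,
                       levels1=None, levels2=None) -> pd.DataFrame:
    """Counts over the p1 x p2 level lattice plus display point sizes.

    The display size is ``ln(count) + 1`` for occupied cells (so a count
    of 1 draws at size 1) and 0 for empty cells.
    """
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    for p in (p1, p2):
        if p not in PARAM_COLUMNS:
            raise KeyError(f"unknown parameter {p!r}")
    counts = pd.crosstab(group[p1], group[p2])
    if levels1 is not None:
        counts = counts.reindex(index=list(levels1), fill_value=0)
    if levels2 is not None:
        counts = counts.reindex(columns=list(levels2), fill_value=0)
    out = counts.stack().rename("count").reset_index()
    out["size"] = np.where(out["count"] > 0,
                           np.log(out["count"].clip(lower=1)) + 1.0, 0.0)
    return out
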