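"""Fuzzy-matrix column pipeline: statistics, standardization, min-max
normalization, defuzzification and multi-expert aggregation.

Both method segments share this pipeline: the pairwise criteria matrix
(g x g, zero-filled diagonal) and the alternatives-by-criteria
performance matrix (f x g) are put on a common per-column scale before
the crisp stages downstream.

Two routes are provided:

* the *fuzzy-first* route applies standardization and min-max
  normalization with TSFN arithmetic and defuzzifies at the end
  (operations :func:`standardize`, :func:`minmax_normalize`,
  :func:`defuzzify`);
* the *score-first* route defuzzifies each cell first and applies the
  same standardization and min-max steps to the crisp scores
  (:func:`crisp_pipeline`).

The score-first route is the package default: it maps equal linguistic
codes in a column to equal crisp values, preserves the score ordering of
the scale within every column, and reproduces the published worked
example; the fuzzy-first route is retained as the literal composition of
the fuzzy operator laws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import tsfn as T
from .tsfn import TSFN, ZERO, MembershipPolicy, DEFAULT_POLICY

__all__ = [
    "FuzzyMatrix",
    "ColumnStats",
    "column_stats",
    "standardize",
    "minmax_normalize",
    "defuzzify",
    "aggregate_experts",
    "crisp_pipeline",
    "read_crisp_csv",
    "write_crisp_csv",
]

#: Crisp matrices are plain labelled DataFrames of floats.
CrispMatrix = pd.DataFrame


@dataclass
class FuzzyMatrix:
    """A labelled rectangular grid of TSFNs."""

    row_labels: list[str]
    column_labels: list[str]
    cells: list[list[TSFN]]

    def __post_init__(self) -> None:
        nr, nc = len(self.row_labels), len(self.column_labels)
        if len(set(self.row_labels)) != nr or len(set(self.column_labels)) != nc:
            raise ValueError("labels must be unique")
        if len(self.cells) != nr or any(len(r) != nc for r in self.cells):
            raise ValueError("cell grid does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.column_labels))

    def column(self, j: int) -> list[TSFN]:
        return [row[j] for row in self.cells]

    def map_cells(self, fn) -> "FuzzyMatrix":
        return FuzzyMatrix(list(self.row_labels), list(self.column_labels),
                           [[fn(v) for v in row] for row in self.cells])


@dataclass
class ColumnStats:
    """Per-column fuzzy mean and standard deviation of a fuzzy matrix."""

    means: list[TSFN]
    sds: list[TSFN]
    mean_divisor: int
    sd_divisor: int


def column_stats(m: FuzzyMatrix, mean_divisor: int, sd_divisor: int,
                 policy: MembershipPolicy = DEFAULT_POLICY) -> ColumnStats:
    """Fuzzy mean and SD of every column.

    The divisors are explicit: a pairwise matrix uses (g, g-1) with the
    zero diagonal fill counted, a performance matrix uses (f, f-1).
    """
    if not m.cells or not m.cells[0]:
        raise ValueError("empty matrix")
    means, sds = [], []
    for j in range(len(m.column_labels)):
        col = m.column(j)
        mean = T.fuzzy_mean(col, mean_divisor, policy)
        sd = T.fuzzy_sd(col, mean, sd_divisor, policy)
        means.append(mean)
        sds.append(sd)
    return ColumnStats(means, sds, mean_divisor, sd_divisor)


def standardize(m: FuzzyMatrix, stats: ColumnStats,
                policy: MembershipPolicy = DEFAULT_POLICY) -> FuzzyMatrix:
    """Cellwise ``(cell - column_mean) / column_sd`` via the total
    TSFN subtraction and division (guards make this never raise)."""
    if len(stats.means) != len(m.column_labels):
        raise ValueError("stats do not match matrix columns")
    out = []
    for row in m.cells:
        out.append([T.divide(T.subtract(v, stats.means[j], policy),
                             stats.sds[j], policy)
                    for j, v in enumerate(row)])
    return FuzzyMatrix(list(m.row_labels), list(m.column_labels), out)


def minmax_normalize(m: FuzzyMatrix,
                     scope: Literal["column", "matrix"] = "column",
                     policy: MembershipPolicy = DEFAULT_POLICY) -> FuzzyMatrix:
    """Min-max normalization ``(cell - min) / (max - min)``.

    Min and max cells are selected by the score ordering within the scope
    (default per column).  Cells that tie the scope minimum map to the
    zero element exactly (score 0 downstream); if the scope is constant
    (max ties min) every cell maps to the zero element.
    """
    nr, nc = m.shape

    def normalize_group(vals: list[TSFN]) -> list[TSFN]:
        keys = [T.sort_key(v) for v in vals]
        kmin, kmax = min(keys), max(keys)
        if kmin == kmax:
            return [ZERO] * len(vals)
        vmin = vals[keys.index(kmin)]
        vmax = vals[keys.index(kmax)]
        rng = T.subtract(vmax, vmin, policy)
        return [ZERO if k == kmin
                else T.divide(T.subtract(v, vmin, policy), rng, policy)
                for v, k in zip(vals, keys)]

    if scope == "matrix":
        flat = [v for row in m.cells for v in row]
        norm = normalize_group(flat)
        cells = [norm[i * nc:(i + 1) * nc] for i in range(nr)]
    elif scope == "column":
        cols = [normalize_group(m.column(j)) for j in range(nc)]
        cells = [[cols[j][i] for j in range(nc)] for i in range(nr)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return FuzzyMatrix(list(m.row_labels), list(m.column_labels), cells)


def defuzzify(m: FuzzyMatrix) -> CrispMatrix:
    """Cellwise graded-mean-integration score."""
    data = [[T.score(v) for v in row] for row in m.cells]
    return pd.DataFrame(data, index=m.row_labels, columns=m.column_labels,
                        dtype=float)


def aggregate_experts(mats: Sequence[CrispMatrix]) -> CrispMatrix:
    """Cellwise arithmetic mean over expert matrices (identical labels)."""
    if not mats:
        raise ValueError("no matrices to aggregate")
    first = mats[0]
    for m in mats[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("expert matrices must share shape and labels")
    return sum(mats[1:], first.copy()) / len(mats)


def crisp_pipeline(m: FuzzyMatrix, mean_divisor: int, sd_divisor: int,
                   scope: Literal["column", "matrix"] = "column") -> CrispMatrix:
    """Score-first column pipeline.

    Each cell is defuzzified, then every column is z-standardized
    (mean over ``mean_divisor`` entries, SD with ``sd_divisor`` in the
    denominator) and min-max normalized to [0, 1].  A constant column
    maps to zeros.  Equal codes in a column map to equal outputs and the
    scale's score ordering is preserved within each column.
    """
    s = defuzzify(m)
    if scope not in ("column", "matrix"):
        raise ValueError(f"unknown scope {scope!r}")

    def zscore(col: pd.Series) -> pd.Series:
        mean = col.sum() / mean_divisor
        var = ((col - mean) ** 2).sum() / sd_divisor
        sd = math.sqrt(var)
        if sd == 0.0:
            return col * 0.0
        return (col - mean) / sd

    z = s.apply(zscore, axis=0)
    if scope == "matrix":
        lo, hi = z.values.min(), z.values.max()
        if hi == lo:
            return z * 0.0
        return (z - lo) / (hi - lo)

    def mm(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            return col * 0.0
        return (col - lo) / (hi - lo)

    return z.apply(mm, axis=0)


def write_crisp_csv(m: CrispMatrix, path: Path) -> None:
    """CSV round-trip at 15 significant digits."""
    m.to_csv(path, float_format="%.15g")


def read_crisp_csv(path: Path) -> CrispMatrix:
    return pd.read_csv(path, index_col=0).astype(float)
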