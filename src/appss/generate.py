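"""Seeded random problem generator for property tests and simulation.

Emits a pairwise linguistic preference matrix (uniform over the scale's
terms off the diagonal), a count table whose cells are drawn by first
choosing a bin and then a count within it (so the table spans several
bins by construction), and a criteria hierarchy of near-equal groups.
Identical seeds give identical problems.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .linguistic import ABSENT, BinTable, LinguisticMatrix, covid_bins, default_scale
from .preference import CriteriaHierarchy

__all__ = ["generate_problem"]

_OPEN_BIN_SPAN = 5_000_000  # width used to sample from the unbounded bin


def generate_problem(seed: int, f: int, g: int,
                     hierarchy_shape: Optional[list[int]] = None,
                     bins: Optional[BinTable] = None,
                     ) -> tuple[LinguisticMatrix, pd.DataFrame, CriteriaHierarchy]:
    """Generate a random (PLPM, count table, hierarchy) triple.

    f alternatives, g criteria.  ``hierarchy_shape`` gives the group
    sizes (default: pairs, with a remainder group); it must sum to g.
    When the table is large enough (f*g >= 12) the bin-stratified draw is
    re-run until at least three distinct bins are hit, so the fuzzified
    matrix always has spread.
    """
    if f < 2 or g < 2:
        raise ValueError("need at least 2 alternatives and 2 criteria")
    rng = np.random.default_rng(seed)
    bins = bins if bins is not None else covid_bins()
    codes = default_scale().codes

    crit = [f"C{j+1}" for j in range(g)]
    alts = [f"d{i+1}" for i in range(f)]

    plpm_cells = [[ABSENT if i == j else codes[rng.integers(len(codes))]
                   for j in range(g)] for i in range(g)]
    plpm = LinguisticMatrix(list(crit), list(crit), plpm_cells, kind="PLPM")

    def draw_counts() -> np.ndarray:
        out = np.empty((f, g), dtype=np.int64)
        for i in range(f):
            for j in range(g):
                lo, hi, _ = bins.bins[rng.integers(len(bins.bins))]
                hi = lo + _OPEN_BIN_SPAN if hi is None else hi
                out[i, j] = rng.integers(lo, hi + 1)
        return out

    counts = draw_counts()
    if f * g >= 12:
        from .linguistic import bin_value
        while len({bin_value(int(v), bins) for v in counts.ravel()}) < 3:
            counts = draw_counts()
    data = pd.DataFrame(counts, index=alts, columns=crit)

    if hierarchy_shape is None:
        hierarchy_shape = [2] * (g // 2) + ([g % 2] if g % 2 else [])
    if sum(hierarchy_shape) != g or any(s < 1 for s in hierarchy_shape):
        raise ValueError("hierarchy_shape must be positive sizes summing to g")
    groups, k = {}, 0
    for gi, size in enumerate(hierarchy_shape):
        groups[f"G{gi+1}"] = crit[k:k + size]
        k += size
    return plpm, data, CriteriaHierarchy.from_dict(groups)
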