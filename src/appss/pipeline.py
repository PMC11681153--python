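"""End-to-end orchestration: preference -> performance -> satisfaction.

``run_pipeline`` wires the three stages together: the pairwise
linguistic preference matrix is put through the column pipeline and
weighted into the preference vector W; the count table is binned,
fuzzified and put through the same pipeline into the crisp performance
matrix; the associative iteration ranks the alternatives (R_B); and the
dominance flows over the converged scores yield the flow ranking (R_S)
and the satisfaction classification.  ``alpha_sweep`` repeats the run
over a grid of local/global blend values and reports whether the
ordering of alternatives is stable.

Stage injection allows starting from a precomputed crisp matrix (e.g. a
published intermediate) instead of the fuzzy stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .bam import BAMConfig, BAMState, iterate, rank_alternatives
from .linguistic import (BinTable, LinguisticMatrix, LinguisticScale,
                         bin_value, fuzzify)
from .matrices import (CrispMatrix, FuzzyMatrix, column_stats, crisp_pipeline,
                       defuzzify, minmax_normalize, standardize)
from .preference import CriteriaHierarchy, PreferenceVector, compute_preference
from .satisfaction import adjacency, flows, rank_and_classify
from .tsfn import MembershipPolicy, DEFAULT_POLICY

__all__ = ["RunConfig", "PipelineInputs", "Report", "run_pipeline",
           "alpha_sweep", "performance_matrix", "pairwise_matrix"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full run.

    alpha blends local vs global criteria weights (0.5 = equal).  The
    stage order selects the score-first column pipeline (default; see
    :mod:`appss.matrices`) or the literal fuzzy-first composition.
    """

    alpha: float = 0.5
    gc_mode: Literal["group_sum", "reciprocal"] = "group_sum"
    minmax_scope: Literal["column", "matrix"] = "column"
    stage_order: Literal["score_first", "fuzzy_first"] = "score_first"
    policy: MembershipPolicy = DEFAULT_POLICY
    bam: BAMConfig = BAMConfig()
    expert_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.stage_order not in ("score_first", "fuzzy_first"):
            raise ValueError(f"unknown stage_order {self.stage_order!r}")

    def echo(self) -> dict:
        return {
            "alpha": self.alpha, "gc_mode": self.gc_mode,
            "minmax_scope": self.minmax_scope,
            "stage_order": self.stage_order,
            "policy": {"mode": self.policy.mode.value,
                       "clamp_eps": self.policy.clamp_eps},
            "bam": dataclasses.asdict(self.bam),
            "expert_count": self.expert_count, "seed": self.seed,
        }


@dataclass
class PipelineInputs:
    """Inputs for a run; either linguistic inputs or crisp injections."""

    plpm: Optional[LinguisticMatrix] = None
    data: Optional[pd.DataFrame] = None          # counts, alternatives x criteria
    lpem: Optional[LinguisticMatrix] = None      # already-binned codes
    scale: Optional[LinguisticScale] = None
    bins: Optional[BinTable] = None
    hierarchy: Optional[CriteriaHierarchy] = None
    # stage injection: skip the fuzzy stages of either segment
    pairwise_crisp: Optional[CrispMatrix] = None
    performance_crisp: Optional[CrispMatrix] = None
    weights: Optional[PreferenceVector] = None


@dataclass
class Report:
    """Self-contained result of one run."""

    config: dict
    weights: PreferenceVector
    pairwise_crisp: CrispMatrix
    performance_crisp: CrispMatrix
    bam: BAMState
    ranks_rb: pd.Series
    flow_table: pd.DataFrame           # F+, F-, F, R_S, satisfaction, class
    version: str = _pkg_version

    @property
    def ordering(self) -> list[str]:
        """Alternative labels sorted by descending converged score."""
        return list(self.bam.x.sort_values(ascending=False, kind="stable").index)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "weights": self.weights.to_dict(),
            "x": self.bam.x.to_dict(),
            "converged": self.bam.converged,
            "iterations": self.bam.iteration,
            "ranks_rb": {k: int(v) for k, v in self.ranks_rb.items()},
            "flows": self.flow_table.to_dict(orient="index"),
            "ordering": self.ordering,
        }


def _column_pipeline(fm: FuzzyMatrix, mean_div: int, sd_div: int,
                     cfg: RunConfig) -> CrispMatrix:
    if cfg.stage_order == "score_first":
        return crisp_pipeline(fm, mean_div, sd_div, scope=cfg.minmax_scope)
    stats = column_stats(fm, mean_div, sd_div, cfg.policy)
    std = standardize(fm, stats, cfg.policy)
    norm = minmax_normalize(std, scope=cfg.minmax_scope, policy=cfg.policy)
    return defuzzify(norm)


def pairwise_matrix(plpm: LinguisticMatrix, scale: LinguisticScale,
                    cfg: RunConfig = RunConfig()) -> CrispMatrix:
    """Crisp pairwise preference matrix from the linguistic one."""
    g = len(plpm.column_labels)
    fm = fuzzify(plpm, scale)
    return _column_pipeline(fm, g, g - 1, cfg)


def performance_matrix(inputs: PipelineInputs,
                       cfg: RunConfig = RunConfig()) -> CrispMatrix:
    """Crisp performance matrix from counts (binned) or an LPeM."""
    if inputs.performance_crisp is not None:
        return inputs.performance_crisp
    if inputs.lpem is not None:
        lpem = inputs.lpem
    else:
        if inputs.data is None or inputs.bins is None:
            raise ValueError("need counts+bins, an LPeM, or a crisp injection")
        codes = [[bin_value(int(v), inputs.bins) for v in row]
                 for row in inputs.data.values]
        lpem = LinguisticMatrix(list(map(str, inputs.data.index)),
                                list(map(str, inputs.data.columns)),
                                codes, kind="LPeM")
    if inputs.scale is None:
        raise ValueError("a linguistic scale is required to fuzzify")
    f = len(lpem.row_labels)
    fm = fuzzify(lpem, inputs.scale)
    return _column_pipeline(fm, f, f - 1, cfg)


def run_pipeline(cfg: RunConfig, inputs: PipelineInputs) -> Report:
    """Full run; honors stage injection at any of the three entry points."""
    # Preference stage
    if inputs.weights is not None:
        w = inputs.weights
        q = inputs.pairwise_crisp if inputs.pairwise_crisp is not None \
            else pd.DataFrame()
    else:
        if inputs.pairwise_crisp is not None:
            q = inputs.pairwise_crisp
        else:
            if inputs.plpm is None or inputs.scale is None:
                raise ValueError("need a PLPM+scale, a crisp pairwise matrix, "
                                 "or injected weights")
            q = pairwise_matrix(inputs.plpm, inputs.scale, cfg)
        if inputs.hierarchy is None:
            raise ValueError("a criteria hierarchy is required for weighting")
        w = compute_preference(q, inputs.hierarchy, cfg.alpha, cfg.gc_mode)

    # Performance stage
    o = performance_matrix(inputs, cfg)

    # Association stage
    state = iterate(o, w, cfg.bam)
    rb = rank_alternatives(state.x)

    # Satisfaction stage
    p = adjacency(state.x)
    fl = rank_and_classify(flows(p), rb)
    table = pd.DataFrame({
        "F_plus": fl.positive, "F_minus": fl.negative, "F": fl.overall,
        "R_S": fl.ranks_rs, "R_B": rb, "satisfaction": fl.satisfaction,
        "class": fl.classes,
    })
    return Report(config=cfg.echo(), weights=w, pairwise_crisp=q,
                  performance_crisp=o, bam=state, ranks_rb=rb,
                  flow_table=table)


def alpha_sweep(cfg: RunConfig, inputs: PipelineInputs,
                alphas: Sequence[float]) -> pd.DataFrame:
    """One full run per alpha; returns ranks per alternative and whether
    the ordering is identical across the sweep (column ``stable``)."""
    if any(not 0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    rows, orderings = [], []
    for a in alphas:
        c = dataclasses.replace(cfg, alpha=float(a))
        rep = run_pipeline(c, inputs)
        row = {"alpha": float(a)}
        row.update({k: int(v) for k, v in rep.ranks_rb.items()})
        rows.append(row)
        orderings.append(tuple(rep.ordering))
    out = pd.DataFrame(rows)
    out["stable"] = len(set(orderings)) == 1
    return out
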