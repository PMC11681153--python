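"""Satisfaction scoring: dominance flows and the rank-shift classification.

The converged alternative scores induce a strict-dominance digraph
(P[a, a'] = 1 iff score_a > score_a').  Outranking-style flows summarize
it: the leaving flow F+ (row sum / (f-1)), the entering flow F-
(column sum / (f-1)) and the net flow F = F+ - F-.  Ranking the net
flows (R_S) and comparing with the associative ranking (R_B) gives the
satisfaction value R_S - R_B per alternative: 0 = most optimal,
> 0 = acceptable, < 0 = less optimal.

With distinct scores and strict dominance, net dominance is monotone in
the score, so R_S equals R_B identically and every satisfaction value is
0; nonzero values can only arise from ties or from an externally
supplied flow vector (accepted by :func:`rank_and_classify` for
reproducing alternative analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bam import rank_alternatives

__all__ = [
    "AdjacencyMatrix",
    "FlowResult",
    "adjacency",
    "net_dominance",
    "flows",
    "rank_and_classify",
]

MOST_OPTIMAL = "most_optimal"
ACCEPTABLE = "acceptable"
LESS_OPTIMAL = "less_optimal"

#: Binary dominance grid with zero diagonal (labelled DataFrame of 0/1).
AdjacencyMatrix = pd.DataFrame


@dataclass
class FlowResult:
    """Flows, flow-based ranks and the satisfaction classification."""

    positive: pd.Series               # F+ leaving flow
    negative: pd.Series               # F- entering flow
    overall: pd.Series                # F = F+ - F-
    ranks_rs: Optional[pd.Series] = None
    satisfaction: Optional[pd.Series] = None
    classes: Optional[pd.Series] = None


def adjacency(scores: pd.Series | Sequence[float]) -> AdjacencyMatrix:
    """Strict-dominance adjacency: 1 iff score_a > score_a'; ties give 0
    both ways; zero diagonal."""
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) \
        else scores
    v = s.values
    p = (v[:, None] > v[None, :]).astype(int)
    np.fill_diagonal(p, 0)
    return pd.DataFrame(p, index=s.index, columns=s.index)


def net_dominance(p: AdjacencyMatrix) -> pd.Series:
    """Wins minus losses per alternative: sum_a' (P[a,a'] - P[a',a])."""
    if p.shape[0] != p.shape[1]:
        raise ValueError("adjacency matrix must be square")
    return (p.sum(axis=1) - p.sum(axis=0)).astype(float)


def flows(p: AdjacencyMatrix) -> FlowResult:
    """Leaving, entering and net dominance flows of the digraph."""
    f = p.shape[0]
    if f < 2:
        raise ValueError("flows need at least two alternatives")
    pos = p.sum(axis=1) / (f - 1)
    neg = p.sum(axis=0) / (f - 1)
    neg.index = p.index  # entering flow labelled by alternative
    return FlowResult(positive=pos.astype(float), negative=neg.astype(float),
                      overall=(pos - neg).astype(float))


def rank_and_classify(f: FlowResult, r_b: pd.Series,
                      external_flows: Optional[pd.Series] = None) -> FlowResult:
    """Rank the net flows (competition ranking, descending) and classify.

    ``satisfaction = R_S - R_B``; 0 maps to most_optimal, positive to
    acceptable, negative to less_optimal.  ``external_flows`` replaces
    the computed net flow (for reproducing an externally supplied
    analysis) but keeps F+/F- as computed.
    """
    overall = external_flows if external_flows is not None else f.overall
    if len(overall) != len(r_b):
        raise ValueError("flow vector and R_B have different lengths")
    r_s = rank_alternatives(overall)
    sat = (r_s - r_b.astype(int)).astype(int)

    def classify(v: int) -> str:
        if v == 0:
            return MOST_OPTIMAL
        return ACCEPTABLE if v > 0 else LESS_OPTIMAL

    classes = sat.map(classify)
    classes.name = "class"
    return FlowResult(positive=f.positive, negative=f.negative,
                      overall=pd.Series(overall, dtype=float),
                      ranks_rs=r_s, satisfaction=sat, classes=classes)
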