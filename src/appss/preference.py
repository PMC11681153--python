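"""Criteria weighting from the defuzzified pairwise preference matrix.

Local criteria (leaves, e.g. male/female deaths) sit under global
criteria (their parent categories).  Local weights are the off-diagonal
row sums of the crisp pairwise matrix — the total preference each
criterion expresses over the others.  Global weights aggregate the local
weights within each group.  The two are blended by ``alpha`` (1 = local
only, 0 = global only) and normalized into the preference vector W that
seeds the associative ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .matrices import CrispMatrix

__all__ = [
    "CriteriaHierarchy",
    "PreferenceVector",
    "local_weights",
    "global_weights",
    "overall_scores",
    "preference_vector",
]


@dataclass(frozen=True)
class CriteriaHierarchy:
    """Mapping of global-criterion label to its ordered local criteria."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups",
                           {g: tuple(ls) for g, ls in self.groups.items()})
        seen: set[str] = set()
        for g, locals_ in self.groups.items():
            for c in locals_:
                if c in seen:
                    raise ValueError(f"criterion {c!r} appears in two groups")
                seen.add(c)

    @property
    def local_criteria(self) -> list[str]:
        return [c for ls in self.groups.values() for c in ls]

    def group_of(self, criterion: str) -> str:
        for g, ls in self.groups.items():
            if criterion in ls:
                return g
        raise KeyError(f"criterion {criterion!r} not in hierarchy")

    def validate_against(self, labels: list[str]) -> None:
        if sorted(self.local_criteria) != sorted(labels):
            raise ValueError("hierarchy does not partition the criteria: "
                             f"{self.local_criteria} vs {labels}")

    def to_dict(self) -> dict:
        return {g: list(ls) for g, ls in self.groups.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, list[str]]) -> "CriteriaHierarchy":
        return cls({g: tuple(ls) for g, ls in d.items()})


@dataclass(frozen=True)
class PreferenceVector:
    """Normalized criteria weights with their provenance.

    ``weights`` sum to 1; ``lc``/``gc`` record the local and global
    components and ``alpha`` the blend used.
    """

    weights: Mapping[str, float]
    alpha: float
    lc: Mapping[str, float]
    gc: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lc", dict(self.lc))
        object.__setattr__(self, "gc", dict(self.gc))
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, dtype=float)

    def to_dict(self) -> dict:
        return {"weights": dict(self.weights), "alpha": self.alpha,
                "lc": dict(self.lc), "gc": dict(self.gc)}


def local_weights(q: CrispMatrix) -> dict[str, float]:
    """Off-diagonal row sums of the crisp pairwise matrix.

    Row b holds the (normalized, defuzzified) preferences criterion b
    expresses over every other criterion; their sum is its local weight.
    """
    if q.shape[0] != q.shape[1]:
        raise ValueError("pairwise matrix must be square")
    out = {}
    for i, lab in enumerate(q.index):
        out[str(lab)] = float(q.iloc[i].sum() - q.iloc[i, i])
    return out


def global_weights(lc: Mapping[str, float], h: CriteriaHierarchy,
                   mode: Literal["group_sum", "reciprocal"] = "group_sum",
                   ) -> dict[str, float]:
    """Global weight of each local criterion.

    ``group_sum`` (default): the sum of local weights within the
    criterion's group — every sibling shares the group total.
    ``reciprocal``: total local weight divided by the criterion's own
    local weight (an alternative published form; it inverts the ordering
    and is kept for comparison).
    """
    h.validate_against(list(lc))
    if mode == "group_sum":
        return {c: sum(lc[s] for s in h.groups[h.group_of(c)]) for c in lc}
    if mode == "reciprocal":
        total = sum(lc.values())
        if any(v == 0 for v in lc.values()):
            raise ZeroDivisionError("reciprocal mode with a zero local weight")
        return {c: total / lc[c] for c in lc}
    raise ValueError(f"unknown mode {mode!r}")


def overall_scores(lc: Mapping[str, float], gc: Mapping[str, float],
                   alpha: float) -> dict[str, float]:
    """Blend ``(LC*alpha + GC*(1-alpha)) / 2`` per criterion.

    The /2 is retained from the published form; it cancels in the final
    normalization.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return {c: (lc[c] * alpha + gc[c] * (1.0 - alpha)) / 2.0 for c in lc}


def preference_vector(overall: Mapping[str, float], alpha: float,
                      lc: Mapping[str, float] | None = None,
                      gc: Mapping[str, float] | None = None,
                      ) -> PreferenceVector:
    """Normalize the overall scores into weights summing to 1."""
    total = sum(overall.values())
    if total <= 0:
        raise ValueError("overall scores must have a positive sum")
    w = {c: v / total for c, v in overall.items()}
    return PreferenceVector(w, alpha, lc or {}, gc or {})


def compute_preference(q: CrispMatrix, h: CriteriaHierarchy, alpha: float = 0.5,
                       gc_mode: Literal["group_sum", "reciprocal"] = "group_sum",
                       ) -> PreferenceVector:
    """Full weighting stage: crisp pairwise matrix -> preference vector."""
    lc = local_weights(q)
    gc = global_weights(lc, h, gc_mode)
    ov = overall_scores(lc, gc, alpha)
    return preference_vector(ov, alpha, lc=lc, gc=gc)
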