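"""Bidirectional associative ranking of alternatives.

The preference vector W over the criteria seeds a two-layer associative
iteration against the crisp performance matrix O (alternatives x
criteria): the criteria state y is pushed forward through O to score the
alternatives (x = sigmoid(lambda * O y)), then the alternative state is
pushed back (y = sigmoid(lambda * x O), re-normalized).  The iteration
stops when both states move by at most ``tol`` in the max norm.  The
converged alternative scores are ranked in descending order with
competition ranking (ties share the minimal rank).

An alternative whose performance row is identically zero is a fixed
point at exactly 0.5 (sigmoid of zero), which anchors the bottom of the
converged score band; with a sum-normalized y and O in [0, 1] the
reachable band is (0.5, sigmoid(lambda)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrices import CrispMatrix
from .preference import PreferenceVector

__all__ = [
    "BAMConfig",
    "BAMState",
    "forward_pass",
    "backward_pass",
    "iterate",
    "rank_alternatives",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised by callers that require a converged state."""


@dataclass(frozen=True)
class BAMConfig:
    """Iteration parameters.

    lam
        Sigmoid steepness (> 0).  Default 1.0: with a sum-normalized
        criteria state and performance scores in [0, 1] the converged
        alternative scores then lie in [0.5, sigmoid(1)).
    tol
        Max-norm convergence threshold on both state vectors (default
        0.001).
    max_iter
        Iteration cap; exhaustion is reported, never masked.
    y_normalization
        Re-normalization of the criteria state after each backward
        activation: ``sum_to_one`` (default, keeps y commensurate with
        the preference vector), ``max_to_one`` or ``none``.
    """

    lam: float = 1.0
    tol: float = 1e-3
    max_iter: int = 100
    y_normalization: Literal["sum_to_one", "none", "max_to_one"] = "sum_to_one"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.y_normalization not in ("sum_to_one", "none", "max_to_one"):
            raise ValueError(f"unknown y_normalization {self.y_normalization!r}")


@dataclass
class BAMState:
    """Converged (or capped) state of the associative iteration."""

    x: pd.Series                 # alternative scores, in (0, 1)
    y: pd.Series                 # criteria state
    iteration: int
    converged: bool
    trajectory: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for it, (x, y) in enumerate(self.trajectory, start=1):
            row = {"iteration": it}
            row.update({f"x_{lab}": v for lab, v in zip(self.x.index, x)})
            row.update({f"y_{lab}": v for lab, v in zip(self.y.index, y)})
            rows.append(row)
        return pd.DataFrame(rows)


def _sigmoid(z: np.ndarray, lam: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-lam * z))


def forward_pass(y: np.ndarray, o: CrispMatrix, cfg: BAMConfig) -> np.ndarray:
    """Criteria state -> alternative scores: ``sigmoid(lam * O y)``."""
    y = np.asarray(y, dtype=float)
    if y.shape != (o.shape[1],):
        raise ValueError(f"y has length {y.shape}, expected {o.shape[1]}")
    return _sigmoid(o.values @ y, cfg.lam)


def backward_pass(x: np.ndarray, o: CrispMatrix, cfg: BAMConfig) -> np.ndarray:
    """Alternative scores -> criteria state: ``sigmoid(lam * x O)``,
    re-normalized per ``cfg.y_normalization``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (o.shape[0],):
        raise ValueError(f"x has length {x.shape}, expected {o.shape[0]}")
    y = _sigmoid(x @ o.values, cfg.lam)
    if cfg.y_normalization == "sum_to_one":
        return y / y.sum()
    if cfg.y_normalization == "max_to_one":
        return y / y.max()
    return y


def iterate(o: CrispMatrix, y0: PreferenceVector | Sequence[float],
            cfg: BAMConfig = BAMConfig()) -> BAMState:
    """Alternate forward/backward passes from the preference vector.

    Stops when the max-norm change of *both* x and y is at most
    ``cfg.tol``, or at ``cfg.max_iter`` (then ``converged=False``).
    The full trajectory is recorded.
    """
    if isinstance(y0, PreferenceVector):
        w = y0.as_series().reindex(o.columns)
        if w.isna().any():
            raise ValueError("preference vector labels do not match columns")
        y = w.values.astype(float)
    else:
        y = np.asarray(y0, dtype=float)
        if y.shape != (o.shape[1],):
            raise ValueError("y0 length does not match columns")
    x = np.full(o.shape[0], 0.5)
    trajectory: list[tuple[np.ndarray, np.ndarray]] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        x_new = forward_pass(y, o, cfg)
        y_new = backward_pass(x_new, o, cfg)
        trajectory.append((x_new.copy(), y_new.copy()))
        if (np.abs(x_new - x).max() <= cfg.tol
                and np.abs(y_new - y).max() <= cfg.tol):
            x, y = x_new, y_new
            converged = True
            break
        x, y = x_new, y_new
    return BAMState(
        x=pd.Series(x, index=o.index, name="x"),
        y=pd.Series(y, index=o.columns, name="y"),
        iteration=it,
        converged=converged,
        trajectory=trajectory,
    )


def rank_alternatives(x: Sequence[float] | pd.Series) -> pd.Series:
    """Competition ranking of scores in descending order.

    Ties share the minimal rank and the following rank skips (1224
    ranking).  Returns an integer Series aligned with the input.
    """
    s = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x
    ranks = s.rank(method="min", ascending=False).astype(int)
    ranks.name = "rank"
    return ranks
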