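"""Linguistic scales, quantitative binning and linguistic decision matrices.

Expert judgments enter the method as ordered linguistic terms (K0 "ultra
low" ... K10 "ultra high"), each backed by a TSFN.  Quantitative data
(here, epidemic case counts) are first binned into the same term
vocabulary and then fuzzified through the scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .tsfn import TSFN, ZERO, make_tsfn

__all__ = [
    "LinguisticScale",
    "BinTable",
    "LinguisticMatrix",
    "default_scale",
    "covid_bins",
    "bin_value",
    "fuzzify",
    "ABSENT",
]

#: Marker for absent cells (the diagonal of a pairwise matrix).
ABSENT = "-"


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered mapping from term codes to TSFNs.

    ``terms`` is a list of ``(code, label, value)`` in intensity order;
    codes are unique.
    """

    terms: tuple[tuple[str, str, TSFN], ...]
    source: str = ""

    def __post_init__(self) -> None:
        codes = [t[0] for t in self.terms]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate term codes in scale")

    @property
    def codes(self) -> list[str]:
        return [t[0] for t in self.terms]

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __getitem__(self, code: str) -> TSFN:
        for c, _, v in self.terms:
            if c == code:
                return v
        raise KeyError(f"unknown linguistic term {code!r}")

    def label(self, code: str) -> str:
        for c, lab, _ in self.terms:
            if c == code:
                return lab
        raise KeyError(code)

    def replace(self, code: str, value: TSFN) -> "LinguisticScale":
        """Return a copy with one term's TSFN overridden."""
        if code not in self:
            raise KeyError(code)
        terms = tuple((c, lab, value if c == code else v)
                      for c, lab, v in self.terms)
        return LinguisticScale(terms, source=self.source + f" [{code} override]")

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "terms": [{"code": c, "label": lab, "value": v.to_dict()}
                      for c, lab, v in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinguisticScale":
        terms = tuple((t["code"], t["label"], TSFN.from_dict(t["value"]))
                      for t in d["terms"])
        return cls(terms, source=d.get("source", ""))

    def to_json(self, path: Optional[Path] = None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LinguisticScale":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class BinTable:
    """Count ranges mapping non-negative integers to term codes.

    ``bins`` is an ordered list of ``(lower, upper, code)`` with inclusive
    integer bounds (``upper=None`` means unbounded).  The bins must
    partition [0, inf): first lower = 0, each lower = previous upper + 1,
    exactly one unbounded final bin.
    """

    bins: tuple[tuple[int, Optional[int], str], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("empty bin table")
        lo0 = self.bins[0][0]
        if lo0 != 0:
            raise ValueError("bins must start at 0")
        for i, (lo, hi, _) in enumerate(self.bins):
            last = i == len(self.bins) - 1
            if hi is None and not last:
                raise ValueError("only the final bin may be unbounded")
            if hi is not None and hi < lo:
                raise ValueError(f"bin {i} has upper < lower")
            if not last:
                nxt = self.bins[i + 1][0]
                if hi is None or nxt != hi + 1:
                    raise ValueError(
                        f"bins must partition [0, inf): gap/overlap at bin {i}")
        if self.bins[-1][1] is not None:
            raise ValueError("final bin must be unbounded")

    @property
    def codes(self) -> list[str]:
        return [b[2] for b in self.bins]

    def to_dict(self) -> dict:
        return {"bins": [{"lower": lo, "upper": hi, "code": c}
                         for lo, hi, c in self.bins]}

    @classmethod
    def from_dict(cls, d: dict) -> "BinTable":
        return cls(tuple((int(b["lower"]),
                          None if b["upper"] is None else int(b["upper"]),
                          b["code"]) for b in d["bins"]))

    def to_json(self, path: Optional[Path] = None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "BinTable":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


@dataclass
class LinguisticMatrix:
    """A labelled grid of linguistic term codes.

    ``kind`` distinguishes the square pairwise preference matrix (PLPM,
    absent diagonal) from the alternatives-by-criteria performance matrix
    (LPeM).
    """

    row_labels: list[str]
    column_labels: list[str]
    cells: list[list[str]]
    kind: str = "LPeM"  # "PLPM" | "LPeM"

    def __post_init__(self) -> None:
        if self.kind not in ("PLPM", "LPeM"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        nr, nc = len(self.row_labels), len(self.column_labels)
        if len(self.cells) != nr or any(len(r) != nc for r in self.cells):
            raise ValueError("cell grid does not match labels")
        if self.kind == "PLPM":
            if nr != nc:
                raise ValueError("PLPM must be square")
            for i in range(nr):
                if self.cells[i][i] != ABSENT:
                    raise ValueError("PLPM diagonal must be absent ('-')")

    def validate_codes(self, scale: LinguisticScale) -> None:
        for i, row in enumerate(self.cells):
            for j, code in enumerate(row):
                if code == ABSENT:
                    continue
                if code not in scale:
                    raise KeyError(
                        f"unknown code {code!r} at "
                        f"({self.row_labels[i]}, {self.column_labels[j]})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels,
                            columns=self.column_labels)

    def to_csv(self, path: Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "LPeM") -> "LinguisticMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   [[str(v) for v in row] for row in df.values], kind=kind)

    @classmethod
    def from_csv(cls, path: Path, kind: str = "LPeM") -> "LinguisticMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0, dtype=str), kind)


def default_scale() -> LinguisticScale:
    """The eleven-term K0..K10 scale, stored exactly as published.

    Note: the K1 belonging degree is 0.05 in the published table, which
    breaks the otherwise monotone pattern of the scale (0.95, 0.85, 0.80,
    ...).  It is stored verbatim here; use
    ``scale.replace("K1", ...)`` for the monotone variant (the bundled
    study fixture does exactly that).
    """
    rows = [
        ("K0", "Ultra low", (0.00, 0.05, 0.10, 0.95, 0.05, 0.10)),
        ("K1", "Supreme low", (0.07, 0.14, 0.21, 0.05, 0.10, 0.20)),
        ("K2", "Very low", (0.18, 0.22, 0.26, 0.85, 0.20, 0.25)),
        ("K3", "Slightly low", (0.25, 0.28, 0.30, 0.80, 0.30, 0.30)),
        ("K4", "Low", (0.29, 0.36, 0.43, 0.70, 0.35, 0.40)),
        ("K5", "Intermediate", (0.38, 0.45, 0.52, 0.65, 0.40, 0.50)),
        ("K6", "High", (0.50, 0.56, 0.62, 0.55, 0.50, 0.60)),
        ("K7", "Slightly high", (0.61, 0.68, 0.75, 0.45, 0.40, 0.70)),
        ("K8", "Very high", (0.73, 0.83, 0.88, 0.25, 0.20, 0.75)),
        ("K9", "Supreme high", (0.85, 0.94, 0.98, 0.10, 0.10, 0.85)),
        ("K10", "Ultra high", (0.95, 0.985, 1.00, 0.05, 0.05, 0.95)),
    ]
    terms = tuple((code, label, make_tsfn(*vals)) for code, label, vals in rows)
    return LinguisticScale(terms, source="published 11-term scale")


def covid_bins() -> BinTable:
    """Case-count ranges for the COVID-19 worked example.

    Integer counts are assigned lower-exclusive to the higher bin
    ("<= 1000" is K0, so K1 starts at 1001); the final bin is open-ended.
    """
    edges = [1000, 25_000, 100_000, 250_000, 500_000, 1_000_000, 2_000_000,
             3_000_000, 4_000_000, 5_000_000]
    bins: list[tuple[int, Optional[int], str]] = []
    lo = 0
    for k, hi in enumerate(edges):
        bins.append((lo, hi, f"K{k}"))
        lo = hi + 1
    bins.append((lo, None, "K10"))
    return BinTable(tuple(bins))


def bin_value(v: int, bins: BinTable) -> str:
    """Map a non-negative integer count to its unique bin's term code."""
    if v < 0:
        raise ValueError(f"count must be non-negative, got {v}")
    for lo, hi, code in bins.bins:
        if v >= lo and (hi is None or v <= hi):
            return code
    raise AssertionError("bin table does not cover value")  # unreachable


def fuzzify(matrix: LinguisticMatrix, scale: LinguisticScale,
            diagonal_fill: TSFN = ZERO):
    """Convert a linguistic matrix into a fuzzy matrix cell by cell.

    Absent diagonal cells of a pairwise matrix are replaced by
    ``diagonal_fill`` (default: the zero element, which defuzzifies to 0
    and makes the column mean a true g-entry mean).
    """
    from .matrices import FuzzyMatrix  # local import to avoid a cycle

    matrix.validate_codes(scale)
    cells = [[diagonal_fill if code == ABSENT else scale[code]
              for code in row] for row in matrix.cells]
    return FuzzyMatrix(list(matrix.row_labels), list(matrix.column_labels),
                       cells)
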