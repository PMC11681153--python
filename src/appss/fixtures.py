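"""Bundled worked-example inputs: COVID-19 impact by age group in India.

Eleven age groups (d1 Infant ... d11 90+) are assessed against six local
criteria — male/female COVID-positive cases (C1, C2), hospitalizations
(C3, C4) and deaths (C5, C6) — grouped under three global criteria.  The
tables here are transcribed from the published study: the pairwise
linguistic preference matrix over the criteria, the 11-term linguistic
scale, the raw case-count table with its binning rule, the criteria
hierarchy, and the printed defuzzified pairwise matrix (for stage
injection, since the published fuzzy-stage conventions are not exactly
recoverable from the printed intermediate).

Transcription notes
-------------------
* Counts: the published table's digit runs are reflowed in extraction;
  rows were segmented under the male/female-pair and magnitude pattern.
  The infant row is the one ambiguous case: its stored counts are chosen
  consistent with the prose-pinned codes (K1, K1, K0, K0, K0, K0).
* The study scale corrects the K1 belonging degree from the printed 0.05
  (which breaks the scale's monotone pattern and the infant anchor) to
  0.90; :func:`appss.linguistic.default_scale` keeps the printed value.
* Age-group labels other than d1, d5, d7, d8 are inferred decade bands
  (the published label figure is graphical only).
"""

from __future__ import annotations

import pandas as pd

from .linguistic import (BinTable, LinguisticMatrix, LinguisticScale,
                         covid_bins, default_scale)
from .matrices import CrispMatrix
from .preference import CriteriaHierarchy
from .tsfn import make_tsfn

__all__ = ["fixtures", "FIXTURE_NAMES", "AGE_GROUPS"]

CRITERIA = ["C1", "C2", "C3", "C4", "C5", "C6"]
ALTERNATIVES = [f"d{i}" for i in range(1, 12)]

AGE_GROUPS = {
    "d1": "Infant", "d2": "1-9", "d3": "10-19", "d4": "20-29",
    "d5": "30-39", "d6": "40-49", "d7": "50-59", "d8": "60-69",
    "d9": "70-79", "d10": "80-89", "d11": "90+",
}

_PLPM_ROWS = [
    ["-", "K4", "K6", "K4", "K8", "K4"],
    ["K5", "-", "K5", "K5", "K6", "K4"],
    ["K6", "K5", "-", "K7", "K5", "K5"],
    ["K6", "K4", "K7", "-", "K6", "K7"],
    ["K7", "K4", "K6", "K5", "-", "K4"],
    ["K6", "K4", "K5", "K4", "K8", "-"],
]

_COUNTS = {
    "d1":  [3243, 3255, 0, 0, 629, 777],
    "d2":  [663464, 566640, 53118, 44665, 272, 153],
    "d3":  [1859655, 1493623, 141900, 106762, 595, 505],
    "d4":  [4863748, 3424344, 381877, 247425, 3562, 2189],
    "d5":  [5574392, 3392564, 484538, 267434, 12324, 4833],
    "d6":  [4220769, 2750252, 387151, 226250, 24083, 11251],
    "d7":  [3323505, 2327632, 311917, 197033, 39339, 20921],
    "d8":  [2191686, 1607215, 211645, 150805, 50661, 28396],
    "d9":  [1049700, 714205, 103857, 67464, 39533, 19875],
    "d10": [302475, 218457, 27561, 18059, 16409, 7792],
    "d11": [41778, 39051, 3638, 3405, 2509, 1533],
}

# Printed defuzzified pairwise matrix (3-decimal rounding as published).
_DEFUZZIFIED = [
    [0.000, 0.712, 0.742, 0.430, 0.595, 0.430],
    [0.554, 0.000, 0.554, 0.582, 0.601, 0.430],
    [0.742, 0.976, 0.000, 0.881, 0.449, 0.582],
    [0.742, 0.712, 0.831, 0.000, 0.601, 0.881],
    [0.831, 0.712, 0.742, 0.582, 0.000, 0.430],
    [0.742, 0.712, 0.554, 0.430, 0.595, 0.000],
]

_HIERARCHY = {
    "COVID-positive": ["C1", "C2"],
    "Hospitalized": ["C3", "C4"],
    "Deaths": ["C5", "C6"],
}

FIXTURE_NAMES = (
    "covid-india-plpm",
    "covid-india-scale",
    "covid-india-data",
    "covid-india-defuzzified",
    "covid-india-hierarchy",
    "covid-india-bins",
)


def _study_scale() -> LinguisticScale:
    """Published scale with the K1 belonging degree restored to the
    monotone pattern (0.90); see the module docstring."""
    return default_scale().replace(
        "K1", make_tsfn(0.07, 0.14, 0.21, 0.90, 0.10, 0.20))


def fixtures(name: str):
    """Return a bundled worked-example input by name.

    Names: ``covid-india-plpm`` (LinguisticMatrix), ``covid-india-scale``
    (LinguisticScale, K1-corrected study variant), ``covid-india-data``
    (DataFrame of counts), ``covid-india-defuzzified`` (printed crisp
    pairwise matrix), ``covid-india-hierarchy`` (CriteriaHierarchy),
    ``covid-india-bins`` (BinTable).
    """
    if name == "covid-india-plpm":
        return LinguisticMatrix(list(CRITERIA), list(CRITERIA),
                                [list(r) for r in _PLPM_ROWS], kind="PLPM")
    if name == "covid-india-scale":
        return _study_scale()
    if name == "covid-india-data":
        return pd.DataFrame([_COUNTS[a] for a in ALTERNATIVES],
                            index=ALTERNATIVES, columns=CRITERIA, dtype=int)
    if name == "covid-india-defuzzified":
        return pd.DataFrame(_DEFUZZIFIED, index=CRITERIA, columns=CRITERIA,
                            dtype=float)
    if name == "covid-india-hierarchy":
        return CriteriaHierarchy.from_dict(_HIERARCHY)
    if name == "covid-india-bins":
        return covid_bins()
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
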