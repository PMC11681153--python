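"""Triangular spherical fuzzy numbers (TSFNs) and their algebra.

A TSFN couples a triangular fuzzy triple ``(a, b, c)`` (left spread, mode,
right spread) with three spherical membership degrees: belonging ``mu``,
neutral ``eta`` and non-belonging ``nu``, constrained by
``mu**2 + eta**2 + nu**2 <= 1``.  The residual commitment is the refusal
degree ``sqrt(1 - (mu**2 + eta**2 + nu**2))``.

The arithmetic follows the probabilistic-sum laws for the membership
degrees (addition accumulates belonging, multiplication accumulates
neutrality/non-belonging), while the triples use interval-style
triangular arithmetic.  Subtraction and division of membership degrees
are only well defined under side conditions that cannot hold throughout
a standardization pipeline (values below a mean must be subtracted), so
this module makes them *total*: every ratio is guarded and every
membership result is clamped back to [0, 1].  See :class:`MembershipPolicy`
for how violations of the spherical constraint are handled.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TSFN",
    "MembershipPolicy",
    "PolicyMode",
    "ZERO",
    "UNIT",
    "make_tsfn",
    "add",
    "multiply",
    "scalar_multiply",
    "power",
    "subtract",
    "divide",
    "score",
    "compare",
    "weighted_aggregate",
    "fuzzy_mean",
    "fuzzy_sd",
]

_SCORE_TOL = 1e-12


class PolicyMode(str, enum.Enum):
    """How to treat results whose squared membership sum exceeds 1."""

    ALLOW = "allow"    # store as-is, log the excess
    SCALE = "scale"    # rescale (mu, eta, nu) back onto the unit sphere
    STRICT = "strict"  # raise


@dataclass(frozen=True)
class MembershipPolicy:
    """Constraint-handling policy for TSFN construction.

    mode
        One of ``allow`` (default: spherical-constraint violations are
        stored and logged), ``scale`` (degrees are rescaled by
        ``1/sqrt(mu^2+eta^2+nu^2)`` when the squared sum exceeds 1) or
        ``strict`` (violations raise ``ValueError``).
    clamp_eps
        Guard threshold for divisions: denominators smaller than this in
        magnitude are treated as zero (guarded ratio) or replaced by
        ``clamp_eps`` (triple division).  Must be positive and <= 1e-6.
    """

    mode: PolicyMode = PolicyMode.ALLOW
    clamp_eps: float = 1e-9

    def __post_init__(self) -> None:
        mode = PolicyMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not (0.0 < self.clamp_eps <= 1e-6):
            raise ValueError("clamp_eps must be in (0, 1e-6]")


DEFAULT_POLICY = MembershipPolicy()


def _clamp01(t: float) -> float:
    return min(1.0, max(0.0, t))


@dataclass(frozen=True)
class TSFN:
    """A triangular spherical fuzzy number ``((a, b, c); mu, eta, nu)``."""

    a: float
    b: float
    c: float
    mu: float
    eta: float
    nu: float

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def memberships(self) -> tuple[float, float, float]:
        return (self.mu, self.eta, self.nu)

    @property
    def sphere_excess(self) -> float:
        """``mu^2 + eta^2 + nu^2 - 1`` (positive = constraint violated)."""
        return self.mu**2 + self.eta**2 + self.nu**2 - 1.0

    @property
    def refusal(self) -> float:
        """Residual degree not committed to belonging/neutral/non-belonging."""
        return math.sqrt(max(0.0, -self.sphere_excess))

    def to_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c,
                "mu": self.mu, "eta": self.eta, "nu": self.nu}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "TSFN":
        return cls(float(d["a"]), float(d["b"]), float(d["c"]),
                   float(d["mu"]), float(d["eta"]), float(d["nu"]))

    def to_json(self) -> str:
        # repr-based float serialization round-trips bit-exactly
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TSFN":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # compact ((a,b,c);mu,eta,nu) form
        return (f"TSFN(({self.a:g},{self.b:g},{self.c:g});"
                f"{self.mu:g},{self.eta:g},{self.nu:g})")


def make_tsfn(a: float, b: float, c: float, mu: float, eta: float, nu: float,
              policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """Construct a TSFN, enforcing the invariants.

    The triple is re-sorted so ``a <= b <= c`` and each membership degree
    is clamped to [0, 1].  The spherical constraint is then handled per
    ``policy.mode``.
    """
    vals = (a, b, c, mu, eta, nu)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite TSFN components: {vals}")
    a, b, c = sorted((float(a), float(b), float(c)))
    mu, eta, nu = _clamp01(float(mu)), _clamp01(float(eta)), _clamp01(float(nu))
    sq = mu * mu + eta * eta + nu * nu
    if sq > 1.0 + _SCORE_TOL:
        if policy.mode is PolicyMode.STRICT:
            raise ValueError(
                f"spherical constraint violated: mu^2+eta^2+nu^2 = {sq:.6f} > 1")
        if policy.mode is PolicyMode.SCALE:
            f = 1.0 / math.sqrt(sq)
            mu, eta, nu = mu * f, eta * f, nu * f
        else:
            logger.debug("sphere excess %.6f allowed for ((%g,%g,%g);%g,%g,%g)",
                         sq - 1.0, a, b, c, mu, eta, nu)
    return TSFN(a, b, c, mu, eta, nu)


#: Additive zero element ((0,0,0); 0, 0, 1) — also the diagonal fill for
#: pairwise matrices; its score is 0.
ZERO = TSFN(0.0, 0.0, 0.0, 0.0, 0.0, 1.0)

#: Multiplicative identity ((1,1,1); 1, 0, 0).
UNIT = TSFN(1.0, 1.0, 1.0, 1.0, 0.0, 0.0)


def _guarded_ratio(num: float, den: float, eps: float) -> float:
    """t/0 -> 1, 0/0 -> 0, otherwise the plain ratio (caller clamps)."""
    if abs(den) < eps:
        return 0.0 if abs(num) < eps else 1.0
    return num / den


def add(x: TSFN, y: TSFN, policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """TSFN addition: componentwise triple sum, probabilistic-sum belonging."""
    return make_tsfn(x.a + y.a, x.b + y.b, x.c + y.c,
                     x.mu + y.mu - x.mu * y.mu,
                     x.eta * y.eta,
                     x.nu * y.nu, policy)


def multiply(x: TSFN, y: TSFN, policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """TSFN multiplication: componentwise triple product, probabilistic-sum
    neutral/non-belonging (the law that can overflow the sphere)."""
    return make_tsfn(x.a * y.a, x.b * y.b, x.c * y.c,
                     x.mu * y.mu,
                     x.eta + y.eta - x.eta * y.eta,
                     x.nu + y.nu - x.nu * y.nu, policy)


def scalar_multiply(lam: float, x: TSFN,
                    policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """``lam * x`` for ``lam >= 0``: the n-fold-addition law extended."""
    if lam < 0:
        raise ValueError("scalar multiplier must be non-negative")
    return make_tsfn(lam * x.a, lam * x.b, lam * x.c,
                     1.0 - (1.0 - x.mu) ** lam,
                     x.eta ** lam,
                     x.nu ** lam, policy)


def power(x: TSFN, lam: float,
          policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """``x ** lam`` for ``lam >= 0``.

    Integer even powers of sign-mixed triples are re-sorted; fractional
    powers floor negative components at 0 (keeps the square root in the
    fuzzy standard deviation defined).
    """
    if lam < 0:
        raise ValueError("power exponent must be non-negative")
    if float(lam).is_integer():
        a, b, c = x.a, x.b, x.c
    else:
        a, b, c = max(0.0, x.a), max(0.0, x.b), max(0.0, x.c)
    return make_tsfn(a ** lam, b ** lam, c ** lam,
                     x.mu ** lam,
                     1.0 - (1.0 - x.eta) ** lam,
                     1.0 - (1.0 - x.nu) ** lam, policy)


def subtract(x: TSFN, y: TSFN,
             policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """Total TSFN subtraction.

    Triple: ``(a1 - c2, b1 - b2, c1 - a2)`` (re-sorted).  Memberships use
    the inverse-of-addition ratios, guarded and clamped so the operation
    never raises: ``mu = clamp((mu1-mu2)/(1-mu2))``, ``eta = clamp(eta1/eta2)``,
    ``nu = clamp(nu1/nu2)``; ``t/0 -> 1`` and ``0/0 -> 0``.
    """
    eps = policy.clamp_eps
    return make_tsfn(x.a - y.c, x.b - y.b, x.c - y.a,
                     _clamp01(_guarded_ratio(x.mu - y.mu, 1.0 - y.mu, eps)),
                     _clamp01(_guarded_ratio(x.eta, y.eta, eps)),
                     _clamp01(_guarded_ratio(x.nu, y.nu, eps)), policy)


def divide(x: TSFN, y: TSFN,
           policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """Total TSFN division.

    Triple: interval-arithmetic analogue ``(a1/c2, b1/b2, c1/a2)`` with
    eps-guarded denominators, re-sorted.  Memberships invert the
    multiplication law: ``mu = clamp(mu1/mu2)``,
    ``eta = clamp((eta1-eta2)/(1-eta2))``, ``nu = clamp((nu1-nu2)/(1-nu2))``.
    """
    eps = policy.clamp_eps

    def g(d: float) -> float:
        return eps if abs(d) < eps else d

    return make_tsfn(x.a / g(y.c), x.b / g(y.b), x.c / g(y.a),
                     _clamp01(_guarded_ratio(x.mu, y.mu, eps)),
                     _clamp01(_guarded_ratio(x.eta - y.eta, 1.0 - y.eta, eps)),
                     _clamp01(_guarded_ratio(x.nu - y.nu, 1.0 - y.nu, eps)),
                     policy)


def score(x: TSFN) -> float:
    """Graded-mean-integration score.

    ``2 * (a/12 + b/3 + c/12) * ((mu + eta + nu) / 3)`` — the graded mean
    of the triple weighted by the average commitment of the three degrees.
    Zero whenever the graded mean vanishes or all degrees are zero.
    """
    return 2.0 * (x.a / 12.0 + x.b / 3.0 + x.c / 12.0) * \
        ((x.mu + x.eta + x.nu) / 3.0)


def compare(x: TSFN, y: TSFN) -> int:
    """Score-based ordering: -1 (less), 0 (equal), +1 (greater).

    Scores within 1e-12 tie; ties break deterministically on the
    lexicographic key ``(b, c, a, mu, nu, eta)``.
    """
    sx, sy = score(x), score(y)
    if abs(sx - sy) > _SCORE_TOL:
        return -1 if sx < sy else 1
    kx = (x.b, x.c, x.a, x.mu, x.nu, x.eta)
    ky = (y.b, y.c, y.a, y.mu, y.nu, y.eta)
    if kx == ky:
        return 0
    return -1 if kx < ky else 1


def sort_key(x: TSFN) -> tuple:
    """Total-order key consistent with :func:`compare` (for min/max picks)."""
    return (score(x), x.b, x.c, x.a, x.mu, x.nu, x.eta)


def weighted_aggregate(values: Sequence[TSFN], weights: Sequence[float],
                       policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """Weighted TSFN aggregation.

    Triple: weighted componentwise sum.  Degrees use the
    exponent-on-complement convention ``mu = 1 - prod((1-mu_i)^w_i)``,
    ``eta = prod(eta_i^w_i)``, ``nu = prod(nu_i^w_i)``, which is
    idempotent and consistent with the scalar-multiplication law.
    """
    if len(values) != len(weights):
        raise ValueError("values and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {sum(weights)!r})")
    a = sum(w * v.a for w, v in zip(weights, values))
    b = sum(w * v.b for w, v in zip(weights, values))
    c = sum(w * v.c for w, v in zip(weights, values))
    mu = 1.0 - math.prod((1.0 - v.mu) ** w for w, v in zip(weights, values))
    eta = math.prod(v.eta ** w for w, v in zip(weights, values))
    nu = math.prod(v.nu ** w for w, v in zip(weights, values))
    return make_tsfn(a, b, c, mu, eta, nu, policy)


def fuzzy_mean(values: Sequence[TSFN], divisor: int,
               policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """TSFN mean: the TSFN sum scaled by ``1/divisor``.

    The divisor is explicit because pairwise matrices average over all g
    column entries (including the zero diagonal fill) while performance
    matrices average over the f alternatives.
    """
    if not values:
        raise ValueError("fuzzy_mean of empty list")
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    total = values[0]
    for v in values[1:]:
        total = add(total, v, policy)
    return scalar_multiply(1.0 / divisor, total, policy)


def fuzzy_sd(values: Sequence[TSFN], center: TSFN, divisor: int,
             policy: MembershipPolicy = DEFAULT_POLICY) -> TSFN:
    """TSFN standard deviation about ``center``.

    Squared deviations (via total subtraction and the power law) are
    summed, scaled by ``1/divisor`` and square-rooted; the fractional
    power floors negative triple components at 0.
    """
    if not values:
        raise ValueError("fuzzy_sd of empty list")
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    devs = [power(subtract(v, center, policy), 2, policy) for v in values]
    total = devs[0]
    for d in devs[1:]:
        total = add(total, d, policy)
    return power(scalar_multiply(1.0 / divisor, total, policy), 0.5, policy)
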