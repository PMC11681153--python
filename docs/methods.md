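# Methods

This note records the modelling and numerical choices behind the
package, what the bundled fixtures and the generator do and do not
emulate, and the known limitations.

## The TSFN calculus and its guards

All fuzzy computation runs on triangular spherical fuzzy numbers
`((a,b,c); ϱ, ς, ξ)` with `ϱ²+ς²+ξ² ≤ 1`. Addition, multiplication,
scalar multiplication and powers follow the probabilistic-sum operator
laws; subtraction and division invert them. Three issues make the raw
laws unusable in a pipeline, and the package resolves each explicitly:

- **Totality.** The inverse laws are only defined under side conditions
  (e.g. subtrahend belonging ≠ 1, neutral ≠ 0) that necessarily fail
  during standardization, where cells below the column mean must be
  subtracted. Every membership ratio is therefore guarded
  (`t/0 → 1`, `0/0 → 0`, denominators below `clamp_eps = 1e-9` treated
  as zero) and every membership result clamped to [0, 1]. Subtraction
  and division never raise; a property test asserts totality.
- **Sphere violations.** Products of valid TSFNs can leave the unit
  sphere (e.g. two mid-scale terms multiply to squared sum ≈ 1.069).
  The `MembershipPolicy` enum offers `allow` (default: store and log
  the excess — the operator laws are evidently composed without
  renormalization in this method family), `scale` (project back onto
  the sphere) and `strict` (raise).
- **Ordering of triples.** Even powers of sign-mixed triples and the
  interval-style subtraction `(a1−c2, b1−b2, c1−a2)` can disorder
  components; construction always re-sorts to `a ≤ b ≤ c`. Fractional
  powers floor negative components at zero so the square root in the
  fuzzy standard deviation stays real.

A consequence worth noting: `x − x` has the symmetric triple
`(a−c, 0, c−a)`, *not* the zero triple, so the fuzzy SD of a constant
column is a pure-spread TSFN (zero left component, `b = c`) rather than
zero. Downstream this is harmless — a constant column min-max
normalizes to the zero element regardless.

The graded-mean score `2(a/12 + b/3 + c/12)·(ϱ+ς+ξ)/3` is the single
defuzzifier. Its nominal range [−1, 1] is not enforced: triples with
large components can exceed it, and the pipeline never produces them.
Score ties (within 1e-12) break lexicographically on
`(b, c, a, ϱ, ξ, ς)` so min/max selection is deterministic.

## Column pipeline: two routes, score-first default

Both segments share a per-column pipeline: central tendency (mean with
divisor g or f, counting the zero diagonal fill of a pairwise matrix),
dispersion (SD with divisor g−1 or f−1), standardization
`(cell − mean)/SD`, min–max normalization to [0, 1], defuzzification.
Statistics are per *column* (per criterion): the same linguistic code
maps to different values in different columns, which matches the
published intermediate table of the worked example.

Two stage orders are implemented:

- **fuzzy-first** — standardize and normalize with TSFN arithmetic,
  defuzzify last. This is the literal composition of the operator laws.
  The clamping that makes it total also makes the defuzzified output
  non-monotone in the linguistic intensity of the inputs and can
  collapse distinct cells to equal scores.
- **score-first** (default) — defuzzify each cell, then z-standardize
  and min–max normalize the crisp column (same divisors). This route is
  affine in the score within each column, so equal codes map to equal
  values, the scale's score ordering is preserved, and the published
  worked-example results are reproduced exactly at the rank level
  (including the bottom row pinned at 0 and the 3-iteration
  convergence).

Min/max cells are selected by the score ordering; cells tying the scope
minimum map to the zero element exactly (this is what pins the
worked-example infant row, every column's minimum, at a converged score
of exactly 0.5). A constant scope maps entirely to the zero element.
Normalization scope is per column by default, per matrix as an option.

## Preference weighting

Local weights are off-diagonal *row* sums of the crisp pairwise matrix
(row b = preferences expressed by criterion b); this orientation
reproduces the published weight vector. For global weights two modes
exist because the published account is internally inconsistent: the
displayed formula divides the total local weight by the criterion's own
local weight (`reciprocal`), while the accompanying prose aggregates
local weights within each group (`group_sum`). Only `group_sum`
reproduces the published vector (to ±0.005, its printed rounding), so
it is the default; `reciprocal` is retained for comparison. The blend
`(LC·α + GC·(1−α))/2` keeps the published /2, which cancels on
normalization.

## Associative ranking

- λ (sigmoid steepness) defaults to 1.0. The published converged scores
  lie in [0.5, 0.618] ⊂ [0.5, σ(1)), exactly the reachable band for
  λ = 1 with a sum-normalized criteria state and performance scores in
  [0, 1].
- The criteria state is re-normalized to sum 1 after each backward
  activation (configurable: `max_to_one`, `none`); the published
  account says "normalized" without a formula, and sum-to-one keeps the
  state commensurate with the preference vector it starts from.
- Convergence requires the max-norm change of *both* states ≤ 0.001
  (the published threshold). Hitting `max_iter` sets
  `converged=False` on the returned state — never masked; the CLI maps
  it to a distinct exit code.
- Ranking is competition style (ties share the minimal rank, next rank
  skips).

## Satisfaction

The comparative/flow construction is read as the standard outranking
treatment of the dominance digraph: `F⁺` = row sums / (f−1),
`F⁻` = column sums / (f−1), `F = F⁺ − F⁻`. With distinct scores and
strict dominance, net dominance is monotone in the score, so the flow
ranking equals the associative ranking identically and all satisfaction
values are 0 (property-tested). Nonzero satisfaction can only arise
from ties or from an externally supplied flow vector, which
`rank_and_classify` accepts for reproducing alternative analyses whose
flow values are not derivable from the dominance construction (the
published flow table for the worked example is such a case: its values
are internally consistent with its ranks but do not follow from the
stated construction; the extreme rows and the zero-satisfaction anchor
do agree).

## Worked-example fixtures

The bundled tables transcribe the published study inputs: the 6×6
pairwise linguistic matrix, the 11-term scale, the 11×6 case-count
table with its binning rule (counts ≤ 1000 → K0, then
lower-exclusive integer ranges up to the open-ended ≥ 5,000,001 → K10),
the three-group criteria hierarchy, and the published defuzzified
pairwise matrix for stage injection.

Two transcription choices are documented in `appss.fixtures`:

- The published count table is reflowed in extraction; rows were
  segmented under the male/female-pair and magnitude pattern. The
  infant row is genuinely ambiguous and is stored consistent with its
  prose-pinned codes (K1, K1, K0, K0, K0, K0); only the codes enter the
  pipeline.
- The published K1 term's belonging degree (0.05) breaks the scale's
  monotone pattern; `default_scale()` stores it verbatim, while the
  study fixture uses the monotone value 0.90 — with the verbatim value
  K1 scores *below* K0, which contradicts the published bottom-row
  anchor (exact 0.500) and the published ordering under any stage
  order.

Age-group labels other than the four anchored in prose (Infant, 30–39,
50–59, 60–69) are inferred decade bands.

## Random-problem generator

`generate_problem(seed, f, g)` emulates the *shape* of the study data:
a uniform random linguistic pairwise matrix (absent diagonal) and a
count table drawn by picking a bin per cell, then a count within the
bin (the open-ended bin is sampled over a 5,000,000-wide window), with
a redraw guard ensuring at least three distinct bins whenever
f·g ≥ 12. It does not emulate the strong column correlation,
unimodal-in-age profiles or male/female pairing of real epidemic data —
passing property tests on generated problems demonstrates algebraic and
pipeline invariants, not epidemiological realism. Identical seeds give
identical problems (property-tested); all randomness flows through
`numpy.random.default_rng(seed)`.

## Problem sizes and determinism

All computations are desk-scale: the worked example is 6 criteria ×
11 alternatives and converges in 3 iterations; the full test suite and
the acceptance script each run in a few seconds. Every run is
deterministic given its configuration (the seed is echoed in the
report); reports round-trip bit-exactly through JSON via repr-based
float serialization, and crisp matrices through CSV at 15 significant
digits.

## Known limitations

- The published fuzzy-stage conventions are not exactly recoverable
  from the printed intermediate matrix; the package reproduces the
  published results at the level of ranks, anchors and the weight
  vector's printed rounding, not every intermediate digit.
- The fuzzy-first route's clamping makes its defuzzified outputs
  non-monotone in linguistic intensity; use it to study the operator
  laws, not for ranking.
- No consistency check (AHP-style) is applied to the pairwise matrix;
  no alternative normalizations (vector/max/sum) or PROMETHEE-style
  preference functions are implemented.
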