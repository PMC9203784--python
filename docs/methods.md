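# Methods

## The cross-impact model

A cross-impact assessment scores every ordered pair of goals (i, j), i ≠ j,
with an integer w_ij on the seven-point scale −3 (strongly restricting),
−2, −1, 0 (no influence), +1, +2, +3 (strongly promoting), answering how
progress on goal i would influence progress on goal j. The scores form a
square matrix with a *structurally absent* diagonal: self-influence is never
scored, and every aggregate in this package skips i = j rather than treating
the diagonal as zero. A complete matrix on n goals therefore holds exactly
n(n − 1) directed links; scores are validated as integers and fractional
weights are rejected, so all influence statistics are exact integers.

Viewing the matrix as a weighted directed network, three layers of influence
are computed per goal g:

- **first-order**: the weighted out-degree D_g^Out = Σ_{j≠g} w_gj (the row
  sum); the column sum D_g^In measures incoming influence;
- **second-order, pairwise**: I²(A→D) = Σ_i w_Ai · w_iD over the goals i
  connecting A and D. Because the diagonal is zero internally, the i = A and
  i = D terms vanish identically and the whole table is the matrix product
  W·W; its diagonal I²(g→g) is the *feedback-loop strength* — how strongly
  progress on g reinforces itself through one intermediate goal;
- **total**: I_g^Total = D_g^Out + Σ_{j≠g} w_gj · D_j^Out, i.e. direct
  influence plus influence transmitted through each neighbour's own
  out-degree. The formula is implemented literally; in particular D_j^Out
  contains the backlink w_jg, so the second-order term of the total includes
  the goal's own feedback loop. An `exclude_backlink` option removes exactly
  that term (total_literal − total_trimmed = I²(g→g)); the literal form is
  the default.

The second-order table is bilinear in the weights (scaling all w by c scales
every entry by c²) and all statistics are equivariant under goal relabelling;
both properties, together with brute-force path-enumeration and literal
formula-substitution oracles on small random matrices, are enforced by
property tests.

**Ranking.** Goals are ranked by descending first-order and total influence
using competition ranking (tied values share the smallest rank, the next
value takes rank = 1 + number of strictly larger values); tie groups retain
registry order so listings are deterministic. The *rank shift* of a goal is
rank_first − rank_total: positive means the goal gains importance once
indirect effects are counted. No normalisation is applied to influence
scores — raw signed sums are reported.

## Classification and composition

Each link is classified by sign: positive (synergy), negative (trade-off) or
zero (neutral). Composition percentages are 100·count/n(n−1) rounded half
away from zero to integer percent (77.94 → 78, 4.41 → 4, 17.65 → 18); no
largest-remainder adjustment forces the three to sum to 100, so the rounded
sum may be 99–101 (the exact shares always sum to 100). For the Cambodia
composition of 212/12/48 over 272 links this yields 78% / 4% / 18%, summing
to 100 naturally.

## Workshop consensus reconciliation

Breakout groups score (possibly overlapping) subsets of pairs and
cross-verify pairs first scored by another group. A pair is *discrepant*
when scored by at least two groups with a spread (max − min) at or above a
threshold; the default threshold of 1 flags any difference, matching a
protocol in which every disagreement is discussed. Resolution rules:

- `manual` — an explicit decisions table supplies the final score per pair;
  missing decisions are an error, never silently defaulted. This models the
  plenary consensus step of a real workshop.
- `median` / `rounded-mean` — deterministic rules for simulation; an even
  count with a non-integral midpoint rounds half away from zero so results
  stay on the integer scale.

Merging k identical score sets reproduces the input exactly, and any set of
groups whose union covers all pairs merges into a buildable complete matrix.
Inter-rater reliability statistics (e.g. kappa) are out of scope.

## Indicator trend correlation

Goal indicators run in different directions, so before correlating, each
series is *direction-recoded*: values of decrease-is-progress indicators
(mortality, poverty rates…) are negated so that larger always means
progress. Pearson's r is then computed over the exact intersection of
observation years (paired observations only). Numerical choices:

- exact-year pairing, no interpolation — sparse indicator tables would
  otherwise have data invented between observations; observations recorded
  at off-grid years (e.g. a 2003 value in a five-year grid) are stored at
  their true year;
- minimum overlap of 3 shared years by default; fewer raises an explicit
  insufficient-overlap error naming the pair;
- a constant series leaves r undefined and is reported with a distinct
  `degenerate` status, never coerced to 0;
- correlations are per indicator pair; no goal-level composite is formed for
  goals with several indicators.

The bundled Cambodia indicator table was transcribed from published
five-year summaries (2000–2019) of standard sources (SDG indicator
database, World Bank, SWIID, Worldwide Governance Indicators); a handful of
its cells sit at off-grid years and are stored as such.

## Synthetic data generators

The full 272-score Cambodia matrix is only distributed as supplementary
data to the original assessment, so testing relies on generators that
emulate its statistical structure plus the fixtures that *are*
reconstructible from the published text (goal registry; child-health row
and column, obtained by mapping the published qualitative statements
through the seven-point scale; indicator table).

- **Matrices**: each off-diagonal cell i.i.d., sign drawn from
  (p_positive, p_negative, p_zero) = (0.78, 0.04, 0.18) by default —
  calibrated to the published composition — and nonzero magnitude drawn
  uniformly from {1, 2, 3}, since the published composition fixes signs but
  not magnitudes. Cells are independent by default; a `reciprocity`
  parameter copies w_ij onto w_ji with a given probability for sensitivity
  studies, because real assessed matrices are plainly not independent.
- **Group scores**: each group reproduces a truth matrix except that,
  independently per cell with a configurable disagreement rate, the score
  is shifted by a uniform ±k (k ≤ max_shift) and clamped to −3..+3; at the
  scale boundary a clamped shift can leave the score unchanged, which the
  acceptance oracle accounts for exactly.
- **Indicator series**: linear trend plus Gaussian noise on a configurable
  year grid.

Every generator takes a seed and draws from a single
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
output. What the generators do **not** emulate: correlated scoring styles
across groups, systematic optimism of stakeholders, clustered network
structure, or autocorrelated indicator noise — so passing tests demonstrate
correctness of the computations under the stated sampling model, not
robustness to those real-data features.

## Problem sizes in the test and acceptance runs

Property oracles run on random matrices of up to 8 goals (where brute-force
path enumeration is cheap and exhaustive); calibration checks use 1,000
replicate 17-goal matrices for the sign composition and 200 seeded
replicates of two noisy groups for the discrepancy rate, each compared to
exact sampling theory within three standard errors. The discrepancy-rate
oracle enumerates the perturbation kernel per truth cell — including
same-value collisions of two perturbed groups and boundary clamping — rather
than using the first-order approximation 1 − (1 − p)², which is biased high
by those two effects. All acceptance computations run in seconds on one CPU.

## Known limitations

- Influence propagation stops at second order; no eigenvector/Katz
  centrality, community detection or higher-order path sums.
- The analysis is of perceived, not measured, influence: scores encode
  stakeholder judgement, and no causal direction can be established from
  the matrix or from indicator correlations.
- Goal-level only; target-level matrices (hundreds of nodes) would work
  mechanically but the bundled fixtures do not cover them.
- Significance testing of correlations (p-values, trend models) is out of
  scope.
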