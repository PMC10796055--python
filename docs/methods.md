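# Methods

This note documents the modelling choices behind `randgen`: the generative
models and their parameterization, the measurement conventions, the
random-forest ABC procedure, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducibility.

## Target domains

A `TargetDistribution` couples a continuous density with a response grid:

- **Gaussian heights** — N(176.4 cm, 12 cm), the average best-fitting
  Gaussian for the height task; responses are integer centimetres.
  Support is unbounded; the schema generator, which needs a bounded range,
  uses the study's average participant range 131–213 cm
  (`response_range`), and other Gaussian domains default to mean ± 3.5 sd.
- **Uniform-instruction heights** — Beta(1.27, 1.43) scaled to
  [122, 219] cm (the average best-fitting Beta and average participant
  range), integer-centimetre grid. The printed source gives "97 possible
  values" for this range; the inclusive integer count is 98, and we honor
  the printed *range* and let the count fall out of the arithmetic.
- **Item layouts** — a uniform target over 7 items, arranged either on a
  line (items at x = 1…7) or on a hex grid with rows of two, three and two
  pointy-top hexagons. Hex centres are placed so that every pair of
  touching hexes is exactly one unit apart (row offsets ±√3/2 vertically,
  ±0.5 horizontally); the centre item has six unit-distance neighbors, the
  ring items three, twelve unit pairs in all.

Continuous samplers on item layouts move over the convex hull of the item
coordinates under a flat density — for the hex grid, the regular hexagon
spanned by the outer centres — and responses are produced by
nearest-item rounding. 1D rounding maps to the nearest grid value with
ties broken toward the smaller value (176.5 → 176), deterministically.

## Generative models

All stateful generators share one **emission contract**: a burn-in of 50
unemitted steps, then exactly one grid-rounded response per iteration, so
Metropolis rejections emit repetitions. How chain iterations map to
utterances is not observable in principle, and this contract is the
package's declared convention; it is what lets rejection rates and
proposal scales express themselves in the behavioral indices. The iid
generator has no state, so burn-in is skipped there (it would be a no-op
on exchangeable draws).

- **Metropolis–Hastings**: Gaussian random-walk proposals with scale σ;
  out-of-support proposals have density zero and auto-reject. The binned
  transition flows of the resulting chain are symmetric (detailed balance),
  which the test suite verifies by brute force on a 5-bin discretization.
- **Hamiltonian proposals**: standard leapfrog with unit mass — half-step
  momentum, full-step position, half-step momentum — with positions
  reflecting at support boundaries (and across the hex hull's edges) while
  negating the momentum component normal to the crossed boundary. Energy
  error is O(ε²), verified numerically.
- **Recycled momentum**: `p ← α·p_prev + √(1−α²)·z`, `z ~ N(0, I)`; α = 0
  is plain HMC and the AR(1) form preserves the standard-normal momentum
  marginal. On rejection the refreshed momentum is *retained unflipped*
  (flag-switchable via `flip_on_reject`): the modelled phenomenon is
  direction maintained across utterances, and flipping on rejection would
  erase exactly that signature.
- **Coupled chains**: chain *i* targets `p(x)^(1/T_i)` with
  `T_i = (1+Δ)^i`; each iteration advances every chain, then with
  probability *s* one random neighbor pair attempts a swap accepted with
  the standard tempered-exchange ratio. Swaps exchange positions and
  momenta (momenta belong to trajectories). Only the cold chain (T = 1) is
  observed.
- **Schema generator**: six rules (+1, −1, +2, −2, repeat, random jump) on
  an ordered integer range; with persistence probability ρ the active rule
  is reapplied, otherwise a fresh rule is drawn from the rule weights.
  Results beyond the range are reflected once (7 + 1 → 6 on a 7-item
  range), so a permanently active "+1" rule ramps upward and then
  oscillates between the top two items. The rule set and the
  persistence/switching mechanism follow the published description of
  schema-based generation; the weights and ρ are its free parameters.
  The generator is defined for univariate ordered ranges only and raises
  on two-dimensional layouts.

One compiled kernel (numba) advances all MCMC variants; a single code path
makes the reduction identities exact under a shared random stream:
MC3 with one chain reproduces MH draw-for-draw, REC with α = 0 reproduces
HMC, and MCREC with one chain and α = 0 reproduces HMC. The test suite
asserts byte-identical sequences for these reductions.

## Parameter priors

Each parameter has an independent uniform prior scaled to the support
width W (bounded families: support length; Gaussian: 6 sd; hex hull:
diameter 2):

| parameter | meaning | prior |
|---|---|---|
| σ | random-walk proposal sd | U(0.005 W, 0.5 W) |
| ε | leapfrog step size | U(0.005 W, 0.3 W) |
| L | leapfrog steps per proposal | U{1, …, 20} |
| α | momentum recycling coefficient | U(0, 0.99) |
| C | number of chains | U{2, …, 6} |
| Δ | temperature spacing | U(0.1, 5) |
| s | swap probability | U(0, 1) |
| w₁…w₆ | schema rule weights | flat Dirichlet |
| ρ | schema rule persistence | U(0, 1) |

Parameter counts respect the semi-factorial feature design: MH 1, MC³ 4,
HMC 2, REC 3, MCHMC 5, MCREC 6 (the gradient family replaces σ with ε and
adds the trajectory length L as the gradient feature's second degree of
freedom).

## Measurement conventions

- *Repetitions*: fraction of transitions repeating the previous item,
  computed on the full sequence.
- *Adjacencies*, *Turning Points*, *Distances*: computed after collapsing
  runs of consecutive identical responses, so they reflect transition
  geometry, not repetition frequency. Adjacency means a Euclidean step of
  exactly one grid unit (tolerance 1e-9). A turn is a sign reversal of the
  step in 1D, and an angle between consecutive displacement vectors
  strictly greater than 90° in 2D (a right angle is not a turn). The
  turning-point denominator is the number of transitions with a defined
  previous direction (stripped length − 2).
- *Central turning points* restrict the count to turns whose origin (the
  middle item of the triple) lies in the central region: the 37.5–62.5
  percentile window of the target for continuous domains (an
  `empirical=True` flag computes the window from the sequence instead),
  the three middle items of the line layout, the centre hex of the grid.
- *Shape*: `S = mean[lpdf_G(xₙ)] − lpdf_U`, Gaussian fitted by maximum
  likelihood (sample mean, population 1/N variance) and uniform by maximum
  likelihood (support [min, max] of the sequence). Repeats are not
  removed. Constant sequences raise (both fits are degenerate).
- Statistics that are undefined for a given sequence propagate as NaN,
  never as silent zeros.
- **Reshuffle null**: each of *n* reshuffles (default 10⁴) permutes the
  full sequence uniformly; repetitions are measured on the permuted
  sequence, the transition-geometry indices after stripping it; the null
  is the per-index mean. Shape is permutation-invariant and omitted. The
  repetition null has the closed form Σcᵢ(cᵢ−1)/(N(N−1)) for item counts
  cᵢ, which the Monte-Carlo null matches within sampling error.

Two exact reference values used throughout: turning points of stripped
continuous iid sequences converge to 2/3 (two of the six orderings of
three distinct values are monotone), and the no-repeat iid expectation at
the three central line items is 58/108 ≈ 0.537 by direct enumeration of
triples. On integer-centimetre grids the stripped iid turn rate sits
slightly above 2/3 (≈ 0.673 at length 150 for the Gaussian height domain)
— a small discreteness effect of rounding plus stripping.

## Random-forest ABC

A reference table holds `n_per_model` summarized sequences per candidate,
parameters drawn from the priors; rows whose summary vector is incomplete
(a statistic undefined at that sequence) are resimulated rather than
imputed. The inference feature vector is (repetitions, adjacencies,
**central** turning points, distances, shape): the central restriction is
where the turning-point index is diagnostic, since boundaries and uneven
mass contaminate the global rate.

Classification uses a 500-tree random forest (default sklearn feature
subsampling, fixed seed). The error probability for a query is estimated
by a regression forest trained on the classifier's out-of-bag
misclassification indicator — a pointwise estimate, with the global
out-of-bag error exposed as a diagnostic. Posteriors are built
recursively: the classifier over the remaining models picks a winner,
which receives a share (1 − e) of the remaining probability mass; mass e
recurses into the reduced model set; the final model takes the remainder.
The source procedure states the recursion but not the mass arithmetic;
this rule is our reading, chosen because it reduces exactly to the
published two-model ABC-RF posterior (1 − e, e). Posteriors from several
conditions combine by elementwise product and renormalization.

Feature-level Bayes factors compare matched sets only — models with an
identical counterpart across the divide: multiple chains
{MC³, MCHMC, MCREC} vs {MH, HMC, REC}; gradient proposals {HMC, MCHMC} vs
{MH, MC³} (REC and MCREC are excluded because no model has recycled
momentum without gradients); recycled momentum {REC, MCREC} vs
{HMC, MCHMC}. Ratios with a zero denominator return an infinite-BF
sentinel.

Model recovery trains on a fresh table and classifies held-out simulations
of known origin. At desk scale (2000 training simulations per model,
500 tests per model, sequences of 400 — a deliberately reduced version of
the source study's 10⁵-per-model scale, configurable via `n_per_model`), the iid
generator is recovered essentially perfectly on both height domains, and
the characteristic within-family confusions appear (REC is mistaken for
HMC, and MCREC for MCHMC, in roughly a fifth to a quarter of cases): the
recycled variants shade into their non-recycled counterparts as α → 0.
Class-level separation between the local-sampling family and iid/schema is
sharper here than in the source study; that margin depends on the
parameter priors, whose published account is only partial, so
class-level recovery rates should be read as prior-dependent.

## Synthetic cohorts

`synthetic_data` emulates the *structure* of the human studies: two
conditions per participant (Gaussian and Uniform height targets at 150
responses each — five minutes at 30 responses/min — or two blocks on a
learned 7-item layout at 355 responses each, the observed ~71/min pace),
integer-centimetre rounding, and a manifest recording the ground-truth
model, parameters, seeds and domains. Model-comparison simulations stay
at 400 items per sequence.

What the cohorts do **not** emulate: response timing, unit heterogeneity
(participants could answer in feet/inches; cohorts are centimetres only),
the learning stage of the layout task, exclusion-criterion behavior, and
any within-participant drift or fatigue. Passing pipeline tests on these
cohorts therefore demonstrates correctness of the machinery and
recoverability of the generative models under the stated conditions — not
that human sequences satisfy any particular model.

## Numerical conventions

- One seeded `numpy.random.Generator` per sequence; all seeds recorded;
  fixed (model, params, seed) reproduces sequences byte-identically.
  The compiled kernels consume the same generator stream as the
  interpreted step functions.
- Chain initialization: a target draw (Gaussian) or a uniform draw over
  the support (bounded families, hex hull by rejection); the 50-step
  burn-in absorbs the difference.
- Acceptance tests use log-space Metropolis rules throughout; flat-target
  proposals inside the support always accept.
- Boundary reflection is iterated (bounded loop) so arbitrarily long
  leapfrog excursions fold back into the support.
- Tie-breaks: grid rounding ties go to the smaller value; nearest-item
  rounding ties go to the lower item index; 90° angles are not turns.
- Reported simulation scales (100 sequences × 150 for the turning-point
  demonstrations, ~10⁵ pooled draws for the central-window rate, 2000/500
  per model for recovery) are the package's desk-scale defaults; all are
  parameters of the corresponding functions.

## Known limitations

- The recursive posterior's mass-allocation rule and the emission contract
  are declared conventions for procedures whose originals are not fully
  specified in print; both are documented and flag-controlled where
  behavior could reasonably differ (`flip_on_reject`, `empirical` central
  windows, `n_per_model`).
- The "small-transitions" demonstration sampler (iid resampled until the
  draw lies within 1 sd of the previous item) stabilizes at a turning-point
  rate ≈ .55 under this package's literal reading; narrower windows give
  lower rates (≈ .52 at half a sd), so comparisons of this figure across
  implementations are sensitive to the window convention.
- Feature-level Bayes factors inherit the finite resolution of the
  regression-forest error estimate: posteriors can hit exact zeros, where
  ratios degenerate to the infinite/NaN sentinels rather than smooth
  values.
- The schema generator's rule set is a minimal ordered-range instantiation;
  richer habitual structures (digit patterns, culturally salient values)
  are out of scope.
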