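# Methods

## The probability model

A granule cell fires when at least `m` of its `n = 4` dendrites receive
an active, un-vetoed mossy-fiber input. Each dendrite is treated as an
independent Bernoulli trial with success probability
`q = (1 − P(v)) · x / y`: `x` of the field's `y = 100` mossy fibers are
active, and Golgi inhibition independently vetoes each glomerulus with
probability `P(v)`. The expected count over `N = 8750` cells is the
binomial tail `N · P(Binomial(n, q) ≥ m)`.

Two simplifications are inherited deliberately. First, dendrites are
independent even though one mossy-fiber terminal contacts ~50 granule
cells, so neighbouring cells' inputs are in reality correlated; the
expectation is unaffected, only the field-level variance is understated.
Second, the veto is applied per glomerulus rather than per cell, because
a granule cell may be inhibited by a different Golgi cell at each
dendrite.

`realize_threshold_counts` is the Monte-Carlo twin: per cell it draws
the number of active dendrites from `Binomial(n, x/y)` and thins it by
`Binomial(k, 1 − P(v))`. This is distributionally identical to drawing
the `2n` per-dendrite Bernoulli variables and guarantees
`firing ≤ threshold` draw by draw. A test holds the Monte-Carlo mean to
the analytic expectation within 3 standard errors on an `(x, P(v))`
grid, and the analytic path is itself checked against exhaustive
enumeration of all per-dendrite configurations.

## Golgi feedback and its fixed point

The feedback loop translates the *density* of parallel-fiber activity
into the veto probability:

1. **Drive.** Each field's Golgi population is driven by its own beam's
   total active-granule count, with the same-field term multiplied by
   `local_weight` (default 2 — same-field granule cells are much more
   likely to contact a local Golgi cell), plus `neighbor_weight`
   (default 0.5) times the corresponding drive of the sagittally
   adjacent field in each adjacent beam (the Golgi axonal plexus is
   sagittally elongated; no wraparound at the outer beams), plus a
   direct mossy-fiber term: `basal_boost` (default 800 active-PF units)
   scaled by the hypergeometric probability that at least 4 of the
   `basal_contacts = 12` mossy fibers sampled by a Golgi cell's basal
   dendrites are active. 12 contacts makes the basal term a steep
   function of `x` — essentially silent below ~15 active fibers and
   strong above ~25 — which is what lets high input ranges depress the
   regulated total.
2. **Veto.** Drive maps linearly to active inputs per Golgi cell
   (`1600 / 350,000` of the beam's active fibers) and then through a
   logistic rescaled to be exactly 0 at 4 inputs and exactly `veto_max`
   at 16 (midpoint 10, the centre of that span).
3. **Update.** `p ← (1 − damping) p + damping p_new`, counts recomputed,
   until the maximum relative change of any field's firing count falls
   below `tol = 0.01` or `max_iter = 50`.

The count→veto→count map is decreasing with a loop gain of roughly 3–6
at the operating point, so undamped iteration would oscillate. The
damped error factor is `1 − damping · (1 + gain)`; `damping = 0.2` keeps
it comfortably inside the unit circle and converges in ≤ 20 iterations
on every grid in the test matrix, whereas values near 0.3–0.5 sit close
to the sign flip and can take hundreds of iterations to settle. In
realization mode the counts are redrawn each iteration, so the
count-change criterion rarely drops below `tol`; such runs report
`converged=False` at `max_iter` and return the damped end state. The
default mode is the expectation mode: the model's own framing is that
large numbers make the realized ratios converge to their probabilities.

**Calibration.** The sigmoid's free parameters are not anatomical
constants; the model specifies a *behaviour* — regulated totals flat
across widely different input ranges. `calibrate_gain` therefore
grid-searches `veto_max` × `sigmoid_steepness` and scores each candidate
by the coefficient of variation of mean regulated totals across the
input ranges (5–25), (10–25), (15–30), with common random numbers across
candidates. The frozen defaults, `veto_max = 0.6` and
`sigmoid_steepness = 0.8`, are the winners of that search (CV ≈ 0.035–
0.038 across seeds); `basal_boost = 800` is the weakest value at which
the (20–30) range falls below (15–30), the qualitative signature of the
direct basal pathway. No single published count was targeted; the
resulting default-range regulated total (~1.07 × 10³ per beam) emerges
from the plateau calibration.

## What the trial generator emulates — and what it does not

Each trial draws every field's active-mossy-fiber count independently
and uniformly from 3..30, the model's stated input statistics. Trials
use independently spawned child streams of one root seed, so any trial
is reproducible in isolation. The generator does not emulate temporal
dynamics (feedback lag, spillover integration windows), correlated input
across fields, stratified superficial/deep Golgi populations, or
granule-cell membrane properties. Passing tests therefore show that the
*combinatorial and statistical* claims hold under the stated input
statistics — not that the biological circuit converges on this fixed
point in real time.

## Rate recoding

The four population shapes are concrete readings of loosely described
distributions: "uniform" as an even grid, "random" as i.i.d. uniform
draws, "discontinuous" as uniform with excluded bands, and
"top-weighted" as density ∝ `z^2` toward the maximum (a scaled
Beta(3, 1)). The default gap bands (120–160 Hz, 200–280 Hz) are
asymmetric on purpose: they give the parent distribution a skew of
~0.5, so the central-limit symmetrization of the sample means is a
measurable effect rather than a statement about an already-symmetric
parent.

Granule cells sample `sample_size = 3` *distinct* fibers (their
dendrites contact different mossy fibers) — hence the finite-population
correction `(1 − 2/299)` on the variance of the sample means, which a
test checks against brute-force resampling. Cells sample independently
of one another. The top slice is the plain top-`k` of the sample means
(`k = 1200` of 4500), with ties resolved toward earlier-indexed cells;
granule output rate is taken as the identity function of mean input
rate, so top-slice statistics stand in directly for granule rate
statistics. Location shifts reuse the same sampling design, which makes
translation equivariance exact and the linearity of top-slice mean
against population mean hold with R² > 0.99 by construction plus
resampling noise.

## Pattern overlap

The analytic spectrum is the binomial `C(n, k) p^k (1 − p)^(n−k)` over
`k = 0..n` other stored patterns. The Monte-Carlo cross-check draws
patterns as fixed-size random subsets (density is functionally fixed in
the model), which is hypergeometric rather than Bernoulli per fiber; at
the model scale (1200 of 350,000) the discrepancy is far inside the
total-variation tolerance (0.05) used for the comparison.

## Numerical choices and degenerate inputs

- Binomial and hypergeometric tails come from `scipy.stats`; the
  binomial coefficient is the standard `C(n, k)`.
- Convergence is declared on counts with an absolute floor of one cell
  in the relative-change denominator, so all-zero grids (e.g. `x = 0`
  everywhere) converge immediately instead of dividing by zero.
- `x_range = (0, 0)` and `p_veto ∈ {0, 1}` are valid degenerate inputs
  returning exact zeros; out-of-range `x` or probabilities raise
  domain errors naming the offending parameter.
- Analytic overlap proportions are renormalized to sum to exactly 1.

## Problem sizes

The standard experiments are desk-scale by design: 100 trials of a
5 × 20 expectation-mode grid take ~1–2 s; the calibration grid search,
minutes. The test suite uses reduced Monte-Carlo repetition counts
(e.g. 1000–3000 field realizations per grid point) sized so that the
3-standard-error oracle comparisons retain their power.

## Known limitations

- The paper-level constants (8750 cells, 100 fibers, 4 dendrites, the
  4–16 input sigmoid span) are point estimates; no uncertainty is
  propagated through them.
- Expectation mode understates trial-to-trial variance relative to a
  fully realized simulation (it omits within-field binomial noise).
- The sigmoid's shape between its anchored endpoints, the local and
  neighbour weights, and the basal-term scale are modelling choices
  constrained only by qualitative behaviour; all are exposed in the
  JSON config for sensitivity analysis.
- The top slice is selected by mean input rate; a selection driven by
  realized per-glomerulus veto outcomes would blur its edges.
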