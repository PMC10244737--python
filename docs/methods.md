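# Methods

This note documents the models and procedures implemented in `dispersim`,
the parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## The game and its state

Two players alternate as sender and receiver. Each turn the sender is shown
one referent from the currently active set and produces a signal — an
ordered series of colors, each the image of a pad position in the unit
square under the condition's color law. The receiver guesses a referent and
both players see the outcome. All analyses operate on the first color of
each signal: in practice signals are overwhelmingly one color repeated, and
the first token gives exactly one point per turn without having to separate
similar phonemes from imperfect repetitions.

**Establishment and unlocking.** A referent is *established* when at least
3 of its last `min(4, k)` occurrences succeeded (`k` the number of
occurrences so far; with fewer than 3 occurrences the criterion is
unsatisfiable, so 3/3 qualifies and 2/2 does not — a literal reading of "at
least three"). Occurrence histories pool both senders, treating
establishment as a dyad-level fact; a per-player variant exists behind
`MasteryTracker(per_player=True)` for success-by-player questions. When all
active referents are established and fewer than 12 are active, a block of 4
unlocks at round end (mid-round unlocking is not modeled). The active-set
trajectory is therefore non-decreasing through {4, 8, 12}.

**Success index.** `(Σᵢ sᵢ) / (12 · n_r)` with `sᵢ` the established count in
round `i`. It is 0 for a game with no establishment and 1 only if all 12
referents are established on every round (unattainable in practice, since
the game starts unestablished).

## The color law

The original apparatus's exact pad-to-color mapping is not published; the
mapping here is a polar reconstruction isolated behind the `ColorMap`
interface so an alternative law can be substituted without touching any
analysis code. Hue follows the angle about the pad center; saturation is 1;
brightness (the HSV value, hence the brightest RGB channel) is a function of
radial distance `r ∈ [0, √0.5]`:

- **outer_edge**: linear ramp from `b_min = 0.15` at the center to
  `b_max = 1.0` at the corners.
- **inner_edge**: triangular profile from `b_min` at the center up to
  `b_max` at the ridge radius `0.6·√0.5 ≈ 0.42` and back down to `b_min` at
  the corners.

The ridge fraction of 0.6 keeps the ridge ring strictly inside the pad in
every direction (the largest in-pad radius along an edge-normal ray is 0.5),
so brightness has an interior maximum along *any* ray — the qualitative
signature of the inner-edge condition. A larger fraction would push the
ridge outside the pad except toward the corners and make the two conditions
nearly indistinguishable over most of the pad. `b_min`, `b_max` and the
ridge fraction are configurable. Channels are stored in [0, 1]; 0–255
rendering is an I/O concern only.

## Dispersion and convergence measures

All are computed on first-color pad points unless stated otherwise; the
inventory-level entry points accept arbitrary point sets (e.g. phoneme
centroids).

- *Mean pairwise distance* over unordered pairs, and *mean distance from the
  center* (0.5, 0.5). The center-to-corner distance is `√0.5 ≈ 0.707`;
  corner-to-corner is `√2 ≈ 1.41`.
- *Mode brightness*: per phoneme, the mean over exemplars of the brightest
  RGB channel; then the mean over phonemes.
- *Extremeness*: `|d/√0.5 − 0.5| / 0.5`. Exactly 1 at the center and the
  corners, 0 on the ring at half the center-to-corner radius.
- *Auto-distance* and *partner distance*: distance to the most recent prior
  first-color point for the same referent by the same player / the partner;
  explicitly missing when no prior signal exists. Both are invariant to
  relabeling which player is 0 and which is 1.
- *Rolling dispersion* at turn *t*: mean pairwise distance among the most
  recent successful signal per referent at or before *t*; missing with fewer
  than 2 successful referents. At the final turn it coincides with the mean
  pairwise distance of the final successful inventory.

**Signal area.** For one referent in one game quintile, the cloud is the
set of successful first-color points. Points farther from the cloud centroid
than mean + 2 SD of the centroid distances are removed once (a radial,
dimension-free reading of the 2-SD rule; not iterated, so the result is
order-independent). Survivors are centered and projected onto their first
two principal components (numpy SVD — 2-D clouds need no heavier machinery),
and the area is `π · (w/2) · (h/2)` with `w`, `h` the coordinate ranges
along PC1 and PC2 — reading "width" and "height" as the full ellipse
diameters. Clouds with ≤ 1 surviving point, and collinear clouds, have area
0. Areas are in pad units squared (total space = 1). PCA projection makes
the measure invariant under rotation and translation of the cloud.

**Quintiles.** A game's turn sequence is split into 5 contiguous blocks
whose sizes differ by at most 1, earlier blocks absorbing the remainder
(deterministic and order-preserving). Per-quintile mean areas average over
the (referent, quintile) clouds that contain at least one successful signal;
referents absent from a quintile contribute nothing.

## Chance-level nulls

Observed dispersion is compared against inventories of points drawn
uniformly on the unit square — the maximum-entropy reading of "by chance";
the sampling law is a modeling choice and is configurable scholarship-wise
only by editing one function. For each of `n` inventories (default 100,000)
of a given size the statistic is computed; the null mean is the chance
level. Closed forms anchor the calibration: the expected distance between
two uniform points in the unit square is
`(2 + √2 + 5·asinh 1)/15 ≈ 0.52140`, and the expected distance of one
uniform point from the center is `(√2 + ln(1+√2))/6 ≈ 0.38260`. Because
pairs are exchangeable, the pairwise null mean is invariant in expectation
to inventory size; pair-level comparisons nonetheless match the inventory
size to each dyad's observed successful-referent count. For mode brightness
the points are mapped through the condition's color law. Empirical p-values
use the add-one estimator `(1 + #{samples ≥ observed}) / (n + 1)`. All
sampling flows from a single seeded generator; the same seed reproduces the
distribution bitwise.

## Color phonemes

Each referent seeds one group containing every color token either player
used for it (signals are dominated by one repeated color per referent, so
referent-wise seeding is the natural unit). The two-group Pillai–Bartlett
trace — `trace(H(H+E)⁻¹)` on the 2-D pad coordinates, in [0, 1] for two
groups — measures how separable two groups are. Greedily, the pair of
groups with the lowest trace is merged while that trace is below the merge
threshold (default 0.3); ties break on the lexicographically lowest pair of
referent-id labels, so the merge trace is reproducible. Groups too small to
score (< 3 points) are attached to the group with the nearest centroid at
the end. A singular total scatter matrix is ridge-regularized (1e-10); a
cloud with zero variance in every direction yields a flagged missing score.
The merge criterion is a reconstruction — the original study's exact rule is
not published — and both the threshold and the procedure are exposed as
configuration. Phoneme counts are monotone non-increasing in the threshold.
Note that pooling *all* of a referent's colors, including early exploratory
scatter, inflates within-group variance and biases merging toward fewer
phonemes on long noisy games.

## The synthetic dyad generator

The simulator produces game logs with the statistical structure the
analyses assume; it makes no claim of cognitive plausibility and is not fit
to human data. Defaults (per player, all configurable via `AgentParams`):

| parameter | default | meaning |
|---|---|---|
| `comfort_correlation` | 0.4 | target corr(x, y) of initial exploration |
| `comfort_exclusion` | 0.25 | bottom fraction of pad never sampled initially |
| `motor_sd0` | 0.08 | initial motor noise SD (pad units) |
| `motor_sd_min` | 0.015 | asymptotic motor noise SD |
| `motor_decay` | 0.015 | per-send geometric decay rate toward the asymptote |
| `stay_prob_success` | 0.95 | probability of reusing the last successful point |
| `repel_weight` | 1.0 | strength of distinctiveness pressure |
| `perceptual_sd` | 0.05 | receiver noise SD per RGB channel |
| `n_candidates` | 12 | candidate draws scored during exploration |

Mechanics per turn: senders alternate; the referent is uniform over the
active set. If the dyad's most recent signal for the referent succeeded, the
sender reuses that point plus Gaussian motor noise (SD
`motor_sd_min + (motor_sd0 − motor_sd_min)(1 − motor_decay)^t` after `t`
sends) with probability `stay_prob_success` — outcome-contingent convergence
is keyed to the dyad's last signal, not only the sender's own, which is what
produces the partner-distance contrast by success of the previous outcome.
Otherwise the sender explores: a referent's first-ever candidate is drawn
from the diagonal comfort band (x uniform; y a mixture of x and an
independent uniform rescaled above the exclusion strip, giving the target
correlation), while re-exploration after failure draws uniformly from the
whole pad — players reach more of the space once practiced, and without
this widening the emergent dispersion could never exceed the uniform null
confined to the band. Among `n_candidates` draws the one maximizing the
minimum distance to other referents' established points wins (with
`repel_weight = 0` the first draw is taken, removing the distinctiveness
pressure). The receiver perturbs the observed color with Gaussian channel
noise and guesses the referent of the nearest remembered exemplar in RGB
space, ties to the lowest referent id, uniform over active referents when
its memory is empty; feedback stores the true referent's color in both
players' memories. The condition asymmetry is *not* hand-coded: under the
inner-edge law, extreme pad points map to dark confusable colors, so
perception alone penalizes them.

What the generator reproduces, by construction: positive first-signal x–y
correlation; declining auto-distance and shrinking per-quintile signal areas
(motor decay); smaller auto/partner distance after a success than after a
failure; above-chance final dispersion under outer-edge defaults
(repulsion). What it does not emulate: the 20-second round timer, multiple
sends per round (one effective color token per turn; the log format accepts
multi-token signals), iconicity, fatigue, memory decay, or any parameter
fit to the human data — so passing tests show the pipeline detects these
signatures when present, not that humans produce them at these magnitudes.

## Trend models

Mixed models are fit by REML with statsmodels' `MixedLM`. The first
requested random intercept (normally the dyad) is the grouping factor;
further intercepts and random slopes for non-primary factors enter as
variance components (`0 + C(factor)` and `0 + C(factor):variable`). When the
maximal structure fails to converge, is singular (any random-effects
covariance eigenvalue or slope variance component below 1e-8), or yields
non-finite standard errors, random slopes are removed one at a time —
primary-group slopes before other groups', interaction slopes before
main-effect slopes — and the reduction is recorded in the result. Per
structure a fixed optimizer sequence (default BFGS, then L-BFGS, then
Powell) is tried, so the whole protocol is deterministic. As a flagged last
resort, an intercepts-only boundary fit with finite estimates is returned
with `converged=False` (degenerate data such as zero residual variance);
only if that too fails is the result an explicit empty failure — never a
silent fallback.

Denominator degrees of freedom use the residual approximation
`n_obs − rank(X)`; Satterthwaite df are not reproduced, and conclusions rest
on the sign and magnitude of estimates rather than exact df. Condition is
treatment-coded with outer-edge as the reference level. Quintile areas are
log-transformed as `log(area + 1e-6)` since degenerate clouds give exact
zeros.

## Problem sizes and numerical choices

The packaged test battery simulates 20 outer-edge and 6 inner-edge dyads of
200 turns (enough for most dyads to unlock all 12 referents and for the
practice effects to saturate) and uses 100,000-inventory nulls where the
chance level itself is under test, 2,000–5,000 elsewhere; mixed-model
recovery uses 100 replicates of 20 groups × 25 observations. Tolerances:
geometric identities to 1e-9, the Pillai trace against an independent
eigendecomposition to 1e-8, Monte Carlo means to 3 standard errors.
Degenerate inputs are defined, not patched around: empty logs, single-point
inventories and sub-minimum groups raise; undefined sequential distances are
explicit missings that propagate to the model tables as NaN and are dropped
casewise per fit.

## Known limitations

- The color law and the phoneme-merge criterion are documented
  reconstructions; results that depend on their fine structure (mode
  brightness levels, absolute phoneme counts) are only qualitatively
  comparable across implementations.
- The receiver model is the minimal nearest-exemplar classifier; richer
  receiver behavior (multi-token integration, adaptive criteria) is out of
  scope.
- `MixedLM` supports one true grouping factor; crossed random effects are
  approximated through variance components, which constrains which random
  slopes are expressible.
- The uniform null ignores motor constraints (e.g. the comfort band), so it
  is a conservative baseline for early-game dispersion.
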