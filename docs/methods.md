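# Methods

This note documents the models implemented in `thinktime`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Utility calibration

Raw engine-style evaluations arrive in two units: centipawns and signed
distance-to-mate in plies.  Each unit gets its own univariate logistic
regression against decisive game outcomes (win = 1, loss = 0; draws are
excluded from calibration, though elsewhere in the package a draw counts as
half a win).  The two channels are fitted independently and no continuity is
imposed where they meet; `seam_diagnostic` reports the gap between the
fitted utility at an extreme centipawn value and at mate-in-±1, which a
well-ordered map keeps positive.  Separation is detected exactly — in one
dimension the maximum-likelihood coefficients diverge if and only if the two
outcome classes' value ranges fail to overlap — and raises an error; an
optional L2 ridge penalty (default off, flagged on the output) is the only
rescue, fitted by penalised IRLS.  Mate distance enters the logistic
untransformed; a reciprocal transform would better match the intuition that
mate-in-2 beats mate-in-9, but a single monotone curve in the signed
distance keeps the channel identifiable from modest samples and the seam
diagnostic makes the cost visible.

The Elo expected-score curve is the standard `1/(1 + 10^(-d/400))`; at
`d = +100` it evaluates to 0.6400..., i.e. 64% to two decimals.

## Benefit of computation

Within a consideration set, the true benefit `ΔU_C` is the deep utility of
the deep argmax minus the deep utility of the shallow argmax.  Ties break by
set order everywhere, and ingestion orders moves by descending shallow
value, so ties resolve toward the shallow-preferred move; `ΔU_C ≥ 0` by
construction, and equals zero exactly when the two argmaxes coincide (under
the tie rule; exact deep-value ties between distinct moves are a
measure-zero exception).

The expected benefit models each move's deep utility as an independent
Gaussian `N(U₋C(m), |U_C(m) − U₋C(m)|)` — mean at the shallow value,
standard deviation equal to the single observed discrepancy (the maximum
likelihood scale estimate from one sample).  Independence across moves is an
assumption; candidate moves from one position share board structure, so this
overstates the information in the set, but nothing in the data identifies
the correlation.  Beliefs are not truncated to [0, 1]: truncation would
break the closed-form/quadrature identities, and with utility-scale sigmas
the mass outside the unit interval is small.

`E[max]` of independent Gaussians is computed from the survival-function
identity `E[max] = lo + ∫ (1 − Π_i F_i) dx` on the bracket
`[max_i(μ_i − 8.5σ_i), max_i(μ_i + 8.5σ_i)]`, whose truncation error is
below 1e-12 on utility-scale inputs.  The integral uses composite 64-point
Gauss–Legendre between knots placed at every mean and at ±1σ and ±4σ around
it; degenerate σ = 0 entries become step CDFs whose discontinuities land on
knot boundaries, so the rule's accuracy is preserved (all-σ-zero sets
short-circuit to `max μ`).  Accuracy is validated against the two-Gaussian
closed form (≤ 1e-6 observed) and a seeded Monte-Carlo oracle
(`mc_expected_benefit`), which samples the beliefs directly and subtracts
the sampled value of the shallow argmax — an estimator of the same quantity
with computable standard error.

## Value function, cost of time, stopping policy

`V_tc(T, U)` is the raw binned win proportion (draws = 0.5) over half-open
bins `[lo, hi)` anchored at zero: 3 s in time left, 0.03 in advantage —
deliberately an empirical table, not a smoothed fit.  The advantage
coordinate is the *pre-deliberation* value `U₋C(m₋C)`, so that an offered
benefit `ΔU_C` is a movement along the advantage axis.  Moves outside the
15–75 ply window are excluded, as are moves where the opponent has less
than 60 s (30 s under the 60+0 control) — the floor decorrelates the
mover's clock from the opponent's time trouble.

Cells with fewer than `min_count = 50` observations are inestimable.
Lookups fall back to the nearest estimable cell along the time axis within
the same advantage column (ties toward less time left); this preserves the
U-conditioning that drives the stopping inequality.  A strict mode errors
instead, carrying the cell coordinates.

`ΔT_max(T, U, ΔU_C)` scans ΔT over time-bin multiples from 0 up to T and
returns the *largest* ΔT with `V(T − ΔT, U + ΔU_C) ≥ V(T, U)`; advantage
above the grid top clamps into the top bin (utilities saturate at certain
win).  The largest-satisfying rule follows the stopping definition
literally but is an extreme statistic — a single optimistic far cell
inflates it — so a `contiguous=True` mode stops at the first failing ΔT,
which is never larger and is more robust under sampling noise.  Tests of
surface monotonicity therefore average ΔT_max over several advantage
columns before comparing neighbours.

Implied mean move times evaluate an accept/decline policy over an offer
distribution: each offer is taken in full when its time price is within
ΔT_max at the offer's state, contributing `motor_time + ΔT_C`, else
`motor_time` alone (default 0 for the pure policy quantity, configurable);
means are reported within 0.03-wide benefit bins.

## Move-time statistics

Regressions are OLS with intercept, (optionally square-rooted) benefit,
rating centred at 1500, and their interaction; a per-time-control mode
expands every term per setting, and a pooled mode adds start time,
increment, and their interactions with the benefit.  AIC uses the fixed
Gaussian convention `n·log(RSS/n) + 2k` with additive constants dropped —
well-defined for differences between models on identical row sets, which
`aic_compare` enforces by row count.  p-values are classical t statistics;
rank deficiency is detected by QR and reported with the collinear term
names.

Spearman summaries compute one rho per (game, player) from at least three
moves (average ranks on ties; constant series skipped), average rhos within
100-point rating bins, and drop bins with fewer than 200 contributing
player-games.  Bin width and the mean-of-rho aggregation are package
choices; the rank correlation makes the summary invariant to any monotone
transform of move times.

The power-cost exponent is recovered by OLS of
`log(move_time − motor_time)` on `log ΔU_C` over accepted offers.  This is
consistent because of two generator choices documented below: offered time
prices follow a bounded power-law (so the conditional mean log accepted
price equals the log threshold plus a constant), and timing noise
multiplies the deliberation component only (so subtracting the motor
baseline recovers the noised price exactly).  The estimator's slope is
`1/b`; at 20,000 accepted offers its standard error is ≈ 0.01.

## The synthetic-data generator

The generator defines the study conditions; defaults describe a blitz-like
300+0 population and are fixed once:

- **Ratings** N(1500, 200), one draw per player per game.
- **Advantage** follows a reflected random walk in [0, 1], innovation
  SD 0.02 per ply, so value-grid estimation sees serial correlation.
- **Consideration sets** (5 moves): the top deep utility sits at the
  walk's current value, the rest an Exp(0.08) gap below; shallow values add
  clamped Normal noise with SD `0.08 · ε_m`, `ε_m ~ U(0.5, 1.5)` per move.
  The heteroscedastic factor is deliberate: it creates variation in
  `E[ΔU_C]` at fixed `ΔU_C`, the structure the expected-benefit analysis
  exploits.
- **Offers**: time prices `ΔT_C = s · u · X` with scale `s = 20 000`,
  unit cap `u = 0.002` (so 40 s at the default scale) and `X` from a
  bounded power-law with density ∝ `x^k` on (0, 1), default `k = 0`
  (uniform).  The bounded power-law — rather than a heavy-tailed draw — is
  what makes the log-log exponent recovery exactly consistent:
  `E[log ΔT_C | ΔT_C ≤ τ] = log τ − 1/(k+1)` for any threshold inside the
  support.  A Gaussian copula couples the standalone offer's benefit to its
  price with configurable rank correlation (default 0.3; the coupled
  benefit is an Exp(0.05) draw capped at 1).
- **Policy**: all-or-none acceptance of the full offered price whenever it
  is within ΔT_max for the set's *true* benefit (the simulated player has
  oracle knowledge of `ΔU_C`); default family is the power cost with
  `a = 0.001`, `b = 2`.  Declined offers cost the motor baseline of 1 s —
  the data contain no signal about what a player spends when declining, so
  the baseline is a construction of this package.
- **Timing noise** is lognormal with unit mean and CV 0.1 multiplying the
  deliberation component only; the motor baseline is deterministic.  This
  keeps the clock-derived `move_time − motor_time` equal to the noised
  accepted price, which the recovery regression requires.
- **Clocks** update as `after = before − spent + increment`.  A move on
  which the clock would reach zero ends the game by flagging and is *not*
  emitted as a record: an interrupted move receives no increment, so
  emitting it would break the conservation identity
  `after − before + spent − increment = 0` that holds for every emitted
  move.  Games surviving to 100 plies are decided by the final advantage
  against a symmetric 0.02 draw margin (≈ 8% draws, a plausible fast-game
  rate).
- **Reproducibility**: one RNG stream per game, seeded as
  `(dataset seed, game index)`, so datasets are order-independent and
  bit-reproducible.

`generate_value_records` is a second, simpler input source: records whose
outcomes are Bernoulli draws from an injected value law `V*(T, U)`.  It
feeds the value-grid estimator a known monotone ground truth, which full
game simulation cannot guarantee.

What the generator does **not** emulate: chess-legal moves or any board
semantics; opening-book and endgame phase structure (the advantage walk is
stationary); correlated evaluations across moves of one position; players
whose policies drift with fatigue or rating; time scrambles (offers are
state-independent, and the policy never declines because the clock is
short, only because the price exceeds ΔT_max).  Consequently, passing tests
show that the *pipeline* measures what it claims on data with known
structure — they do not show that real players follow these policies, which
is an empirical question for real move tables.

With uniform offers the simulator's mean move time is close to *linear* in
the benefit (mean accepted price scales with the square of the stopping
threshold), so AIC curvature comparisons are validated on directly
synthesized regression data with known sqrt/linear laws rather than on
simulated games.

## Problem sizes

Default test and acceptance runs use: 200-set × 10⁶-draw Monte-Carlo sweeps
for the quadrature check, 10⁴ random sets for score invariants, 2,600
simulated games (≈ 2 × 10⁴ accepted offers) for exponent recovery, 5 × 10⁴
rows for regression/AIC checks, and 8 × 10⁵ Bernoulli records for the
empirical policy surface.  These sizes give each check a comfortable margin
over its tolerance on a single core.

## Known limitations

- The mate channel's single logistic in signed distance cannot express the
  true non-monotone structure near the seam; the diagnostic quantifies it.
- The empirical ΔT_max is upward-biased at small benefits under the
  largest-satisfying rule; use the contiguous mode for conservative
  estimates.
- The expected-benefit beliefs are untruncated Gaussians; utilities within
  ~2σ of 0 or 1 leak probability outside the unit interval.
- `read_move_table` accepts only the documented column schema; external
  corpora need their columns mapped to it, and their clock-recording
  convention selected via `clock_convention` (`post_increment` when
  recorded clocks already include the increment added back, else
  `literal_paper`).
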