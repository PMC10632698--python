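# Methods

This note documents the models, parameter choices and numerical decisions
behind `puzzletrain`, and what the synthetic-player experiments can and
cannot show about real interventions.

## Difficulty ladder

Both games share one difficulty parameterization: board side `s ∈ [4, 8]`
and number of unique game objects `g ∈ [4, 8]`. A ladder enumerates the 25
combinations sorted lexicographically by `(s, g)`, so
`index = (s − 4)·5 + (g − 4) + 1`. Board growth dominates the order because
enlarging the search field raises visual-search and planning load more than
adding one object type does; it also matches the familiarization
progression (4×4 → 5×5 → 6×6) used when onboarding players. The ladder
index is the scalar "level" that all adaptation and plotting uses.

## Game engines

**Match-3.** Boards are integer grids of codes `1..g`; coordinates are
`(row, col)` with row 0 on top and gravity toward higher rows. Generation
fills cells left-to-right, top-to-bottom, resampling any code that would
complete a run of three (retry cap 1,000); boards without at least one
valid swap are discarded and regenerated. Matches are maximal horizontal or
vertical runs of length ≥ 3; a run longer than three is a single
descriptor, and a cell at the crossing of a row run and a column run is
reported in both but cleared once. Cascade resolution repeats
clear → column-wise drop → refill until quiescent. Refill draws uniformly
over `1..g` from a counter-based generator (Philox) keyed by the caller's
seed, so a replay of the same `(grid, move, seed)` is bit-identical.
A level counts as solved when the player has cleared a quota of `10·g`
gems; the quota also defines "items" for the per-item metrics. This
completion rule is a package choice — tablet deployments use various rules
(score targets, move budgets) and the quota variant keeps level length
roughly proportional to object count.

**Numberlink.** A puzzle places `g` colored endpoint pairs on an `s×s`
grid; a solution joins each pair with orthogonal, cell-disjoint paths that
cover every cell. Generation works backwards from a solution: a serpentine
Hamiltonian path is randomized by `10·s²` backbite moves (reverse a prefix
at a grid neighbor of an endpoint) and cut into exactly `g` contiguous
segments; segment termini become the endpoint pairs. This guarantees a
full-fill witness solution and the exact pair count without rejection
sampling. Segments are at least 3 cells where the budget allows
(`3g ≤ s²`); the combinations (4×4 with 6–8 pairs) violate that bound, so
there the minimum drops to 2 cells (two adjacent endpoints). Solution
uniqueness is not enforced — deciding it is NP-hard in general — but
`count_solutions` provides exhaustive counting for small test instances.
The solver is a deterministic depth-first router (pairs in color order,
neighbors explored up, left, right, down) with two prunes: the active head
must stay connected to its target through free cells, and every unrouted
pair's endpoints must touch a common free component. A node budget
distinguishes "search exhausted" (`unknown`) from a proven `unsolvable`.

## Difficulty adaptation

**Level predictor.** After a solved level the decision compares the
measured time `t_m` with the predicted time `t_p`:
retreat (−1) if `t_m > t_p + c·σ`, advance (+1) if `t_m < t_p − c·σ`,
else stay (0). Inequalities are strict, so a time landing exactly on a band
edge keeps the level. `c` defaults to 0.5 — mid-range of its admissible
interval (0, 1), giving a band of ±half a standard deviation, wide enough
to absorb ordinary attempt-to-attempt noise yet narrow enough to move
within a few attempts. `σ` is the sample SD (n−1) of all recorded games at
that difficulty level, pooled across participants per game; when fewer than
3 attempts exist at a level, the fallback `max(2 s, 0.2·t_p)` prevents a
zero-width band from thrashing. Unsolved or timed-out attempts are recorded
at the 600 s per-game cap and force a retreat: the decision rule is defined
for solved levels, and failing to finish is the clearest signal the level
is too hard.

**Time predictor.** Features per attempt: board size, object count, ladder
index, session index, and the participant's running mean time over earlier
attempts (neutral prior 60 s for a first attempt, so the target never leaks
into its own features). Candidate families: ordinary least squares, a
k-nearest-neighbor mean (k = 5, standardized features), and an averaging
committee of linear + kNN + depth-6 decision tree. The committee plays the
role that voting or neural regressors fill in production systems while
remaining exactly reproducible under a seed. Selection maximizes training
adjusted R² `1 − (1−R²)(n−1)/(n−p−1)` with `p = 5` features for every
family; ties break toward the earlier (simpler) candidate. Selection on
training data favours flexible families — that is a property of the
selection rule being modeled, not a defect of this implementation.
Predictions are clamped below at 1 s, and predicting outside the trained
ladder range raises an extrapolation warning (suppressed inside the
service, where reaching a ladder edge is routine). Before any training data
exists the service uses a fixed reference predictor, the base curve
`20 s + 15 s·(index − 1)`.

**Initial level.** The pretest composite is the mean of z-scores of
(−TMT-A, −SMT, +MoCA) against a reference population (the embedded cohort
by default) — higher is abler. Its mean-rank percentile selects one of
five ladder bands, and play starts at the band's lowest index
(1/6/11/16/21): the median pretest starts mid-ladder, the best starts at
21, and composite rank order is preserved in starting-level order. The
mapping from pretest to level is a package choice; only the pretest
variables themselves are fixed by the protocol.

**Refit cadence.** The service's model is fitted on pooled prior-participant
data and per-level σ tables update continuously from incoming attempts;
`AdaptiveService.train` can be re-invoked (e.g. nightly) to refit on the
accumulated pool. Decisions are emitted per completed level.

## Player simulation

A profile has a skill multiplier (> 0, smaller = faster), a per-session
learning rate and a lognormal noise SD:
`t_m = base(level)·skill·(1 − learning_rate)^(session−1)·exp(ε)` with
`ε ~ N(0, noise_sd²)`. Multiplicative lognormal noise and an exponential
practice curve are the standard shape of response-time data (positive,
right-skewed, diminishing returns). Population priors:
`skill ~ LogNormal(0, 0.25)`, `learning_rate ~ Uniform(0, 0.04)`,
`noise_sd ~ Uniform(0.1, 0.3)`. The schedule is 8 weeks × 3 sessions, both
games per session, 600 s per game and 1,200 s per day. An attempt that
would exceed the per-attempt cap is logged as a timeout (and retreats); an
attempt that merely does not fit the remaining session budget is abandoned
unscored, so end-of-session truncation does not bias decisions downward.
Pretest scores for simulated players scale the cohort-typical completion
times by the skill multiplier, tying initial placement to ability.

Training datasets for the time model emulate pilot data: each simulated
player follows a bounded, mostly ascending random level walk (advance 50%,
stay 30%, retreat 20%) with three attempts per game per session.

What the simulator does **not** model: fatigue within a session, dropout
and adherence, per-game skill differences (both games share one profile by
default), day-to-day mood effects, and any cognitive mechanism beyond the
time curve. Passing closed-loop tests therefore shows that the adaptation
logic steers a time-generating process correctly — not that it improves
cognition in people.

## Closed-loop experiments

Two properties summarize the loop. (1) *Ability ordering:* with 20 players
drawn from the priors and a model trained on a separate simulated pool, the
Spearman rank correlation between player speed (1/skill) and final ladder
index is positive and significant (one-sided, α = 0.05). (2) *Practice
ascent:* a noiseless player improving 2% per session, evaluated against the
fixed base-curve reference predictor, is never demoted after a short
burn-in and ends higher than it started. The reference predictor is used
deliberately in (2): a data-fitted model's running-mean feature
personalizes the bar (a faster history lowers `t_p`), so monotone ascent is
neither guaranteed nor desirable there; against the fixed predictor the
property is exact.

## Trial analysis

The embedded cohort (12 participants; 7 control-first, 5
experimental-first; one further enrollee excluded for incomplete
measurements) and the IMI/NASA-TLX subscale tables are stored as CSV files
whose SHA-256 checksums are verified on load. Summaries use the arithmetic
mean and sample SD (n−1); rounding (half-up, 2 decimals) happens only at
the report layer. One published summary cell (pretest MoCA SD) appears to
have been truncated rather than rounded — the raw column gives 2.0653 —
so consistency checks accept either 2-decimal display convention.

Statistical surfaces wrap scipy (Shapiro–Wilk, paired t, Pearson r); the
one-way within-subject ANOVA computes its sums of squares directly
(`df1 = k−1`, `df2 = (n−1)(k−1)`), with no sphericity correction by
default at this sample size and a Greenhouse–Geisser option behind a flag.
Mid/post wave summary cells are stored as display-only reference constants:
the individual wave-level measurements behind them were never published, so
nothing recomputes them, and the corresponding inferential results on human
data are out of scope by design.

## Problem sizes and determinism

Default experiment sizes — 100 boards per ladder band for engine
soundness, 50 five-by-five solver round-trips, 1,000 random decision cases,
12 training players and 20 closed-loop players over 24 sessions — were
chosen so that every property is measured with comfortable margins while a
full run stays interactive. All randomness flows through explicit integer
seeds (NumPy `SeedSequence`/Philox); identical seeds reproduce logs, boards
and fitted models bit-for-bit.
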