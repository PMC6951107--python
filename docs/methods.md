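# Methods

## The dependency statistic

For one participant and session the data are a 6 × N response matrix: N
three-element events (location–person–object) by the six ordered retrieval
directions L→P, L→O, P→L, P→O, O→L, O→P, each cell correct, incorrect or not
administered. Closed-loop events (all three pairwise associations encoded)
administer all six directions; open-loop events (two associations sharing a
common element) administer only the four directions involving that element.

Six 2×2 contingency tables are built per matrix: for each category X, the
*cue-common* table cross-classifies the correctness of the two directions
cued by X, and the *target-common* table the two directions retrieving X. An
event contributes to a table only when both of its directions were
administered, which restricts open-loops to the two tables matching their
common element. The observed proportion of joint retrieval of a table is
(n11 + n00)/N; the independent model's is P1·P2 + (1−P1)(1−P2) with P1, P2
the participant's marginal accuracies on the two directions. Dependency is
the data-minus-model difference averaged (unweighted) over the non-empty
tables.

Choices within this definition:

- **Participant-level marginals.** Marginal accuracy is one number per
  direction per participant — the operational reading of "mean performance
  across all events". Event-level retrieval probabilities are unobservable
  from a single binary outcome per cell.
- **Per-table event sets.** Marginals are computed over exactly the events
  contributing to that table, so data and model are always evaluated on the
  same event set. For closed-loop matrices with nothing missing this
  coincides with global marginals; for open-loops it does not.
- **Empty tables are dropped**, not imputed (0/0 is undefined); a matrix with
  all six tables empty is an error.
- **Missing responses are recoded as incorrect** at load time, with the count
  logged; both the accuracy and the dependency analyses then see the recoded
  values.
- The statistic scales with accuracy (the model term for equal marginals p is
  1 − 2p(1 − p), minimized at p = .5), so only the data-minus-model
  difference is interpretable, never the joint proportion alone.
- The delayed-session analysis by default excludes events tested at the
  immediate session, the standard control for testing effects
  (`exclude_tested_at_t1=True`).

## The independent-forgetting model

Given a closed-loop T1 matrix and a target accuracy (the participant's
observed T2 accuracy), the model flips k = round((acc_T1 − target) · 6N)
cells, drawn uniformly without replacement from the correct cells, to
incorrect; dependency is recomputed on the simulated matrix with the
independence model re-derived from the *simulated* marginals (dependency is
defined relative to the same matrix's marginals). The mean over n_sims = 100
simulations estimates the dependency expected at T2 if trials were forgotten
independently.

- **Exact-count flipping is the default** because the procedure equates mean
  performance to the observed T2 level; every correct cell is equally likely
  to flip (exchangeable), which realizes "each correct trial has a
  probability of being forgotten proportional to the mean forgetting rate"
  without the binomial jitter. A per-cell Bernoulli scheme
  (`scheme="bernoulli"`, flip probability Δacc/acc_T1) is provided for
  sensitivity analysis; the two agree in expectation.
- Achieved accuracy is within one cell, 1/(6N), of the target in every
  simulation; zero forgetting reproduces the T1 matrix (and its dependency)
  exactly.
- The model only removes memories: a target above T1 accuracy yields zero
  flips and a warning. Recovery (incorrect at T1, correct at T2) is outside
  the conversion rule — a faithful limitation, not an oversight.
- Open-loop matrices are rejected; the model is defined for fully
  administered closed-loop matrices.
- Per-participant seed streams are spawned from one master seed
  (`numpy.random.SeedSequence`), so any single participant's simulations are
  reproducible in isolation.

## The generative cohort model

The generator produces binary outcomes with known ground truth so that every
downstream stage is testable offline. It is a regime contrast, not a fit to
any human sample; its parameter values are not claims about real
participants.

Latent structure per participant:

1. **Storage.** `holistic`: one Bernoulli(p_store) draw per closed-loop event
   — the engram exists or it does not. `independent_associations`: one draw
   per encoded undirected pair. Open-loops always store per pair, in either
   mode: an open-loop is by construction not bound into a single engram,
   which is exactly why its dependency is null, and the generator encodes
   that asymmetry rather than leaving it to parameter choice.
2. **Forgetting (T1 → T2).** Survival is drawn per stored *trace*. Under
   `all_or_none` a holistic event trace survives or dies as a unit (one draw
   per event); under `association_independent` it fragments (one draw per
   undirected pair). Pair-level traces are their own unit, so they take one
   draw per pair under both modes — applying an event-level survival draw to
   independently stored pairs would manufacture dependency out of correlated
   forgetting rather than holistic storage, contradicting the regime's
   definition. A `direction_level_forgetting` flag draws survival per
   direction instead of per pair, for sensitivity analysis.
3. **Response.** A trial with a live trace is correct with probability
   1 − lapse; without one, with probability p_guess = 1/6 (six-alternative
   forced choice). Guesses are independent across trials; foil identity is
   not modelled (outcomes are binary).

Defaults: p_store = .7, lapse = .05, p_guess = 1/6, survival_T2 = .6,
tested_boost = 1 (testing effect off), 26 participants. Marginal T1 accuracy
follows the closed form p_store(1 − lapse) + (1 − p_store)·p_guess ≈ .72,
and T2 accuracy ≈ .50 — the forgetting range of a one-week delay. The
implied dependency (~.3) is far larger than human closed-loop dependency
(~.03–.06): the generator states clean regimes (fully holistic storage, no
subject heterogeneity), so a green test establishes that the analysis
recovers the regime's signature, not that the generator mimics human effect
sizes. Real data also carry features the generator omits: subject-level
parameter heterogeneity, item effects, foil-confusion structure and
reaction-time dynamics.

Under holistic + all-or-none the exact T2 dependency expectation can be
enumerated over the three latent states (stored-and-survived, stored-lost,
never-stored), including the O(1/N) finite-sample term from the covariance
of the two estimated marginals; the test suite checks the simulator against
that enumeration.

## Experimental schedules

Triplet elements are synthetic labels (`location_01`, …); the real word lists
are stimuli, not computation. Schedules reproduce the four layouts:

- Between-subjects designs (Experiments 1–2): 60 triplets of one loop type;
  encoding in 3 (closed) or 2 (open) blocks of 60, one pair per triplet per
  block; the three pair-order rotations are allocated to closed triplets
  round-robin after a shuffle (any balanced allocation is acceptable — the
  source designs state rotation but not the assignment rule); open-loop pair
  order is fixed by the common element. Tests: 30 triplets at T1 (180/120
  trials closed/open), all 60 at T2 (360/240), plus the Experiment-1
  open-loop inference task (the never-encoded pair, both directions, 120
  trials over two extra blocks).
- Within-subject designs (Experiments 3–4): 30 closed + 30 open; encoding in
  blocks of 30/60/60 with the first block closed-loop-only; T2 tests all 60
  (300 trials over six blocks, open-loop directions spread over four of the
  six); Experiment 4 adds a T1 test of 15 + 15 triplets (150 trials). The
  tested-at-T1 assignment is stratified by loop type.
- Breaks (every 30 trials; every 25 at the Experiment-4 immediate test) and
  on-screen placement are metadata only; there is no timing engine.
- One explicit seed drives each schedule's randomization
  (`numpy.random.default_rng`), so schedules are exactly reproducible.

## Inference

- **t-tests / effect sizes.** One-sample (paired-differences) t-tests; the
  per-contrast effect size for two conditions is the mean difference over
  the SD pooled across the two condition samples, applied uniformly to
  within- and between-subject contrasts. Zero-variance samples (numerically,
  sd ≤ 1e−12 relative) are an error: a constant sample admits no t-test.
- **JZS Bayes factor.** Cauchy prior (centre 0, scale r = .707 by default) on
  the standardized effect; the marginal likelihood under the alternative is
  ∫ nct(t; ν, δ√n) dCauchy(δ), integrated by adaptive quadrature
  (`scipy.integrate.quad`, limit 200). One-sided alternatives truncate and
  renormalize the prior to the stated sign (prior truncation, not
  posterior-odds correction). The "exceedance probability" reported with a
  Bayes factor is the posterior probability of the favored hypothesis at
  equal prior odds, BF/(1 + BF) — the reading that makes a BF of 5.41
  correspond to .84. A non-finite integrand raises with diagnostics rather
  than returning garbage.
- **Power.** Exact noncentral-t power; `required_sample_size` scans n upward
  from 2 (a t-test needs two observations, so very large effects floor
  there). The design constant d = .62, α = .05, power = .85 (two-tailed,
  one-sample) gives n = 26, with exact power .845 at n = 25 and .859 at
  n = 26.
- Mixed ANOVAs are deliberately out of scope; group contrasts go through
  t-tests and Bayes factors.

## Numerical conventions

- Response matrices are int8 arrays with 1/0/−1 for correct/incorrect/not
  administered; all statistics ignore −1 cells.
- Proportions are reported to 3 decimals in summaries.
- CSV: comma-separated, UTF-8, header required, lower-case enumerations,
  sessions named `T1`/`T2`. Loading validates every categorical column and
  names the offending row on error. Second-level (per-participant summary)
  files require an explicit schema map — deposited layouts vary, so no
  column-name guessing is done.
- Monte-Carlo tests in the suite are seeded and compare against oracles at
  multiples of the estimated standard error; the independence-null check
  pools replicate cohorts (600 participants per accuracy level) so the
  estimate sits well inside its 2 SE band rather than at the boundary.

## Known limitations

- The forgetting model cannot represent recovery or reminiscence.
- The generator draws one parameter set per cohort; subject heterogeneity is
  future work.
- Reaction times, response-option confusion and sleep physiology are not
  modelled anywhere.
- The dependency measure is the joint-retrieval difference only; odds-ratio
  or Yule's-Q variants are out of scope.
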