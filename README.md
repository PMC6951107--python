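# loopdep

Retrieval dependency and independent-forgetting modelling for multi-element
episodic memory experiments.

## The problem

In cued-recognition studies of three-element events (a location, a person and
an object bound together at encoding), the question is not just *how much* is
forgotten between an immediate test (T1) and a delayed test (T2), but *how*:
do the pairwise associations of an event fragment independently, or is the
whole event retained or lost as a unit? The behavioral signature is
**retrieval dependency**: whether successfully retrieving one association of
an event predicts successfully retrieving another association of the same
event.

For each participant, six 2×2 contingency tables cross-classify the
correctness of pairs of retrieval directions that share an element — for each
element category X, one table for the two directions *cued by* X and one for
the two directions *retrieving* X. The proportion of joint retrieval of a
table is the leading diagonal over the total,

    p_joint = (n11 + n00) / N,

the fraction of events where the two directions succeed or fail together. The
**independent model** predicts that proportion from the participant's marginal
accuracies alone,

    p_independent = P1·P2 + (1 − P1)(1 − P2),

and dependency is the data-minus-model difference, averaged over the six
tables. Positive dependency means holistic, pattern-completion-like retrieval;
zero dependency is what "open-loop" structures (only two of the three
associations encoded) produce.

The **independent-forgetting model** asks whether dependency observed after a
delay exceeds what element-wise forgetting would leave behind: it takes a
participant's T1 trial matrix (6 retrieval directions × N events), flips
correct cells to incorrect uniformly at random until mean accuracy matches the
observed T2 accuracy, recomputes dependency on each of (by default) 100
simulated matrices, and reports the mean. Observed T2 dependency above the
simulated mean is evidence that forgetting was *not* independent — i.e. that
events are forgotten all-or-none.

The package also includes the experiment-design generator (triplets, encoding
and test schedules, 6-alternative foil sets for all four experiment layouts),
a generative simulator of whole cohorts under explicit encoding/forgetting
regimes (so every stage is testable without any data download), and the
inferential layer: one-sample t-tests, pooled Cohen's d, JZS Bayes factors
(Cauchy prior, numerical integration, one-sided variants by prior truncation)
and exact noncentral-t power analysis.

## Worked example

```python
from loopdep import (
    ExperimentConfig, GenerativeParams, RetrievalDependencyModel,
    IndependentForgettingModel, simulate_cohort,
)

params = GenerativeParams(
    p_store=0.7, lapse=0.05, survival_T2=0.6,
    encoding_mode="holistic", forgetting_mode="all_or_none",
    n_participants=26, seed=1,
)
cohort = simulate_cohort(params, ExperimentConfig.for_experiment(2))
fit = RetrievalDependencyModel.from_cohort(cohort).fit()
print(fit.summary())
```

prints

```
Retrieval dependency analysis
==================================
       closed T1  n= 26  data 0.849 (0.031)  model 0.577 (0.044)  dependency +0.272 (0.040)
       closed T2  n= 26  data 0.814 (0.048)  model 0.508 (0.013)  dependency +0.305 (0.047)
```

Joint retrieval in the data exceeds the independent model at both sessions:
under holistic storage with all-or-none forgetting, dependency survives the
loss of roughly a third of the stored events (accuracy drops from ~.72 to
~.50) because surviving events stay intact. Feeding the same participants' T1
matrices to the independent-forgetting model shows what fragmentation would
have looked like instead:

```python
# t1_matrices: per-participant closed-loop T1 matrices
# t2_targets:  per-participant observed T2 accuracy
fm = IndependentForgettingModel(t1_matrices, t2_targets).fit(n_sims=100, seed=3)
print(fm.summary())
```

```
Independent-forgetting model
==================================
participants: 26   simulations per participant: 100
mean T1 accuracy 0.687 -> target 0.525 (mean flips 29.3)
observed T1 dependency  +0.272
simulated T2 dependency +0.168
predicted decrease: t(25) = 11.15, p = 3.4e-11, d = 2.19
```

Independent forgetting predicts a large drop in dependency (+.272 → +.168);
the observed T2 dependency (+.305) shows no such drop — the all-or-none
dissociation.

The same chain is available from the shell:

```bash
loopdep simulate --participants 26 --seed 1 --out trials.csv
loopdep analyze trials.csv
loopdep forgetting-model trials.csv --n-sims 100 --seed 3
loopdep power -d 0.62 --power 0.85       # -> required sample size: 26
loopdep run --config run.yaml --out report/
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch —
simulating a 26-participant cohort under the holistic/all-or-none regime,
computing dependency at both sessions, fitting the independent-forgetting
model (100 simulations per participant) and evaluating the inferential layer —
and writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the printed summaries are recomputed at
run time.
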