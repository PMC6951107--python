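"""The independent-forgetting model.

Given a participant's immediate-session (T1) trial matrix for closed-loops and
their observed delayed-session (T2) accuracy, the model simulates what
dependency would look like at T2 if individual retrieval trials were forgotten
independently of one another: correct cells of the 6 x N matrix are converted
to incorrect, uniformly at random, until mean performance matches the observed
T2 accuracy. Dependency is then recomputed on each simulated matrix (with the
independence model re-derived from the simulated marginals). If observed T2
dependency exceeds the simulated mean, forgetting did not act independently on
the event's associations.

The model can only remove memories: when the target accuracy exceeds T1
accuracy no cells are flipped and a warning is raised. Recovery (incorrect at
T1, correct at T2) is outside the model, a faithful limitation of the
correct-to-incorrect conversion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dependency import dependency_for_participant
from .matrix import ResponseMatrix


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _check_closed(matrix: ResponseMatrix) -> None:
    if not matrix.is_closed_only():
        raise ValueError(
            "independent-forgetting model applies to closed-loop matrices only "
            "(all six directions administered)"
        )


def flip_count(acc_t1: float, target_accuracy: float, n_cells: int) -> int:
    """Number of correct->incorrect conversions equating mean performance."""
    k = int(round((acc_t1 - target_accuracy) * n_cells))
    return max(k, 0)


def simulate_t2_matrix(
    matrix_t1: ResponseMatrix,
    target_accuracy: float,
    seed,
    scheme: str = "exact",
) -> ResponseMatrix:
    """Degrade a T1 matrix to the target accuracy by random independent flips.

    ``scheme='exact'`` (default) flips exactly k = round(delta_acc * 6N) cells
    drawn uniformly without replacement from the correct cells, equating mean
    performance to the target. ``scheme='bernoulli'`` instead flips each
    correct cell independently with probability delta_acc / acc_T1 (same
    expectation, binomial variation around it).
    """
    _check_closed(matrix_t1)
    if not 0.0 <= target_accuracy <= 1.0:
        raise ValueError("target_accuracy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix_t1.copy()
    out.session = "T2_simulated"

    acc = matrix_t1.accuracy()
    correct = np.argwhere(out.responses == 1)
    if target_accuracy > acc:
        warnings.warn(
            "target accuracy exceeds T1 accuracy; the model cannot add "
            "memories, no cells flipped"
        )
        return out

    if scheme == "exact":
        k = min(flip_count(acc, target_accuracy, out.responses.size), len(correct))
        chosen = correct[rng.choice(len(correct), size=k, replace=False)]
    elif scheme == "bernoulli":
        p_flip = 0.0 if acc == 0 else min((acc - target_accuracy) / acc, 1.0)
        chosen = correct[rng.random(len(correct)) < p_flip]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out.responses[chosen[:, 0], chosen[:, 1]] = 0
    return out


@dataclass
class ForgettingSimResult:
    """Monte-Carlo summary for one participant."""

    participant: object
    n_sims: int
    dependencies: np.ndarray
    flips_per_sim: np.ndarray
    target_accuracy: float
    t1_accuracy: float
    t1_dependency: float

    @property
    def mean_dependency(self) -> float:
        return float(np.mean(self.dependencies))

    @property
    def sd_dependency(self) -> float:
        return float(np.std(self.dependencies, ddof=1)) if self.n_sims > 1 else 0.0


def forgetting_model_dependency(
    matrix_t1: ResponseMatrix,
    target_accuracy: float,
    n_sims: int = 100,
    seed=None,
    scheme: str = "exact",
) -> ForgettingSimResult:
    """Simulated T2 dependency under independent forgetting for one participant."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    _check_closed(matrix_t1)
    ss = _seedseq(seed)
    t1_res = dependency_for_participant(matrix_t1)
    deps = np.empty(n_sims)
    flips = np.empty(n_sims, dtype=int)
    for s, child in enumerate(ss.spawn(n_sims)):
        sim = simulate_t2_matrix(matrix_t1, target_accuracy, child, scheme=scheme)
        deps[s] = dependency_for_participant(sim).dependency
        flips[s] = int(np.sum((matrix_t1.responses == 1) & (sim.responses == 0)))
    return ForgettingSimResult(
        participant=matrix_t1.participant,
        n_sims=n_sims,
        dependencies=deps,
        flips_per_sim=flips,
        target_accuracy=target_accuracy,
        t1_accuracy=matrix_t1.accuracy(),
        t1_dependency=t1_res.dependency,
    )


class IndependentForgettingModel:
    """Cohort-level independent-forgetting model.

    Parameters
    ----------
    matrices_t1 : sequence of ResponseMatrix
        Closed-loop immediate-session matrices, one per participant.
    target_accuracies : mapping or sequence
        Observed delayed-session accuracy per participant (dict keyed by
        participant id, or a sequence aligned with ``matrices_t1``).
    """

    def __init__(self, matrices_t1, target_accuracies, scheme: str = "exact"):
        self.matrices_t1 = list(matrices_t1)
        if isinstance(target_accuracies, dict):
            self.targets = [target_accuracies[m.participant] for m in self.matrices_t1]
        else:
            self.targets = list(target_accuracies)
        if len(self.targets) != len(self.matrices_t1):
            raise ValueError("one target accuracy required per matrix")
        self.scheme = scheme

    def fit(self, n_sims: int = 100, seed=None) -> "IndependentForgettingResults":
        ss = _seedseq(seed)
        results = []
        for m, target, child in zip(
            self.matrices_t1, self.targets, ss.spawn(len(self.matrices_t1))
        ):
            results.append(
                forgetting_model_dependency(
                    m, target, n_sims=n_sims, seed=child, scheme=self.scheme
                )
            )
        return IndependentForgettingResults(self, results)


class IndependentForgettingResults:
    """Per-participant simulated dependency and cohort-level contrasts."""

    def __init__(self, model, results):
        self.model = model
        self.participant_results = results
        self.table = pd.DataFrame(
            {
                "participant": [r.participant for r in results],
                "t1_accuracy": [r.t1_accuracy for r in results],
                "target_accuracy": [r.target_accuracy for r in results],
                "t1_dependency": [r.t1_dependency for r in results],
                "simulated_dependency": [r.mean_dependency for r in results],
                "mean_flips": [float(np.mean(r.flips_per_sim)) for r in results],
            }
        )

    def predicted_decrease(self):
        """Paired t-test: observed T1 dependency vs simulated T2 dependency."""
        from .stats import one_sample_t

        diff = (
            self.table["t1_dependency"] - self.table["simulated_dependency"]
        ).to_numpy()
        return one_sample_t(diff)

    def compare_observed(self, observed_t2: dict):
        """Paired t-test: observed T2 dependency vs simulated T2 dependency."""
        from .stats import one_sample_t

        obs = np.array([observed_t2[p] for p in self.table["participant"]])
        return one_sample_t(obs - self.table["simulated_dependency"].to_numpy())

    def summary(self) -> str:
        t = self.table
        dec = self.predicted_decrease()
        lines = [
            "Independent-forgetting model",
            "=" * 34,
            f"participants: {len(t)}   simulations per participant: "
            f"{self.participant_results[0].n_sims}",
            f"mean T1 accuracy {t['t1_accuracy'].mean():.3f} -> target "
            f"{t['target_accuracy'].mean():.3f} "
            f"(mean flips {t['mean_flips'].mean():.1f})",
            f"observed T1 dependency  {t['t1_dependency'].mean():+.3f}",
            f"simulated T2 dependency {t['simulated_dependency'].mean():+.3f}",
            f"predicted decrease: t({dec.df}) = {dec.t:.2f}, p = {dec.p:.2g}, "
            f"d = {dec.d:.2f}",
        ]
        return "\n".join(lines)
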