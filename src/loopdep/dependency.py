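"""Retrieval dependency: observed joint retrieval versus the independent model.

For each participant, six 2x2 contingency tables cross-classify the
correctness of two retrieval directions that share an element: for each
category X, one table for the two directions cued by X (cue-common) and one
for the two directions retrieving X (target-common). The proportion of joint
retrieval in a table is the leading diagonal over the total, (n11 + n00) / N —
the fraction of events where both directions were retrieved together, either
both correctly or both incorrectly. The independent model predicts that
proportion from the participant's marginal accuracies alone, as
p1 * p2 + (1 - p1)(1 - p2). Dependency is the data-minus-model difference,
averaged over the (non-empty) tables.

Marginals are participant-level and computed per table over the events that
contribute to that table, so data and model are always evaluated on identical
event sets; this matters for open-loops, whose events contribute only to the
two tables matching their common element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DIRECTIONS, CATEGORIES
from .matrix import ResponseMatrix


@dataclass(frozen=True)
class TableSpec:
    """One of the six contingency-table specifications."""

    common_category: str
    orientation: str  # 'cue_common' | 'target_common'

    def __post_init__(self):
        if self.common_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.common_category!r}")
        if self.orientation not in ("cue_common", "target_common"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def direction_indices(self) -> tuple:
        """The two direction columns this table cross-classifies."""
        role = 0 if self.orientation == "cue_common" else 1
        idx = [i for i, d in enumerate(DIRECTIONS) if d[role] == self.common_category]
        assert len(idx) == 2
        return tuple(idx)

    def __str__(self):
        return f"{self.orientation}({self.common_category})"


TABLE_SPECS = tuple(
    TableSpec(cat, orient)
    for orient in ("cue_common", "target_common")
    for cat in CATEGORIES
)


@dataclass
class ContingencyTable:
    n11: int
    n10: int
    n01: int
    n00: int
    spec: TableSpec
    p1: float = float("nan")  # marginal accuracy of the first direction
    p2: float = float("nan")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def empty(self) -> bool:
        return self.total == 0


def tabulate(matrix: ResponseMatrix, spec: TableSpec) -> ContingencyTable:
    """Cross-classify the two directions of ``spec`` over contributing events.

    An event contributes only when both directions were administered, which
    restricts open-loop events to the two tables matching their common
    element.
    """
    i, j = spec.direction_indices
    a, b = matrix.responses[:, i], matrix.responses[:, j]
    mask = (a >= 0) & (b >= 0)
    a, b = a[mask], b[mask]
    table = ContingencyTable(
        n11=int(np.sum((a == 1) & (b == 1))),
        n10=int(np.sum((a == 1) & (b == 0))),
        n01=int(np.sum((a == 0) & (b == 1))),
        n00=int(np.sum((a == 0) & (b == 0))),
        spec=spec,
    )
    if table.total:
        table.p1 = float(a.mean())
        table.p2 = float(b.mean())
    return table


def joint_retrieval(table: ContingencyTable) -> float:
    """Leading diagonal over the total: (n11 + n00) / N."""
    if table.total == 0:
        raise ValueError(f"table {table.spec} has no contributing events")
    return (table.n11 + table.n00) / table.total


def independent_joint(p1: float, p2: float) -> float:
    """Joint proportion predicted when the two retrievals are independent."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("marginal accuracies must lie in [0, 1]")
    return p1 * p2 + (1.0 - p1) * (1.0 - p2)


@dataclass
class DependencyResult:
    """Per-participant dependency with the per-table breakdown."""

    participant: object
    session: str
    p_joint_data: float
    p_joint_model: float
    tables: list

    @property
    def dependency(self) -> float:
        return self.p_joint_data - self.p_joint_model

    @property
    def n_tables(self) -> int:
        return sum(not t.empty for t in self.tables)

    def breakdown(self) -> pd.DataFrame:
        rows = []
        for t in self.tables:
            rows.append(
                {
                    "table": str(t.spec),
                    "n11": t.n11,
                    "n10": t.n10,
                    "n01": t.n01,
                    "n00": t.n00,
                    "p1": t.p1,
                    "p2": t.p2,
                    "p_joint_data": joint_retrieval(t) if not t.empty else np.nan,
                    "p_joint_model": (
                        independent_joint(t.p1, t.p2) if not t.empty else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)


def dependency_for_participant(matrix: ResponseMatrix) -> DependencyResult:
    """Dependency statistic for one participant-session matrix.

    The observed and model joint proportions are unweighted means over the
    non-empty tables; empty tables (possible for sparse open-loop designs)
    are excluded rather than imputed.
    """
    tables = [tabulate(matrix, spec) for spec in TABLE_SPECS]
    filled = [t for t in tables if not t.empty]
    if not filled:
        raise ValueError("all six contingency tables are empty")
    p_data = float(np.mean([joint_retrieval(t) for t in filled]))
    p_model = float(np.mean([independent_joint(t.p1, t.p2) for t in filled]))
    return DependencyResult(
        participant=matrix.participant,
        session=matrix.session,
        p_joint_data=p_data,
        p_joint_model=p_model,
        tables=tables,
    )


def results_frame(results: Sequence[DependencyResult], **extra) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "participant": r.participant,
                "session": r.session,
                "p_joint_data": r.p_joint_data,
                "p_joint_model": r.p_joint_model,
                "dependency": r.dependency,
                **extra,
            }
        )
    return pd.DataFrame(rows)


def group_summary(frame: pd.DataFrame, by=("session",)) -> pd.DataFrame:
    """Group means and SDs of the joint proportions and dependency.

    Mirrors the shape of a summary table with one row per group and
    mean (SD) for the data, the independent model and their difference.
    """
    by = list(by)
    cols = ["p_joint_data", "p_joint_model", "dependency"]
    groups = []
    for key, g in frame.groupby(by, dropna=False):
        if g.empty:
            warnings.warn(f"empty group {key!r} omitted from summary")
            continue
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(g)
        for c in cols:
            row[f"{c}_mean"] = float(g[c].mean())
            row[f"{c}_sd"] = float(g[c].std(ddof=1)) if len(g) > 1 else 0.0
        groups.append(row)
    return pd.DataFrame(groups)


class RetrievalDependencyModel:
    """Dependency analysis over a set of participant-session matrices.

    Parameters
    ----------
    matrices : sequence of ResponseMatrix
        One matrix per participant per session.
    exclude_tested_at_t1 : bool
        When True, delayed-session (T2) matrices are restricted to events not
        tested at the immediate session before analysis, the standard control
        for testing effects.

    ``fit()`` returns a :class:`RetrievalDependencyResults` carrying the
    per-participant statistics, group summaries and data-versus-model tests.
    """

    def __init__(self, matrices: Sequence[ResponseMatrix], exclude_tested_at_t1: bool = True):
        self.matrices = list(matrices)
        self.exclude_tested_at_t1 = exclude_tested_at_t1
        if not self.matrices:
            raise ValueError("no matrices supplied")

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, **kwargs) -> "RetrievalDependencyModel":
        """Build from the trial-level table (one row per retrieval trial)."""
        from .io import trials_to_matrices

        return cls(trials_to_matrices(trials), **kwargs)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "RetrievalDependencyModel":
        mats = []
        for p in cohort.participants:
            mats.extend(cohort.matrices[p].values())
        return cls(mats, **kwargs)

    def _analysis_matrix(self, m: ResponseMatrix) -> ResponseMatrix:
        if self.exclude_tested_at_t1 and m.session == "T2":
            keep = ~m.events["tested_at_T1"].to_numpy(dtype=bool)
            if keep.any() and not keep.all():
                return m.subset(keep)
        return m

    def fit(self) -> "RetrievalDependencyResults":
        results, rows = [], []
        for m in self.matrices:
            mm = self._analysis_matrix(m)
            res = dependency_for_participant(mm)
            results.append(res)
            loop_types = set(mm.events["loop_type"])
            rows.append(
                {
                    "participant": res.participant,
                    "session": res.session,
                    "loop_type": loop_types.pop() if len(loop_types) == 1 else "mixed",
                    "accuracy": mm.accuracy(),
                    "p_joint_data": res.p_joint_data,
                    "p_joint_model": res.p_joint_model,
                    "dependency": res.dependency,
                }
            )
        return RetrievalDependencyResults(self, results, pd.DataFrame(rows))


class RetrievalDependencyResults:
    """Fitted dependency analysis: per-participant table plus inference."""

    def __init__(self, model, results, table: pd.DataFrame):
        self.model = model
        self.participant_results = results
        self.table = table

    def summary_table(self, by=("loop_type", "session")) -> pd.DataFrame:
        return group_summary(self.table, by=[b for b in by if b in self.table])

    def ttest_data_vs_model(self, session: Optional[str] = None, loop_type: Optional[str] = None):
        """Paired t-test of joint retrieval in the data against the model."""
        from .stats import one_sample_t

        sub = self.table
        if session is not None:
            sub = sub[sub["session"] == session]
        if loop_type is not None:
            sub = sub[sub["loop_type"] == loop_type]
        return one_sample_t(sub["dependency"].to_numpy())

    def summary(self) -> str:
        lines = ["Retrieval dependency analysis", "=" * 34]
        summ = self.summary_table()
        for _, r in summ.iterrows():
            label = " ".join(
                str(r[c]) for c in ("loop_type", "session") if c in summ.columns
            )
            lines.append(
                f"{label:>16}  n={int(r['n']):3d}  "
                f"data {r['p_joint_data_mean']:.3f} ({r['p_joint_data_sd']:.3f})  "
                f"model {r['p_joint_model_mean']:.3f} ({r['p_joint_model_sd']:.3f})  "
                f"dependency {r['dependency_mean']:+.3f} ({r['dependency_sd']:.3f})"
            )
        return "\n".join(lines)
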