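"""The per-participant response matrix: events x six retrieval directions.

Entries are coded 1 (correct), 0 (incorrect), -1 (not administered). A
closed-loop event has all six directions administered; an open-loop event has
only the four directions involving its common element. This is the "6 x N"
trial matrix that both the dependency analysis and the independent-forgetting
simulation operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DIRECTIONS, administered_directions

CORRECT, INCORRECT, NOT_ADMINISTERED = 1, 0, -1


@dataclass
class ResponseMatrix:
    """Binary retrieval outcomes for one participant in one session."""

    participant: object
    session: str
    responses: np.ndarray  # (n_events, 6) int8 in {1, 0, -1}
    events: pd.DataFrame  # columns: triplet_id, loop_type, common_category, tested_at_T1

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.int8)
        if self.responses.ndim != 2 or self.responses.shape[1] != len(DIRECTIONS):
            raise ValueError("responses must be (n_events, 6)")
        if len(self.events) != self.responses.shape[0]:
            raise ValueError("event metadata does not match the response array")
        if not np.isin(self.responses, (1, 0, -1)).all():
            raise ValueError("entries must be 1 (correct), 0 (incorrect) or -1")
        self.events = self.events.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return self.responses.shape[0]

    @property
    def administered(self) -> np.ndarray:
        return self.responses >= 0

    def accuracy(self) -> float:
        """Mean proportion correct over administered cells."""
        mask = self.administered
        if not mask.any():
            raise ValueError("matrix has no administered trials")
        return float(self.responses[mask].mean())

    def is_closed_only(self) -> bool:
        return bool((self.events["loop_type"] == "closed").all()) and bool(
            self.administered.all()
        )

    def subset(self, row_mask) -> "ResponseMatrix":
        mask = np.asarray(row_mask, dtype=bool)
        return ResponseMatrix(
            participant=self.participant,
            session=self.session,
            responses=self.responses[mask].copy(),
            events=self.events.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "ResponseMatrix":
        return self.subset(np.ones(self.n_events, dtype=bool))


def empty_matrix(participant, session, triplets) -> ResponseMatrix:
    """All-not-administered matrix with event metadata from ``triplets``."""
    events = pd.DataFrame(
        {
            "triplet_id": [t.id for t in triplets],
            "loop_type": [t.loop_type for t in triplets],
            "common_category": [t.common_category for t in triplets],
            "tested_at_T1": [t.tested_at_T1 for t in triplets],
        }
    )
    responses = np.full((len(triplets), len(DIRECTIONS)), NOT_ADMINISTERED, np.int8)
    return ResponseMatrix(participant, session, responses, events)


def administered_mask_for_events(events: pd.DataFrame) -> np.ndarray:
    """Boolean (n_events, 6) mask of directions administered per event."""
    mask = np.zeros((len(events), len(DIRECTIONS)), dtype=bool)
    for i, (lt, cc) in enumerate(zip(events["loop_type"], events["common_category"])):
        cc = None if (cc is None or (isinstance(cc, float) and np.isnan(cc)) or cc == "") else cc
        mask[i, list(administered_directions(lt, cc))] = True
    return mask
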