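"""Generative model of cohort retrieval data under explicit encoding and
forgetting regimes.

The generator exists to give every downstream stage data with a known ground
truth. Two encoding regimes are available: ``holistic`` stores a closed-loop
event as a single all-or-none engram (one storage draw per event), while
``independent_associations`` stores each encoded pairwise association
independently. Open-loops always store per pair: an open-loop is, by
construction, not bound into a single engram, which is what makes its
dependency null. Two forgetting regimes map onto the same contrast between
sessions: ``all_or_none`` draws one survival indicator per event (the whole
trace lives or dies together), ``association_independent`` draws one per
stored undirected pair (the trace fragments).

A trial is answered from its trace when one exists (correct with probability
1 - lapse) and by guessing otherwise (correct with probability 1/6 under
six-alternative forced choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    DIRECTIONS,
    PAIRS,
    ExperimentConfig,
    Triplet,
    generate_triplets,
)
from .matrix import ResponseMatrix, empty_matrix, administered_mask_for_events

ENCODING_MODES = ("holistic", "independent_associations")
FORGETTING_MODES = ("all_or_none", "association_independent")

#: direction index -> index of its undirected pair in PAIRS
_DIR_PAIR = tuple(PAIRS.index(frozenset(d)) for d in DIRECTIONS)


@dataclass
class GenerativeParams:
    """Parameters of the synthetic behavioral model.

    p_store : probability an event (holistic) or pairwise association is
        stored at encoding.
    lapse : probability a stored trace nevertheless yields an incorrect
        response on a given retrieval trial.
    p_guess : probability of a correct response without a trace (1/6 for
        six-alternative forced choice).
    survival_T2 : probability a stored trace survives to the delayed session.
    tested_boost : multiplicative increase of survival for triplets tested at
        the immediate session (1 = testing effect off).
    direction_level_forgetting : sensitivity flag; when True, survival under
        ``association_independent`` is drawn per retrieval direction instead
        of per undirected pair.
    """

    p_store: float = 0.7
    lapse: float = 0.05
    p_guess: float = 1.0 / 6.0
    survival_T2: float = 0.6
    encoding_mode: str = "holistic"
    forgetting_mode: str = "all_or_none"
    tested_boost: float = 1.0
    direction_level_forgetting: bool = False
    n_participants: int = 26
    seed: int = 0

    def __post_init__(self):
        for name in ("p_store", "lapse", "p_guess", "survival_T2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tested_boost < 0 or self.survival_T2 * self.tested_boost > 1.0:
            raise ValueError("survival_T2 * tested_boost must lie in [0, 1]")
        if self.encoding_mode not in ENCODING_MODES:
            raise ValueError(f"unknown encoding_mode {self.encoding_mode!r}")
        if self.forgetting_mode not in FORGETTING_MODES:
            raise ValueError(f"unknown forgetting_mode {self.forgetting_mode!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def p_store_for_accuracy(accuracy: float, lapse: float = 0.0, p_guess: float = 1 / 6) -> float:
    """Invert the marginal-accuracy closed form acc = p(1-lapse) + (1-p)p_guess."""
    denom = (1.0 - lapse) - p_guess
    p = (accuracy - p_guess) / denom
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy {accuracy} unreachable with lapse={lapse}")
    return p


def _trace_matrix(params: GenerativeParams, triplets, rng) -> np.ndarray:
    """Per-direction trace indicator (n_events, 6) at the immediate session."""
    n = len(triplets)
    has_trace = np.zeros((n, 6), dtype=bool)
    for i, t in enumerate(triplets):
        if t.loop_type == "closed" and params.encoding_mode == "holistic":
            stored = rng.random() < params.p_store
            has_trace[i, :] = stored
        else:
            pair_ids = {PAIRS.index(p) for p in t.pairs}
            stored_pairs = {
                pid for pid in pair_ids if rng.random() < params.p_store
            }
            for d in range(6):
                if _DIR_PAIR[d] in pair_ids:
                    has_trace[i, d] = _DIR_PAIR[d] in stored_pairs
    return has_trace


def _survive(params: GenerativeParams, triplets, has_trace: np.ndarray, rng) -> np.ndarray:
    """Apply between-session forgetting to the trace matrix.

    Survival is drawn per stored trace: an event-level engram (holistic
    closed-loops) survives or dies as a unit under ``all_or_none`` but
    fragments per undirected pair under ``association_independent``; a
    pair-level trace is its own unit, so it always takes one draw per pair
    (or per direction with the sensitivity flag). Event-level survival draws
    are never applied to independently stored pairs — that would manufacture
    dependency out of correlated forgetting rather than holistic storage.
    """
    surviving = has_trace.copy()
    holistic_event = params.encoding_mode == "holistic"
    for i, t in enumerate(triplets):
        p_surv = params.survival_T2 * (params.tested_boost if t.tested_at_T1 else 1.0)
        event_trace = holistic_event and t.loop_type == "closed"
        if event_trace and params.forgetting_mode == "all_or_none":
            if rng.random() >= p_surv:
                surviving[i, :] = False
        elif params.direction_level_forgetting:
            for d in range(6):
                if surviving[i, d] and rng.random() >= p_surv:
                    surviving[i, d] = False
        else:
            pair_ids = sorted({_DIR_PAIR[d] for d in range(6) if has_trace[i, d]})
            dead = {pid for pid in pair_ids if rng.random() >= p_surv}
            for d in range(6):
                if surviving[i, d] and _DIR_PAIR[d] in dead:
                    surviving[i, d] = False
    return surviving


def _respond(params: GenerativeParams, has_trace, admin_mask, rng) -> np.ndarray:
    p_correct = np.where(has_trace, 1.0 - params.lapse, params.p_guess)
    draws = rng.random(has_trace.shape) < p_correct
    out = np.full(has_trace.shape, -1, dtype=np.int8)
    out[admin_mask] = draws[admin_mask].astype(np.int8)
    return out


def simulate_participant(
    params: GenerativeParams,
    triplets: Sequence[Triplet],
    seed,
    participant: object = 0,
    test_at_t1: bool = True,
) -> dict:
    """Simulate one participant; returns ``{'T1': ResponseMatrix, 'T2': ...}``.

    At the immediate session only triplets flagged ``tested_at_T1`` are
    administered (when the experiment includes an immediate test); at the
    delayed session every triplet is administered on its eligible directions.
    """
    rng = np.random.default_rng(seed)
    base = empty_matrix(participant, "T1", triplets)
    full_admin = administered_mask_for_events(base.events)

    has_trace = _trace_matrix(params, triplets, rng)

    out = {}
    if test_at_t1:
        t1_rows = base.events["tested_at_T1"].to_numpy(dtype=bool)
        t1_admin = full_admin & t1_rows[:, None]
        out["T1"] = ResponseMatrix(
            participant, "T1", _respond(params, has_trace, t1_admin, rng), base.events
        )
    surviving = _survive(params, triplets, has_trace, rng)
    out["T2"] = ResponseMatrix(
        participant, "T2", _respond(params, surviving, full_admin, rng), base.events
    )
    return out


@dataclass
class Cohort:
    """Simulated cohort: per participant, per session response matrices."""

    params: GenerativeParams
    config: ExperimentConfig
    triplets_by_participant: dict
    matrices: dict  # participant -> {'T1': ResponseMatrix, 'T2': ResponseMatrix}

    @property
    def participants(self) -> list:
        return sorted(self.matrices)

    def session_matrices(self, session: str) -> list:
        return [self.matrices[p][session] for p in self.participants if session in self.matrices[p]]

    def to_trials(self) -> pd.DataFrame:
        """Trial-level table (one row per administered direction)."""
        from .io import matrices_to_trials

        rows = []
        for p in self.participants:
            for session, m in self.matrices[p].items():
                rows.append(
                    matrices_to_trials(m, experiment=self.config.experiment)
                )
        return pd.concat(rows, ignore_index=True)


def simulate_cohort(
    params: GenerativeParams,
    config: Optional[ExperimentConfig] = None,
    loop_type: str = "closed",
) -> Cohort:
    """Simulate an independent cohort under one generative regime.

    Per-participant seeds are spawned from the master seed, so any single
    participant is reproducible in isolation. ``loop_type`` selects the
    condition for between-subjects designs and is ignored for within designs.
    """
    if config is None:
        config = ExperimentConfig.for_experiment(2)
    master = np.random.SeedSequence(params.seed)
    triplet_seeds = master.spawn(params.n_participants)
    response_seeds = master.spawn(params.n_participants)

    triplets_by_p, matrices = {}, {}
    for i in range(params.n_participants):
        pid = i + 1
        triplets = generate_triplets(
            config.n_triplets,
            config.loop_design,
            triplet_seeds[i],
            loop_type=loop_type if config.loop_design == "between" else None,
            tested_fraction=0.5 if config.test_at_t1 else 0.0,
        )
        triplets_by_p[pid] = triplets
        matrices[pid] = simulate_participant(
            params,
            triplets,
            response_seeds[i],
            participant=pid,
            test_at_t1=config.test_at_t1,
        )
    return Cohort(params, config, triplets_by_p, matrices)
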