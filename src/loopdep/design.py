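"""Experimental design: triplets, encoding schedules, test schedules, foil sets.

A *triplet* is one location-person-object set. Closed-loops encode all three
pairwise associations; open-loops encode only the two associations that share
a designated common element. Schedules reproduce the block structure of the
four experiments (between-subjects loops with 60 triplets in Experiments 1-2,
within-subject 30+30 in Experiments 3-4), including the closed-loop-only first
encoding block of Experiments 3-4 and the Experiment-1 delayed-test inference
task for open-loops.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("location", "person", "object")

#: The six ordered cue->target retrieval directions, in canonical order:
#: L->P, L->O, P->L, P->O, O->L, O->P.
DIRECTIONS = (
    ("location", "person"),
    ("location", "object"),
    ("person", "location"),
    ("person", "object"),
    ("object", "location"),
    ("object", "person"),
)

#: The three undirected pairwise associations.
PAIRS = (
    frozenset(("location", "person")),
    frozenset(("location", "object")),
    frozenset(("person", "object")),
)

# Presentation order of the three closed-loop pairs across the three encoding
# blocks; the three rotations are allocated to triplets round-robin.
CLOSED_ROTATIONS = (
    (("person", "location"), ("location", "object"), ("object", "person")),
    (("location", "object"), ("object", "person"), ("person", "location")),
    (("object", "person"), ("person", "location"), ("location", "object")),
)

# Open-loops encode the two pairs containing the common element; presentation
# order across the two encoding blocks, keyed by common element category.
OPEN_ORDERS = {
    "location": (("person", "location"), ("location", "object")),
    "object": (("location", "object"), ("object", "person")),
    "person": (("object", "person"), ("person", "location")),
}


def direction_index(cue_role: str, target_role: str) -> int:
    """Index of a cue->target direction in the canonical ``DIRECTIONS`` order."""
    return DIRECTIONS.index((cue_role, target_role))


def encoded_pairs(loop_type: str, common_category: Optional[str]) -> tuple:
    """Undirected pairs encoded for a triplet of the given structure."""
    if loop_type == "closed":
        return PAIRS
    if common_category is None:
        raise ValueError("open-loop triplet requires a common_category")
    return tuple(p for p in PAIRS if common_category in p)


def administered_directions(loop_type: str, common_category: Optional[str]) -> tuple:
    """Indices (into DIRECTIONS) of the directions tested for a triplet."""
    pairs = encoded_pairs(loop_type, common_category)
    return tuple(
        i for i, (c, t) in enumerate(DIRECTIONS) if frozenset((c, t)) in pairs
    )


@dataclass(frozen=True)
class Element:
    category: str
    id: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class Triplet:
    """One three-element event candidate with its associative structure."""

    id: int
    elements: dict  # category -> Element
    loop_type: str  # 'closed' | 'open'
    common_category: Optional[str] = None
    tested_at_T1: bool = False

    def __post_init__(self):
        if set(self.elements) != set(CATEGORIES):
            raise ValueError("triplet must hold exactly one element per category")
        if self.loop_type not in ("closed", "open"):
            raise ValueError(f"unknown loop_type {self.loop_type!r}")
        if (self.common_category is None) != (self.loop_type == "closed"):
            raise ValueError("common_category must be present iff loop_type is open")

    @property
    def pairs(self) -> tuple:
        return encoded_pairs(self.loop_type, self.common_category)


@dataclass(frozen=True)
class EncodingTrial:
    triplet_id: int
    pair: tuple  # (left, right) presentation order; unordered as association
    block: int
    position_in_block: int


@dataclass(frozen=True)
class TestTrial:
    session: str  # 'T1' | 'T2'
    triplet_id: int
    cue_role: str
    target_role: str
    block: int
    trial_kind: str = "direct"  # 'direct' | 'inference'

    def __post_init__(self):
        if self.cue_role == self.target_role:
            raise ValueError("cue and target roles must differ")


@dataclass
class ExperimentConfig:
    """Per-experiment schedule constants.

    ``loop_design`` is 'between' (each participant learns one loop type,
    Experiments 1-2) or 'within' (30 closed + 30 open per participant,
    Experiments 3-4). Break spacing is carried as metadata only.
    """

    experiment: int
    loop_design: str
    n_triplets: int = 60
    test_at_t1: bool = True
    inference_at_t2: bool = False  # Experiment 1 open-loop inference task
    closed_first_block: bool = False  # Experiments 3-4 encoding block 1
    break_every: dict = field(
        default_factory=lambda: {"encoding": 30, "T1": 30, "T2": 30}
    )

    @classmethod
    def for_experiment(cls, experiment: int) -> "ExperimentConfig":
        if experiment in (1, 2):
            return cls(
                experiment=experiment,
                loop_design="between",
                inference_at_t2=(experiment == 1),
            )
        if experiment == 3:
            return cls(
                experiment=3,
                loop_design="within",
                test_at_t1=False,
                closed_first_block=True,
            )
        if experiment == 4:
            return cls(
                experiment=4,
                loop_design="within",
                closed_first_block=True,
                break_every={"encoding": 30, "T1": 25, "T2": 30},
            )
        raise ValueError(f"unknown experiment id {experiment!r}")


def element_pools(n: int) -> dict:
    """Synthetic element pools: n labelled elements per category."""
    width = max(2, len(str(n)))
    return {
        cat: [Element(cat, f"{cat}_{i + 1:0{width}d}") for i in range(n)]
        for cat in CATEGORIES
    }


def generate_triplets(
    n: int,
    loop_design: str,
    seed,
    loop_type: Optional[str] = None,
    tested_fraction: float = 0.5,
    pools: Optional[dict] = None,
) -> list:
    """Generate ``n`` disjoint triplets with randomized condition assignment.

    For ``loop_design='between'`` every triplet takes the given ``loop_type``.
    For ``'within'`` half are closed and half open (``n`` must be even).
    Open-loops are partitioned as evenly as possible over the three possible
    common-element categories, and ``tested_fraction`` of the triplets are
    flagged as tested at the immediate session.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = element_pools(n)
    for cat in CATEGORIES:
        if len(pools[cat]) < n:
            raise ValueError(f"element pool for {cat!r} exhausted (need {n})")

    if loop_design == "within":
        if n % 2:
            raise ValueError("within design requires an even number of triplets")
        loop_types = ["closed"] * (n // 2) + ["open"] * (n // 2)
    elif loop_design == "between":
        if loop_type not in ("closed", "open"):
            raise ValueError("between design requires loop_type 'closed' or 'open'")
        loop_types = [loop_type] * n
    else:
        raise ValueError(f"unknown loop_design {loop_design!r}")
    rng.shuffle(loop_types)

    # Randomized element assignment: an independent permutation per category.
    chosen = {
        cat: [pools[cat][i] for i in rng.permutation(len(pools[cat]))[:n]]
        for cat in CATEGORIES
    }

    # Equal partition of open-loops over the three common categories.
    n_open = sum(1 for lt in loop_types if lt == "open")
    commons = [CATEGORIES[i % 3] for i in range(n_open)]
    rng.shuffle(commons)

    # immediate-test assignment, stratified by loop type so each condition
    # contributes the same number of tested triplets
    tested = np.zeros(n, dtype=bool)
    for lt in set(loop_types):
        idx = np.array([i for i, t in enumerate(loop_types) if t == lt])
        n_tested = int(round(tested_fraction * len(idx)))
        tested[idx[rng.permutation(len(idx))[:n_tested]]] = True

    triplets = []
    open_i = 0
    for i, lt in enumerate(loop_types):
        common = None
        if lt == "open":
            common = commons[open_i]
            open_i += 1
        triplets.append(
            Triplet(
                id=i,
                elements={cat: chosen[cat][i] for cat in CATEGORIES},
                loop_type=lt,
                common_category=common,
                tested_at_T1=bool(tested[i]),
            )
        )
    return triplets


def _rotation_assignment(triplets: Sequence[Triplet], rng) -> dict:
    """Round-robin allocation of the three closed rotations after a shuffle."""
    closed_ids = [t.id for t in triplets if t.loop_type == "closed"]
    order = [closed_ids[i] for i in rng.permutation(len(closed_ids))]
    return {tid: i % 3 for i, tid in enumerate(order)}


def _pair_sequence(triplet: Triplet, rotation: Optional[int]) -> tuple:
    """Presentation-ordered pairs for one triplet across its encoding blocks."""
    if triplet.loop_type == "closed":
        return CLOSED_ROTATIONS[rotation]
    return OPEN_ORDERS[triplet.common_category]


def build_encoding_schedule(
    triplets: Sequence[Triplet], config: ExperimentConfig, seed
) -> list:
    """Encoding schedule: one pairwise association per trial.

    Experiments 1-2: one pair from every triplet per block (2 blocks for
    open-loops, 3 for closed-loops), randomized within block. Experiments 3-4:
    three blocks of 30/60/60 with the first block closed-loop-only.
    """
    rng = np.random.default_rng(seed)
    rotation = _rotation_assignment(triplets, rng)
    seqs = {t.id: _pair_sequence(t, rotation.get(t.id)) for t in triplets}

    blocks: list = []
    if config.closed_first_block:
        closed = [t for t in triplets if t.loop_type == "closed"]
        open_ = [t for t in triplets if t.loop_type == "open"]
        if not closed or not open_:
            raise ValueError("closed-first encoding requires both loop types")
        blocks.append([(t.id, seqs[t.id][0]) for t in closed])
        for b in (1, 2):
            mixed = [(t.id, seqs[t.id][b]) for t in closed]
            mixed += [(t.id, seqs[t.id][b - 1]) for t in open_]
            blocks.append(mixed)
    else:
        n_blocks = max(len(seqs[t.id]) for t in triplets)
        if any(len(seqs[t.id]) != n_blocks for t in triplets):
            raise ValueError("between design expects a single loop type")
        for b in range(n_blocks):
            blocks.append([(t.id, seqs[t.id][b]) for t in triplets])

    trials = []
    for b, entries in enumerate(blocks, start=1):
        order = rng.permutation(len(entries))
        for pos, k in enumerate(order, start=1):
            tid, pair = entries[k]
            trials.append(
                EncodingTrial(triplet_id=tid, pair=pair, block=b, position_in_block=pos)
            )
    return trials


def build_test_schedule(
    triplets: Sequence[Triplet],
    session: str,
    config: ExperimentConfig,
    seed,
    include_inference: Optional[bool] = None,
) -> list:
    """Cued-recognition test schedule for one session.

    Every encoded pairwise association of every eligible triplet is tested in
    both directions exactly once. The immediate session tests only triplets
    flagged ``tested_at_T1``; the delayed session tests all. Closed-loop
    directions are spread over six blocks (one per block); open-loop
    directions over four blocks (four out of six in the within designs). In
    Experiment 1 the delayed open-loop session appends the inference task:
    the never-encoded pair, both directions, over two further blocks.
    """
    if session not in ("T1", "T2"):
        raise ValueError(f"unknown session {session!r}")
    if session == "T1" and not config.test_at_t1:
        raise ValueError(f"experiment {config.experiment} has no immediate test")
    rng = np.random.default_rng(seed)

    if session == "T1":
        eligible = [t for t in triplets if t.tested_at_T1]
    else:
        eligible = list(triplets)
    if not eligible:
        raise ValueError("no eligible triplets for this session")

    loop_types = {t.loop_type for t in triplets}
    within = config.loop_design == "within"
    n_blocks = 6 if ("closed" in loop_types or within) else 4

    # block -> list of (triplet_id, cue, target, kind)
    assigned: dict = {b: [] for b in range(1, n_blocks + 1)}
    for t in eligible:
        dirs = [DIRECTIONS[i] for i in administered_directions(t.loop_type, t.common_category)]
        k = len(dirs)  # 6 closed, 4 open
        block_ids = 1 + rng.permutation(n_blocks)[:k]
        for (cue, tgt), b in zip(dirs, block_ids):
            assigned[int(b)].append((t.id, cue, tgt, "direct"))

    if include_inference is None:
        include_inference = (
            config.inference_at_t2 and session == "T2" and "open" in loop_types
        )
    if include_inference:
        open_loops = [t for t in eligible if t.loop_type == "open"]
        if not open_loops:
            raise ValueError("inference trials requested but no open-loops present")
        for t in open_loops:
            (a, b) = sorted(set(CATEGORIES) - {t.common_category})
            for blk, (cue, tgt) in zip(
                1 + n_blocks + rng.permutation(2), ((a, b), (b, a))
            ):
                assigned.setdefault(int(blk), []).append((t.id, cue, tgt, "inference"))

    trials = []
    for b in sorted(assigned):
        entries = assigned[b]
        for k in rng.permutation(len(entries)):
            tid, cue, tgt, kind = entries[k]
            trials.append(
                TestTrial(
                    session=session,
                    triplet_id=tid,
                    cue_role=cue,
                    target_role=tgt,
                    block=b,
                    trial_kind=kind,
                )
            )
    return trials


def foil_set(trial: TestTrial, triplets: Sequence[Triplet], seed) -> list:
    """Six response options: the correct target plus five same-category foils.

    Foils are drawn without replacement from other triplets' elements of the
    target category; the target occupies a uniformly random slot.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in triplets}
    target = by_id[trial.triplet_id].elements[trial.target_role]
    pool = [
        t.elements[trial.target_role]
        for t in triplets
        if t.id != trial.triplet_id
    ]
    if len(pool) < 5:
        raise ValueError("fewer than 5 eligible foils in the target category")
    foils = [pool[i] for i in rng.permutation(len(pool))[:5]]
    options = foils[:]
    options.insert(int(rng.integers(0, 6)), target)
    return options


def break_positions(n_trials: int, every: int) -> list:
    """Trial indices (1-based) after which a 20-s break occurs."""
    return list(range(every, n_trials + 1, every))


def schedule_to_frame(trials, triplets, experiment: int, participant, session=None) -> pd.DataFrame:
    """Tabulate a schedule as one row per trial (the trial-level CSV schema)."""
    by_id = {t.id: t for t in triplets}
    rows = []
    for i, tr in enumerate(trials, start=1):
        t = by_id[tr.triplet_id]
        if isinstance(tr, EncodingTrial):
            cue_role, target_role, kind, sess = tr.pair[0], tr.pair[1], "encoding", "encoding"
        else:
            cue_role, target_role, kind, sess = tr.cue_role, tr.target_role, tr.trial_kind, tr.session
        rows.append(
            {
                "experiment": experiment,
                "participant": participant,
                "session": session or sess,
                "block": tr.block,
                "trial_index": i,
                "triplet_id": tr.triplet_id,
                "loop_type": t.loop_type,
                "common_category": t.common_category or "",
                "trial_kind": kind,
                "cue_role": cue_role,
                "target_role": target_role,
                "tested_at_T1": t.tested_at_T1,
            }
        )
    return pd.DataFrame(rows)
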