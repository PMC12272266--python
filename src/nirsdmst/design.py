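"""Experimental-design generation for the auditory delayed-matching-to-sample task.

Two sequences of sound items (S1, S2) separated by a silent retention delay
must be judged same/different. Items are drawn from fixed six-item
inventories: six piano tones of the C-major scale (C2 < E2 < G2 < B2 < D3 <
F3 in pitch) or six consonant-vowel syllables. This module generates item
sequences under the per-experiment combinatorial constraints, derives S2
from S1 (identical, one replaced item that changes the melodic contour, or
an adjacent swap), builds timed block schedules with interspersed silent
baseline trials, and counterbalances block order with Williams Latin
squares balanced for first-order carryover.

Experiment 1 crosses task (perception / memory) with material (musical /
verbal) using five-item sequences. Experiment 2 uses only the memory task
and crosses memory load (ML1-ML3: sequence length 4/5/6 musical, 6/7/8
verbal) with material; item repetition is then allowed under spacing rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ItemInventory",
    "TrialTiming",
    "EditRecord",
    "SequencePair",
    "TrialEntry",
    "BlockSchedule",
    "ExperimentPlan",
    "MUSICAL_ITEMS",
    "VERBAL_ITEMS",
    "compute_contour",
    "validate_sequence",
    "derive_s2",
    "make_perception_s2",
    "trial_duration",
    "sequence_duration",
    "build_condition_pool",
    "schedule_block",
    "latin_square_carryover",
    "build_experiment_plan",
    "session_events",
    "write_events_tsv",
    "ML_LENGTHS",
]

#: Musical inventory in ascending pitch order (rank = position).
MUSICAL_ITEMS = ("C2", "E2", "G2", "B2", "D3", "F3")

#: Verbal inventory (opaque labels, no ordering).
VERBAL_ITEMS = ("fi", "gu", "ly", "mo", "te", "za")

#: Sequence lengths per memory load and material in Experiment 2.
ML_LENGTHS = {
    ("ML1", "musical"): 4, ("ML2", "musical"): 5, ("ML3", "musical"): 6,
    ("ML1", "verbal"): 6, ("ML2", "verbal"): 7, ("ML3", "verbal"): 8,
}


@dataclass(frozen=True)
class ItemInventory:
    """Six-item inventory; musical items carry a strict pitch order."""

    material: str  # "musical" | "verbal"
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 6 or len(set(self.items)) != 6:
            raise ValueError("inventory must contain exactly 6 distinct items")

    @classmethod
    def musical(cls) -> "ItemInventory":
        return cls("musical", MUSICAL_ITEMS)

    @classmethod
    def verbal(cls) -> "ItemInventory":
        return cls("verbal", VERBAL_ITEMS)

    @classmethod
    def for_material(cls, material: str) -> "ItemInventory":
        if material == "musical":
            return cls.musical()
        if material == "verbal":
            return cls.verbal()
        raise ValueError(f"unknown material {material!r}")

    def rank(self, item: int) -> int:
        """Pitch rank of an item index (musical material only)."""
        if self.material != "musical":
            raise ValueError("pitch rank is defined for musical items only")
        return item  # items are stored in ascending pitch order


@dataclass(frozen=True)
class TrialTiming:
    """Trial timing constants in milliseconds.

    SOA = item + ISI = 600 ms; a trial is S1, a 6 s silent delay, S2, then a
    3 s response window, then a jittered silent inter-trial interval.
    """

    item_ms: int = 500
    isi_ms: int = 100
    delay_ms: int = 6000
    response_ms: int = 3000
    jitter_ms: tuple[int, int] = (5000, 9000)
    silent_trial_ms: tuple[int, int] = (22800, 26800)

    def __post_init__(self) -> None:
        for v in (self.item_ms, self.isi_ms, self.delay_ms, self.response_ms):
            if v < 0:
                raise ValueError("durations must be non-negative")

    @property
    def soa_ms(self) -> int:
        return self.item_ms + self.isi_ms

    @classmethod
    def for_experiment(cls, experiment: str) -> "TrialTiming":
        if experiment == "exp1":
            return cls(silent_trial_ms=(22800, 26800))
        if experiment == "exp2":
            return cls(silent_trial_ms=(26400, 30400))
        raise ValueError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class EditRecord:
    """How S2 was derived from S1."""

    mode: str  # "same" | "exp1_new_item" | "exp2_adjacent_swap" | "perception"
    position: int | None = None  # 1-based changed/swap position
    old_item: int | None = None
    new_item: int | None = None
    last_two_same: bool | None = None  # perception task only


@dataclass(frozen=True)
class SequencePair:
    """A constrained S1/S2 pair with its condition labels."""

    s1: tuple[int, ...]
    s2: tuple[int, ...]
    material: str
    task: str  # "perception" | "memory"
    trial_type: str  # "same" | "different"
    memory_load: str | None  # "ML1".."ML3" or None (Experiment 1)
    edit: EditRecord

    def __post_init__(self) -> None:
        if len(self.s1) != len(self.s2):
            raise ValueError("S1 and S2 must have equal length")


# ---------------------------------------------------------------------------
# Sequence-level operations
# ---------------------------------------------------------------------------

def compute_contour(seq, inventory: ItemInventory | None = None) -> list[str]:
    """Up/down pattern of successive pitch intervals of a musical sequence.

    Element ``i`` is ``"up"`` iff the pitch rank rises from item ``i`` to
    ``i+1``. Adjacent equal items make the contour undefined and raise.
    """
    inventory = inventory or ItemInventory.musical()
    seq = list(seq)
    if len(seq) < 2:
        raise ValueError("contour requires at least 2 items")
    out = []
    for a, b in zip(seq, seq[1:]):
        ra, rb = inventory.rank(a), inventory.rank(b)
        if ra == rb:
            raise ValueError("contour undefined: adjacent equal items")
        out.append("up" if rb > ra else "down")
    return out


def _repeated_kgrams(seq: list[int], k: int) -> bool:
    grams = [tuple(seq[i:i + k]) for i in range(len(seq) - k + 1)]
    return len(grams) != len(set(grams))


def validate_sequence(seq, material: str, experiment: str) -> list[str]:
    """Check a sequence against the per-experiment construction rules.

    Returns a (possibly empty) list of human-readable violations.

    Experiment 1: all items distinct; musical sequences need at least one
    ascending and one descending interval. Experiment 2: the first item is
    never repeated; repeats need >= 2 intervening items; <= 3 occurrences per
    item; no repeated 3- or 4-item sub-patterns; musical contour rule as in
    Experiment 1.
    """
    seq = list(seq)
    if not seq:
        raise ValueError("empty sequence")
    if any((not isinstance(x, (int, np.integer))) or x < 0 or x > 5 for x in seq):
        raise ValueError("item indices must be integers in 0..5")
    violations: list[str] = []

    if experiment == "exp1":
        if len(set(seq)) != len(seq):
            violations.append("items not all distinct")
    elif experiment == "exp2":
        if seq[0] in seq[1:]:
            violations.append("first item repeated")
        for item in set(seq):
            pos = [i for i, x in enumerate(seq) if x == item]
            if len(pos) > 3:
                violations.append(f"item {item} occurs more than 3 times")
            for a, b in zip(pos, pos[1:]):
                if b - a < 3:
                    violations.append(
                        f"item {item} repeated with fewer than 2 items in between"
                    )
                    break
        for k in (3, 4):
            if len(seq) > k and _repeated_kgrams(seq, k):
                violations.append(f"repeated {k}-item pattern")
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    if material == "musical":
        try:
            contour = compute_contour(seq)
        except ValueError:
            violations.append("adjacent equal items (contour undefined)")
        else:
            if "up" not in contour:
                violations.append("no ascending interval")
            if "down" not in contour:
                violations.append("no descending interval")
    elif material != "verbal":
        raise ValueError(f"unknown material {material!r}")
    return violations


def derive_s2(s1, mode: str, material: str, position: int | None = None,
              rng: np.random.Generator | None = None):
    """Derive S2 from S1.

    ``mode="same"`` returns an identical copy. ``mode="exp1_new_item"``
    replaces the item at a 1-based interior ``position`` (2-4) with the item
    of the inventory unused by S1; for musical material the replacement must
    change the contour, otherwise an error with diagnostics is raised.
    ``mode="exp2_adjacent_swap"`` exchanges the items at ``position`` and
    ``position + 1`` (``position >= 2``: the first item never moves); for
    musical material the swap necessarily flips one interval, changing the
    contour.

    Returns ``(s2, EditRecord)``.
    """
    s1 = tuple(s1)
    if mode == "same":
        return s1, EditRecord(mode="same")

    if mode == "exp1_new_item":
        if position is None or position not in (2, 3, 4):
            raise ValueError("exp1 replacement position must be 2, 3 or 4")
        if len(set(s1)) != len(s1):
            raise ValueError("exp1 S1 must have all-distinct items")
        unused = [x for x in range(6) if x not in s1]
        idx = position - 1
        candidates = list(unused)
        if material == "musical":
            c1 = compute_contour(s1)
            candidates = []
            for cand in unused:
                s2 = s1[:idx] + (cand,) + s1[idx + 1:]
                try:
                    c2 = compute_contour(s2)
                except ValueError:
                    continue
                if c2 != c1:
                    candidates.append(cand)
            if not candidates:
                raise ValueError(
                    f"no contour-changing replacement at position {position} "
                    f"for S1={s1} (unused items: {unused})"
                )
        if not candidates:
            raise ValueError(f"no replacement item available for S1={s1}")
        rng = rng or np.random.default_rng()
        new = int(candidates[rng.integers(len(candidates))])
        s2 = s1[:idx] + (new,) + s1[idx + 1:]
        return s2, EditRecord(mode=mode, position=position,
                              old_item=s1[idx], new_item=new)

    if mode == "exp2_adjacent_swap":
        if position is None or position < 2 or position >= len(s1):
            raise ValueError(
                "swap position must satisfy 2 <= position <= len(s1) - 1 "
                "(the first item cannot be moved)"
            )
        i = position - 1
        s2 = list(s1)
        s2[i], s2[i + 1] = s2[i + 1], s2[i]
        return tuple(s2), EditRecord(mode=mode, position=position,
                                     old_item=s1[i], new_item=s1[i + 1])

    raise ValueError(f"unknown derivation mode {mode!r}")


def _random_valid_sequence(material: str, n_items: int, experiment: str,
                           rng: np.random.Generator, max_tries: int = 10000,
                           predicate=None) -> tuple[int, ...]:
    for _ in range(max_tries):
        if experiment == "exp1":
            seq = tuple(int(x) for x in rng.permutation(6)[:n_items])
        else:
            seq = tuple(int(rng.integers(6)) for _ in range(n_items))
        if validate_sequence(seq, material, experiment):
            continue
        if predicate is not None and not predicate(seq):
            continue
        return seq
    raise RuntimeError(
        f"could not draw a valid {material} {experiment} sequence of "
        f"length {n_items} in {max_tries} tries"
    )


def make_perception_s2(material: str, rng: np.random.Generator,
                       n_items: int = 5, last_two_same: bool | None = None):
    """Build a perception-task S2 with a controlled final item pair.

    Half of the perception pool has identical last two items, half has
    different ones; for musical material a different final pair may not span
    more than three pitch ranks. Apart from an identical final pair, all
    items are distinct; musical sequences keep at least one ascending and
    one descending interval unless the final pair is identical.

    Returns ``(s2, EditRecord(last_two_same=...))``.
    """
    if last_two_same is None:
        last_two_same = bool(rng.integers(2))
    inv = ItemInventory.for_material(material)
    for _ in range(10000):
        if last_two_same:
            head = tuple(int(x) for x in rng.permutation(6)[:n_items - 1])
            seq = head + (head[-1],)
            if material == "musical" and len(head) >= 2:
                # contour rule checked on the distinct head only
                contour = compute_contour(head)
                if "up" not in contour or "down" not in contour:
                    continue
        else:
            seq = tuple(int(x) for x in rng.permutation(6)[:n_items])
            if validate_sequence(seq, material, "exp1"):
                continue
            if material == "musical" and abs(inv.rank(seq[-1]) - inv.rank(seq[-2])) > 3:
                continue
        return seq, EditRecord(mode="perception", last_two_same=last_two_same)
    raise RuntimeError("could not build a perception S2")


def sequence_duration(n_items: int, timing: TrialTiming) -> int:
    """Duration of one n-item sequence in ms: n*SOA - ISI."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return n_items * timing.soa_ms - timing.isi_ms


def trial_duration(n_items: int, timing: TrialTiming) -> int:
    """S1-delay-S2 duration in ms: 2*(n*SOA - ISI) + delay.

    Five 600-ms-SOA items and a 6 s delay give 11800 ms.
    """
    return 2 * sequence_duration(n_items, timing) + timing.delay_ms


# ---------------------------------------------------------------------------
# Pools of sequence pairs
# ---------------------------------------------------------------------------

def _assign_balanced(options: list[int], n: int, rng: np.random.Generator) -> list[int]:
    """n draws over options, as equiprobable as possible; remainder random."""
    base, rem = divmod(n, len(options))
    out = options * base + list(rng.choice(options, size=rem, replace=False))
    rng.shuffle(out)
    return out


def build_condition_pool(material: str, task: str, experiment: str,
                         rng: np.random.Generator,
                         memory_load: str | None = None) -> list[SequencePair]:
    """Build the 12-pair pool for one condition cell (6 same + 6 different).

    Memory pools derive S2 by new-item replacement (Experiment 1) or
    adjacent swap (Experiment 2, change positions balanced over admissible
    swap indices). Perception pools (Experiment 1 only) split 6/6 by
    last-two-items status, with S1 always different from S2.
    """
    pairs: list[SequencePair] = []
    if task == "perception":
        if experiment != "exp1":
            raise ValueError("perception task exists only in Experiment 1")
        for last_same in [True] * 6 + [False] * 6:
            s1 = _random_valid_sequence(material, 5, "exp1", rng)
            s2, edit = make_perception_s2(material, rng, 5, last_two_same=last_same)
            pairs.append(SequencePair(s1, s2, material, "perception",
                                      "same" if last_same else "different",
                                      None, edit))
        return pairs

    if experiment == "exp1":
        n_items = 5
        positions = _assign_balanced([2, 3, 4], 6, rng)
        for trial_type, pos in [("same", None)] * 6 + list(
                zip(["different"] * 6, positions)):
            if trial_type == "same":
                s1 = _random_valid_sequence(material, n_items, "exp1", rng)
                s2, edit = derive_s2(s1, "same", material)
            else:
                # retry S1 until a contour-changing replacement exists there
                for _ in range(10000):
                    s1 = _random_valid_sequence(material, n_items, "exp1", rng)
                    try:
                        s2, edit = derive_s2(s1, "exp1_new_item", material,
                                             position=pos, rng=rng)
                        break
                    except ValueError:
                        continue
                else:
                    raise RuntimeError("no S1 admits a contour change")
            pairs.append(SequencePair(s1, s2, material, "memory", trial_type,
                                      None, edit))
        return pairs

    # Experiment 2 memory pools
    if memory_load is None:
        raise ValueError("Experiment 2 pools require a memory_load")
    n_items = ML_LENGTHS[(memory_load, material)]
    swap_positions = _assign_balanced(list(range(2, n_items)), 6, rng)
    for trial_type, pos in [("same", None)] * 6 + list(
            zip(["different"] * 6, swap_positions)):
        s1 = _random_valid_sequence(material, n_items, "exp2", rng)
        if trial_type == "same":
            s2, edit = derive_s2(s1, "same", material)
        else:
            s2, edit = derive_s2(s1, "exp2_adjacent_swap", material, position=pos)
        pairs.append(SequencePair(s1, s2, material, "memory", trial_type,
                                  memory_load, edit))
    return pairs


# ---------------------------------------------------------------------------
# Block scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialEntry:
    """One scheduled slot: a stimulation trial or a silent baseline trial.

    Onsets are in ms from block start. Silent entries carry only
    ``onset_ms`` and ``duration_ms``.
    """

    slot: int  # 1-based position in the block
    kind: str  # "stimulation" | "silent"
    pair: SequencePair | None
    onset_ms: float
    delay_onset_ms: float | None
    s2_onset_ms: float | None
    response_onset_ms: float | None
    response_end_ms: float | None
    duration_ms: float


@dataclass(frozen=True)
class BlockSchedule:
    """An ordered, timed 16-slot block (12 stimulation + 4 silent trials)."""

    entries: tuple[TrialEntry, ...]
    block_id: str
    duration_ms: float

    @property
    def stimulation_entries(self) -> list[TrialEntry]:
        return [e for e in self.entries if e.kind == "stimulation"]


def _max_run(labels: list) -> int:
    best = run = 0
    prev = object()
    for x in labels:
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def _order_ok(pairs: list[SequencePair]) -> bool:
    if _max_run([p.trial_type for p in pairs]) > 3:
        return False
    loads = [p.memory_load for p in pairs]
    if len(set(loads)) > 1 and _max_run(loads) > 3:
        return False
    materials = [p.material for p in pairs]
    if len(set(materials)) > 1 and _max_run(materials) > 4:
        return False
    return True


def schedule_block(pairs: list[SequencePair], timing: TrialTiming,
                   rng: np.random.Generator,
                   silent_positions: tuple[int, ...] = (1, 6, 11, 16),
                   block_id: str = "block", max_retries: int = 10000) -> BlockSchedule:
    """Order 12 stimulation pairs into a 16-slot block and assign onsets.

    Silent trials occupy the configured 1-based slot positions; stimulation
    order is rejection-sampled until no more than 3 consecutive same (or
    different) trials occur (Experiment 2 pools additionally: <= 3
    consecutive of one memory load, <= 4 consecutive of one material).
    Inter-trial jitter is drawn uniformly; onsets are strictly increasing.
    """
    if len(pairs) != 16 - len(silent_positions):
        raise ValueError(
            f"expected {16 - len(silent_positions)} stimulation pairs, got {len(pairs)}"
        )
    order = None
    for _ in range(max_retries):
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        if _order_ok(perm):
            order = perm
            break
    if order is None:
        raise RuntimeError(
            f"could not satisfy ordering constraints in {max_retries} retries "
            f"(block {block_id!r}); re-seed and retry"
        )

    entries: list[TrialEntry] = []
    t = 0.0
    it = iter(order)
    for slot in range(1, 17):
        if slot in silent_positions:
            dur = float(rng.integers(timing.silent_trial_ms[0],
                                     timing.silent_trial_ms[1] + 1))
            entries.append(TrialEntry(slot, "silent", None, t, None, None,
                                      None, None, dur))
            t += dur
        else:
            pair = next(it)
            n = len(pair.s1)
            seq_ms = sequence_duration(n, timing)
            delay_onset = t + seq_ms
            s2_onset = delay_onset + timing.delay_ms
            resp_onset = s2_onset + seq_ms
            resp_end = resp_onset + timing.response_ms
            jitter = float(rng.integers(timing.jitter_ms[0],
                                        timing.jitter_ms[1] + 1))
            dur = (resp_end - t) + jitter
            entries.append(TrialEntry(slot, "stimulation", pair, t, delay_onset,
                                      s2_onset, resp_onset, resp_end, dur))
            t += dur
    return BlockSchedule(tuple(entries), block_id, t)


# ---------------------------------------------------------------------------
# Counterbalancing and experiment plans
# ---------------------------------------------------------------------------

def latin_square_carryover(n: int) -> np.ndarray:
    """Williams Latin square balanced for first-order carryover effects.

    For even ``n`` returns an ``n x n`` square in which every ordered pair of
    distinct conditions is adjacent equally often across rows. For odd ``n``
    the Williams construction needs the square plus its mirror, so a
    ``2n x n`` matrix is returned; each block of ``n`` rows is a Latin
    square and the pair achieves carryover balance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[0]])
    # Williams first row: 0, 1, n-1, 2, n-2, 3, ... (interleaved ends)
    base = [0, 1]
    lo, hi = 1, n - 1
    while len(base) < n:
        base.append(hi)
        hi -= 1
        if len(base) < n:
            lo += 1
            base.append(lo)
    base = np.array(base)
    square = (base[None, :] + np.arange(n)[:, None]) % n
    if n % 2 == 0:
        return square
    return np.vstack([square, square[:, ::-1]])


@dataclass(frozen=True)
class ExperimentPlan:
    """Blocks, per-participant block orders and the conditions of a study."""

    experiment: str
    n_participants: int
    block_orders: np.ndarray  # (participant, block_index_in_sequence) -> block idx
    blocks: tuple[BlockSchedule, ...]
    timing: TrialTiming
    seed: int

    def participant_blocks(self, participant: int) -> list[BlockSchedule]:
        return [self.blocks[j] for j in self.block_orders[participant]]


EXP1_BLOCKS = [("memory", "musical"), ("memory", "verbal"),
               ("perception", "musical"), ("perception", "verbal")]


def build_experiment_plan(experiment: str, n_participants: int,
                          seed: int) -> ExperimentPlan:
    """Generate the full design of one experiment.

    Experiment 1: four single-condition blocks (task x material), one
    12-pair pool each. Experiment 2: six mixed blocks, each containing one
    trial from each of the 12 (load x material x trial-type) cells.
    Block orders follow the carryover-balanced Latin square, rows cycled
    over participants.
    """
    rng = np.random.default_rng(seed)
    timing = TrialTiming.for_experiment(experiment)
    blocks: list[BlockSchedule] = []
    if experiment == "exp1":
        for task, material in EXP1_BLOCKS:
            pool = build_condition_pool(material, task, "exp1", rng)
            blocks.append(schedule_block(pool, timing, rng,
                                         block_id=f"{task}-{material}"))
    elif experiment == "exp2":
        # one 12-pair pool per (load, material) cell; block b takes pair b of
        # each cell, so every block holds one trial per condition cell
        cell_pools = {}
        for load in ("ML1", "ML2", "ML3"):
            for material in ("musical", "verbal"):
                pool = build_condition_pool(material, "memory", "exp2", rng,
                                            memory_load=load)
                same = [p for p in pool if p.trial_type == "same"]
                diff = [p for p in pool if p.trial_type == "different"]
                cell_pools[(load, material)] = (same, diff)
        for b in range(6):
            pairs = []
            for (load, material), (same, diff) in cell_pools.items():
                pairs.append(same[b])
                pairs.append(diff[b])
            blocks.append(schedule_block(pairs, timing, rng, block_id=f"block{b + 1}"))
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    n_blocks = len(blocks)
    square = latin_square_carryover(n_blocks)
    orders = np.array([square[p % square.shape[0]] for p in range(n_participants)])
    return ExperimentPlan(experiment, n_participants, orders, tuple(blocks),
                          timing, seed)


# ---------------------------------------------------------------------------
# Events export
# ---------------------------------------------------------------------------

def condition_label(pair: SequencePair, experiment: str) -> str:
    """GLM condition label: task:material (Exp 1) or load:material (Exp 2)."""
    if experiment == "exp1":
        return f"{pair.task}:{pair.material}"
    return f"{pair.memory_load}:{pair.material}"


def session_events(blocks: list[BlockSchedule],
                   experiment: str,
                   block_gap_ms: float = 0.0) -> pd.DataFrame:
    """Concatenate blocks into one session-level events table.

    One row per phase (S1 / delay / S2 / response) of each stimulation trial
    plus one row per silent trial, with onsets and durations in seconds
    (BIDS-events-like dialect). Also includes a ``block_onset``/
    ``block_duration`` pair of columns for GLM block regressors.
    """
    rows = []
    t0 = 0.0
    for blk in blocks:
        for e in blk.entries:
            common = dict(block=blk.block_id, slot=e.slot,
                          block_onset=t0 / 1000.0,
                          block_duration=blk.duration_ms / 1000.0)
            if e.kind == "silent":
                rows.append(dict(onset=(t0 + e.onset_ms) / 1000.0,
                                 duration=e.duration_ms / 1000.0,
                                 phase="silent", trial_type="silent", task="",
                                 material="", memory_load="", condition="",
                                 **common))
                continue
            p = e.pair
            cond = condition_label(p, experiment)
            seq_s = (e.delay_onset_ms - e.onset_ms) / 1000.0
            lab = dict(trial_type=p.trial_type, task=p.task, material=p.material,
                       memory_load=p.memory_load or "", condition=cond, **common)
            rows.append(dict(onset=(t0 + e.onset_ms) / 1000.0, duration=seq_s,
                             phase="S1", **lab))
            rows.append(dict(onset=(t0 + e.delay_onset_ms) / 1000.0,
                             duration=(e.s2_onset_ms - e.delay_onset_ms) / 1000.0,
                             phase="delay", **lab))
            rows.append(dict(onset=(t0 + e.s2_onset_ms) / 1000.0, duration=seq_s,
                             phase="S2", **lab))
            rows.append(dict(onset=(t0 + e.response_onset_ms) / 1000.0,
                             duration=(e.response_end_ms - e.response_onset_ms) / 1000.0,
                             phase="response", **lab))
        t0 += blk.duration_ms + block_gap_ms
    df = pd.DataFrame(rows)
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)
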