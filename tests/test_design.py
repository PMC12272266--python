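"""Sequence constraints, S2 derivations, schedules and counterbalancing."""

import itertools

import numpy as np
import pytest

from nirsdmst import design as dz

TONE = {name: i for i, name in enumerate(dz.MUSICAL_ITEMS)}


def seq(*names):
    return [TONE[n] for n in names]


# ---------------------------------------------------------------------------
# Contour
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("items, expected", [
    (("E2", "C2", "B2", "G2", "F3"), ["down", "up", "down", "up"]),
    (("E2", "C2", "B2", "D3", "F3"), ["down", "up", "up", "up"]),
    (("C2", "E2"), ["up"]),
])
def test_contour_examples(items, expected):
    assert dz.compute_contour(seq(*items)) == expected


def test_contour_rejects_adjacent_repeats_and_singletons():
    with pytest.raises(ValueError):
        dz.compute_contour([0, 0, 1])
    with pytest.raises(ValueError):
        dz.compute_contour([2])


# ---------------------------------------------------------------------------
# Sequence validation
# ---------------------------------------------------------------------------

def brute_force_valid_exp1(s, material):
    """Independent re-statement of the Experiment-1 rules."""
    if len(set(s)) != len(s):
        return False
    if material == "musical":
        ups = [b > a for a, b in zip(s, s[1:])]
        if all(ups) or not any(ups):
            return False
    return True


def test_validator_agrees_with_brute_force_on_all_5_permutations():
    n_valid = 0
    for perm in itertools.permutations(range(6), 5):
        ok = not dz.validate_sequence(list(perm), "musical", "exp1")
        assert ok == brute_force_valid_exp1(perm, "musical")
        n_valid += ok
    # 720 orderings minus the 12 monotone ones
    assert n_valid == 708


def test_monotone_musical_sequence_flagged():
    v = dz.validate_sequence(seq("C2", "E2", "G2", "B2", "D3"),
                             "musical", "exp1")
    assert any("descending" in x for x in v)


@pytest.mark.parametrize("s, fragment", [
    ([0, 1, 2, 0, 3], "first item"),           # first item repeated
    ([1, 2, 3, 2, 4, 5], "in between"),        # repeat spaced < 2 items
    ([1, 2, 3, 4, 2, 3, 4, 5], "pattern"),     # repeated 3-gram
])
def test_exp2_rule_violations(s, fragment):
    v = dz.validate_sequence(s, "verbal", "exp2")
    assert any(fragment in x for x in v), v


def test_validator_rejects_unknown_items():
    with pytest.raises(ValueError):
        dz.validate_sequence([0, 9], "verbal", "exp1")


# ---------------------------------------------------------------------------
# S2 derivation
# ---------------------------------------------------------------------------

def test_derive_same_is_identity():
    s1 = tuple(seq("E2", "C2", "B2", "G2", "F3"))
    s2, edit = dz.derive_s2(s1, "same", "musical")
    assert s2 == s1 and edit.mode == "same"


def test_exp1_new_item_example_changes_contour():
    s1 = seq("E2", "C2", "B2", "G2", "F3")
    s2, edit = dz.derive_s2(s1, "exp1_new_item", "musical", position=4,
                            rng=np.random.default_rng(0))
    # D3 is the only unused tone; it must land at position 4
    assert s2 == tuple(seq("E2", "C2", "B2", "D3", "F3"))
    assert edit.old_item == TONE["G2"] and edit.new_item == TONE["D3"]
    assert dz.compute_contour(s1) != dz.compute_contour(s2)


def test_exp2_swap_example_and_contour_change():
    s1 = seq("E2", "C2", "B2", "G2")
    s2, edit = dz.derive_s2(s1, "exp2_adjacent_swap", "musical", position=2)
    assert s2 == tuple(seq("E2", "B2", "C2", "G2"))
    assert dz.compute_contour(s1) != dz.compute_contour(s2)


def test_swap_at_first_position_is_an_error():
    with pytest.raises(ValueError):
        dz.derive_s2(seq("E2", "C2", "B2"), "exp2_adjacent_swap", "musical",
                     position=1)


def test_exp1_position_out_of_range_is_an_error():
    with pytest.raises(ValueError):
        dz.derive_s2(seq("E2", "C2", "B2", "G2", "F3"), "exp1_new_item",
                     "musical", position=5)


# ---------------------------------------------------------------------------
# Perception S2
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("material", ["musical", "verbal"])
def test_perception_s2_final_pair_contract(material):
    rng = np.random.default_rng(3)
    for last_same in (True, False):
        for _ in range(20):
            s2, edit = dz.make_perception_s2(material, rng,
                                             last_two_same=last_same)
            assert (s2[-1] == s2[-2]) == last_same
            if material == "musical" and not last_same:
                assert abs(s2[-1] - s2[-2]) <= 3


def test_perception_pool_splits_six_six():
    rng = np.random.default_rng(4)
    pool = dz.build_condition_pool("musical", "perception", "exp1", rng)
    assert len(pool) == 12
    same = [p for p in pool if p.edit.last_two_same]
    assert len(same) == 6


# ---------------------------------------------------------------------------
# Trial durations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, expected", [(4, 10600), (5, 11800), (6, 13000),
                                         (7, 14200), (8, 15400)])
def test_trial_durations(n, expected):
    assert dz.trial_duration(n, dz.TrialTiming()) == expected


def test_trial_duration_degenerate_and_errors():
    t = dz.TrialTiming(delay_ms=0)
    assert dz.trial_duration(1, t) == 1000
    with pytest.raises(ValueError):
        dz.trial_duration(0, dz.TrialTiming())


# ---------------------------------------------------------------------------
# Memory pools: composition and contour invariant
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("experiment, load", [("exp1", None), ("exp2", "ML1"),
                                              ("exp2", "ML3")])
def test_musical_pool_composition_and_contour_change(experiment, load):
    rng = np.random.default_rng(5)
    pool = dz.build_condition_pool("musical", "memory", experiment, rng,
                                   memory_load=load)
    assert len(pool) == 12
    same = [p for p in pool if p.trial_type == "same"]
    diff = [p for p in pool if p.trial_type == "different"]
    assert len(same) == 6 and len(diff) == 6
    for p in same:
        assert p.s2 == p.s1
    for p in diff:
        assert dz.compute_contour(p.s1) != dz.compute_contour(p.s2)
        assert not dz.validate_sequence(p.s1, "musical", experiment)


# ---------------------------------------------------------------------------
# Block scheduling
# ---------------------------------------------------------------------------

def test_block_structure_and_silent_positions():
    rng = np.random.default_rng(6)
    pool = dz.build_condition_pool("verbal", "memory", "exp1", rng)
    blk = dz.schedule_block(pool, dz.TrialTiming(), rng)
    assert len(blk.entries) == 16
    silent = [e.slot for e in blk.entries if e.kind == "silent"]
    assert silent == [1, 6, 11, 16]
    assert len(blk.stimulation_entries) == 12


@pytest.mark.parametrize("seed", range(100))
def test_schedule_constraints_hold_for_any_seed(seed):
    rng = np.random.default_rng(seed)
    pools = []
    for load in ("ML1", "ML2", "ML3"):
        for mat in ("musical", "verbal"):
            pool = dz.build_condition_pool(mat, "memory", "exp2", rng,
                                           memory_load=load)
            pools.append((pool[0], pool[6]))  # one same + one different
    pairs = [p for pair in pools for p in pair]
    blk = dz.schedule_block(pairs, dz.TrialTiming.for_experiment("exp2"), rng)
    onsets = [e.onset_ms for e in blk.entries]
    assert onsets == sorted(onsets) and len(set(onsets)) == 16
    stim = [e.pair for e in blk.stimulation_entries]

    def max_run(labels):
        best = run = 0
        prev = object()
        for x in labels:
            run = run + 1 if x == prev else 1
            prev = x
            best = max(best, run)
        return best

    assert max_run([p.trial_type for p in stim]) <= 3
    assert max_run([p.memory_load for p in stim]) <= 3
    assert max_run([p.material for p in stim]) <= 4


def test_zero_jitter_block_duration_is_closed_form():
    rng = np.random.default_rng(7)
    pool = dz.build_condition_pool("verbal", "memory", "exp1", rng)
    timing = dz.TrialTiming(jitter_ms=(5000, 5000),
                            silent_trial_ms=(22800, 22800))
    blk = dz.schedule_block(pool, timing, rng)
    expected = 12 * (dz.trial_duration(5, timing) + 3000 + 5000) + 4 * 22800
    assert blk.duration_ms == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Latin squares
# ---------------------------------------------------------------------------

def test_latin_square_trivial_case():
    assert dz.latin_square_carryover(1).tolist() == [[0]]


@pytest.mark.parametrize("n", [2, 4, 6])
def test_even_williams_square_properties(n):
    sq = dz.latin_square_carryover(n)
    assert sq.shape == (n, n)
    for row in sq:
        assert sorted(row) == list(range(n))
    for col in sq.T:
        assert sorted(col) == list(range(n))
    tally = {}
    for row in sq:
        for a, b in zip(row, row[1:]):
            tally[(a, b)] = tally.get((a, b), 0) + 1
    assert set(tally.values()) == {1}
    assert len(tally) == n * (n - 1)


def test_odd_williams_needs_mirrored_pair():
    sq = dz.latin_square_carryover(5)
    assert sq.shape == (10, 5)
    tally = {}
    for row in sq:
        for a, b in zip(row, row[1:]):
            tally[(a, b)] = tally.get((a, b), 0) + 1
    assert set(tally.values()) == {2}


# ---------------------------------------------------------------------------
# Experiment plans and events
# ---------------------------------------------------------------------------

def test_exp1_plan_blocks_and_orders(exp1_plan):
    assert len(exp1_plan.blocks) == 4
    for row in exp1_plan.block_orders:
        assert sorted(row) == [0, 1, 2, 3]


def test_exp2_blocks_cover_every_condition_cell(exp2_plan):
    assert len(exp2_plan.blocks) == 6
    for blk in exp2_plan.blocks:
        cells = {(e.pair.memory_load, e.pair.material, e.pair.trial_type)
                 for e in blk.stimulation_entries}
        assert len(cells) == 12


def test_session_events_are_sorted_and_phased(exp1_events):
    assert (exp1_events.onset.diff().dropna() >= 0).all()
    stim = exp1_events[exp1_events.phase != "silent"]
    assert set(stim.phase) == {"S1", "delay", "S2", "response"}
    assert (exp1_events[exp1_events.phase == "silent"].shape[0] == 16)
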