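"""Assignment: match classification, frame alignment, nearest item,
observed distributions and chance levels."""

from fractions import Fraction

import numpy as np
import pytest

from gazeprime import assign, gazesim, stimulus
from gazeprime.assign import (
    CATEGORIES,
    MatchCategory,
    chance_levels,
    classify_match,
    expected_chance,
    expected_chance_exact,
    first_sample_per_frame,
    nearest_item,
    nth_fixation_categories,
    samples_per_frame,
    trial_distribution,
)
from gazeprime.events import FixationEvent
from gazeprime.gazesim import GazeStream
from gazeprime.stimulus import (
    ALL_ITEM_TYPES,
    Color,
    ItemType,
    Shape,
    Trajectories,
    TrialSpec,
    sample_composition,
)

from conftest import BLUE_CIRCLE, make_trial


@pytest.mark.parametrize(
    "item,expected",
    [
        (ItemType(Color.BLUE, Shape.CIRCLE), MatchCategory.FULL),
        (ItemType(Color.BLUE, Shape.PLUS), MatchCategory.COLOR),
        (ItemType(Color.GREEN, Shape.CIRCLE), MatchCategory.SHAPE),
        (ItemType(Color.RED, Shape.PLUS), MatchCategory.NONE),
    ],
)
def test_classify_match_examples(item, expected):
    assert classify_match(BLUE_CIRCLE, item) is expected


def test_classification_partitions_the_taxonomy():
    """For every prime, the 9 types split 1 full / 2 color / 2 shape / 4 none."""
    for prime in ALL_ITEM_TYPES:
        counts = {c: 0 for c in CATEGORIES}
        for item in ALL_ITEM_TYPES:
            counts[classify_match(prime, item)] += 1
        assert [counts[c] for c in CATEGORIES] == [1, 2, 2, 4]


def _dense_stream(n_ms=3000):
    t = np.arange(n_ms, dtype=float)
    return GazeStream(t=t, x=np.zeros(n_ms), y=np.zeros(n_ms),
                      valid=np.ones(n_ms, dtype=bool))


def _spec(n_frames=180, seed=0, present=True):
    rng = np.random.default_rng(seed)
    comp = sample_composition(BLUE_CIRCLE, present, rng)
    return TrialSpec(0, 0, BLUE_CIRCLE, comp, n_frames=n_frames, rng_seed=seed)


def test_sixteen_whole_samples_fit_per_frame():
    assert samples_per_frame(1000.0, 60.0) == 16
    # every 1/60 s window of a 1000 Hz stream holds 16 or 17 integer-ms
    # samples, never fewer than 16
    edges = np.arange(181) * 1000.0 / 60.0
    counts = [
        np.sum((np.arange(3000) >= lo) & (np.arange(3000) < hi))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    assert min(counts) == 16 and max(counts) == 17


def test_first_sample_per_frame_dense_stream():
    spec = _spec()
    idx = first_sample_per_frame(_dense_stream(), spec)
    assert idx.size == 180 and np.all(idx >= 0)
    # the selected sample is the first at or after the window start
    edges = np.arange(180) * 1000.0 / 60.0
    np.testing.assert_array_equal(idx, np.ceil(edges).astype(int))


def test_missing_frame_is_omitted():
    spec = _spec()
    stream = _dense_stream()
    lo, hi = int(np.ceil(10 * 1000 / 60)), int(np.ceil(11 * 1000 / 60))
    stream.valid[lo:hi] = False
    idx = first_sample_per_frame(stream, spec)
    assert idx[10] == -1
    assert np.sum(idx >= 0) == 179


def _static_traj(centers, item_types, n_frames=6):
    pos = np.repeat(np.asarray(centers, dtype=float)[:, None, :], n_frames, axis=1)
    return Trajectories(positions=pos, item_types=tuple(item_types), speed=0.0)


def test_nearest_item_center_and_tiebreak():
    spec, traj, _ = make_trial(seed=1)
    assert nearest_item(traj.positions[5, 17], traj, 17) == 5
    # equidistant point between items 3 and 7 resolves to the lower id
    centers = np.zeros((12, 2))
    centers[3] = (1.0, 0.0)
    centers[7] = (-1.0, 0.0)
    centers[np.arange(12)[np.r_[0:3, 4:7, 8:12]]] = 50.0
    traj2 = _static_traj(centers, [ALL_ITEM_TYPES[0]] * 12)
    assert nearest_item((0.0, 0.0), traj2, 0) == 3


def test_nearest_item_agrees_with_bruteforce_scan(rng):
    spec, traj, _ = make_trial(seed=2)
    for _ in range(1000):
        frame = int(rng.integers(traj.n_frames))
        pt = rng.uniform(-13, 13, size=2)
        best, best_d = None, np.inf
        for i in range(traj.n_items):
            d = float(np.hypot(*(traj.positions[i, frame] - pt)))
            if d < best_d:
                best, best_d = i, d
        assert nearest_item(pt, traj, frame) == best


def test_distribution_gaze_glued_to_full_match_item():
    bias = gazesim.BiasParams(noise_sd=0.0, jitter_sd=0.0, pursuit_gain=1.0,
                              p_center_first=0.0, w_full=1e12,
                              fix_dur_mean=1e6)
    spec, traj, stream = make_trial(seed=3, bias=bias, prime_present=True)
    dist = trial_distribution(spec, traj, stream=stream, basis="samples")
    np.testing.assert_allclose(dist.proportions, [1.0, 0.0, 0.0, 0.0])
    assert dist.frames_used == 180


def test_distribution_hand_counted_fixture():
    """Six frames whose nearest items are FULL, FULL, COLOR, NONE, NONE,
    NONE -> proportions (1/3, 1/6, 0, 1/2)."""
    types = [
        ItemType(Color.BLUE, Shape.CIRCLE),   # FULL
        ItemType(Color.BLUE, Shape.PLUS),     # COLOR
        ItemType(Color.RED, Shape.PLUS),      # NONE
    ] * 4
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [8.0, 0.0]] * 4)
    centers[3:, :] += [[0.0, 50.0]] * 9  # park the other copies far away
    traj = _static_traj(centers, types, n_frames=6)
    comp = stimulus.DisplayComposition(
        types=tuple(sorted(set(types) | {
            ItemType(Color.GREEN, Shape.SQUARE),
            ItemType(Color.GREEN, Shape.CIRCLE),
            ItemType(Color.RED, Shape.SQUARE),
        })),
        prime=BLUE_CIRCLE, prime_present=True,
    )
    spec = TrialSpec(0, 0, BLUE_CIRCLE, comp, n_frames=6)
    # one sample per ms over 100 ms; x follows the frame schedule
    per_frame_x = [0.0, 0.0, 4.0, 8.0, 8.0, 8.0]
    t = np.arange(100, dtype=float)
    frames = np.minimum((t * 60 / 1000).astype(int), 5)
    stream = GazeStream(
        t=t, x=np.array([per_frame_x[f] for f in frames]), y=np.zeros(100),
        valid=np.ones(100, dtype=bool),
    )
    dist = trial_distribution(spec, traj, stream=stream, basis="samples")
    np.testing.assert_allclose(dist.proportions, [2 / 6, 1 / 6, 0.0, 3 / 6])


def test_all_invalid_trial_is_flagged_excluded():
    spec = _spec()
    stream = _dense_stream()
    stream.valid[:] = False
    dist = trial_distribution(spec, traj=make_trial(seed=0)[1], stream=stream,
                              basis="samples")
    assert dist.excluded and dist.frames_used == 0
    assert np.all(np.isnan(dist.proportions))


def test_chance_levels_worked_example(example_composition):
    """The example display (blue-circle prime among green circle, blue
    circle, blue square, red plus, green plus, blue plus) has chance levels
    2/12, 4/12, 2/12, 4/12."""
    cha = chance_levels(example_composition)
    np.testing.assert_allclose(
        cha.proportions, [2 / 12, 4 / 12, 2 / 12, 4 / 12]
    )


def test_chance_levels_sum_to_one_in_steps_of_two_twelfths(rng):
    for present in (True, False):
        for _ in range(50):
            comp = sample_composition(BLUE_CIRCLE, present, rng)
            p = chance_levels(comp).proportions
            assert abs(p.sum() - 1.0) < 1e-12
            np.testing.assert_allclose(p * 12 % 2, 0.0, atol=1e-9)
            # only 4 no-match types exist, so no-match chance caps at 8/12
            assert p[3] <= 8 / 12 + 1e-12


def test_expected_chance_matches_closed_forms_exactly():
    present = expected_chance_exact(True)
    assert [present[c] for c in CATEGORIES] == [
        Fraction(1, 6), Fraction(5, 24), Fraction(5, 24), Fraction(5, 12)
    ]
    absent = expected_chance_exact(False)
    assert [absent[c] for c in CATEGORIES] == [
        Fraction(0), Fraction(1, 4), Fraction(1, 4), Fraction(1, 2)
    ]
    np.testing.assert_allclose(
        expected_chance(True).proportions, [1 / 6, 5 / 24, 5 / 24, 5 / 12],
        atol=1e-12,
    )


def test_expected_chance_matches_composition_montecarlo(rng):
    """Mean chance over 100,000 sampled compositions sits within 3 standard
    errors of the enumeration expectation."""
    n = 100_000
    for present in (True, False):
        target = expected_chance(present).proportions
        acc = np.zeros(4)
        acc2 = np.zeros(4)
        for _ in range(n):
            comp = sample_composition(BLUE_CIRCLE, present, rng)
            p = chance_levels(comp).proportions
            acc += p
            acc2 += p * p
        mean = acc / n
        se = np.sqrt(np.maximum(acc2 / n - mean**2, 0.0) / n)
        assert np.all(np.abs(mean - target) <= 3 * se + 1e-12)


def test_nth_fixation_majority_vote():
    types = [
        ItemType(Color.RED, Shape.PLUS),    # NONE
        ItemType(Color.BLUE, Shape.PLUS),   # COLOR
    ] + [ItemType(Color.GREEN, Shape.SQUARE)] * 10
    # item 0 nearest on frame 0; item 1 nearest on frames 1-2
    pos = np.zeros((12, 3, 2))
    pos[0, 0] = (0.0, 0.0)
    pos[0, 1] = pos[0, 2] = (9.0, 0.0)
    pos[1, 0] = (5.0, 0.0)
    pos[1, 1] = pos[1, 2] = (0.5, 0.0)
    pos[2:, :, :] = 50.0
    traj = Trajectories(positions=pos, item_types=tuple(types), speed=0.0)
    comp_types = tuple(sorted(set(types) | {
        BLUE_CIRCLE, ItemType(Color.RED, Shape.CIRCLE),
        ItemType(Color.GREEN, Shape.CIRCLE), ItemType(Color.RED, Shape.SQUARE),
    }))[:6]
    spec = TrialSpec(
        0, 0, BLUE_CIRCLE,
        stimulus.DisplayComposition(comp_types, BLUE_CIRCLE, BLUE_CIRCLE in comp_types),
        n_frames=3,
    )
    fx = [FixationEvent(0.0, 50.0, 0.0, 0.0)]
    cats = nth_fixation_categories(spec, fx, traj, n_max=4)
    assert cats == [MatchCategory.COLOR]


def test_nth_fixation_tie_breaks_to_earliest_frame_item():
    types = [ItemType(Color.BLUE, Shape.CIRCLE),
             ItemType(Color.RED, Shape.PLUS)] + [ItemType(Color.GREEN, Shape.SQUARE)] * 10
    pos = np.zeros((12, 2, 2))
    pos[0, 0] = (0.0, 0.0)   # nearest on frame 0
    pos[0, 1] = (9.0, 0.0)
    pos[1, 0] = (5.0, 0.0)
    pos[1, 1] = (0.5, 0.0)   # nearest on frame 1 -> 1-1 tie
    pos[2:, :, :] = 50.0
    traj = Trajectories(positions=pos, item_types=tuple(types), speed=0.0)
    comp_types = tuple(sorted(set(types) | {
        ItemType(Color.RED, Shape.CIRCLE), ItemType(Color.GREEN, Shape.CIRCLE),
        ItemType(Color.RED, Shape.SQUARE), ItemType(Color.BLUE, Shape.PLUS),
    }))[:6]
    spec = TrialSpec(
        0, 0, BLUE_CIRCLE,
        stimulus.DisplayComposition(comp_types, BLUE_CIRCLE, BLUE_CIRCLE in comp_types),
        n_frames=2,
    )
    fx = [FixationEvent(0.0, 40.0, 0.0, 0.0)]
    cats = nth_fixation_categories(spec, fx, traj, n_max=4)
    assert cats == [MatchCategory.FULL]  # earliest frame's item wins the tie


def test_sample_and_fixation_bases_agree_on_fully_fixated_stream():
    """Static items, a single noiseless episode spanning the trial: the two
    analysis paths classify every frame identically."""
    bias = gazesim.BiasParams(noise_sd=0.0, jitter_sd=0.0, pursuit_gain=1.0,
                              p_center_first=0.0, fix_dur_mean=1e6)
    spec, traj, stream = make_trial(seed=8, bias=bias, speed=0.0)
    from gazeprime.events import detect_fixations
    fx = detect_fixations(stream)
    assert len(fx) == 1
    d_samples = trial_distribution(spec, traj, stream=stream, basis="samples")
    d_fix = trial_distribution(spec, traj, basis="fixations", fixations=fx)
    np.testing.assert_allclose(d_samples.proportions, d_fix.proportions)
    assert d_samples.frames_used == d_fix.frames_used == 180
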