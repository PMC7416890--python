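import numpy as np
import pytest

from gazeprime import gazesim, stimulus
from gazeprime.stimulus import Color, DisplayComposition, ItemType, Shape, TrialSpec

BLUE_CIRCLE = ItemType(Color.BLUE, Shape.CIRCLE)

# the worked-example display: two copies each of green circle, blue circle,
# blue square, red plus, green plus, blue plus; prime = blue circle
EXAMPLE_TYPES = (
    ItemType(Color.GREEN, Shape.CIRCLE),
    ItemType(Color.BLUE, Shape.CIRCLE),
    ItemType(Color.BLUE, Shape.SQUARE),
    ItemType(Color.RED, Shape.PLUS),
    ItemType(Color.GREEN, Shape.PLUS),
    ItemType(Color.BLUE, Shape.PLUS),
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_composition():
    return DisplayComposition(
        types=tuple(sorted(EXAMPLE_TYPES)), prime=BLUE_CIRCLE, prime_present=True
    )


def make_trial(
    prime=BLUE_CIRCLE,
    prime_present=True,
    seed=0,
    speed=stimulus.DEFAULT_SPEED,
    bias=None,
    n_frames=180,
):
    """One simulated trial: (spec, trajectories, gaze stream)."""
    rng = np.random.default_rng(seed)
    comp = stimulus.sample_composition(prime, prime_present, rng)
    spec = TrialSpec(
        trial_id=0, subject_id=0, prime=prime, composition=comp,
        n_frames=n_frames, rng_seed=seed,
    )
    traj = stimulus.simulate_motion(comp, spec, speed=speed, rng=rng)
    stream = gazesim.simulate_trial_gaze(spec, traj, bias or gazesim.BiasParams(), rng)
    return spec, traj, stream
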