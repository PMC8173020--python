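import numpy as np
import pytest

from underdrive import CageObservation, Experiment, ExperimentSet


def make_experiment(counts, experiment_id=0, release=None):
    """Build an Experiment from [(TT, tt), ...] count pairs, gen 0 first."""
    obs = tuple(
        CageObservation(experiment_id, k, tt, wt) for k, (tt, wt) in enumerate(counts)
    )
    if release is None:
        tt0, wt0 = counts[0]
        release = tt0 / (tt0 + wt0)
    return Experiment(experiment_id, release, obs)


def make_experiment_set(*count_lists):
    return ExperimentSet(
        tuple(make_experiment(c, experiment_id=i) for i, c in enumerate(count_lists))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_cage():
    """One cage released at 50%, one observed generation of (5, 5)."""
    return make_experiment_set([(5, 5), (5, 5)])
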