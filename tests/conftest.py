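import numpy as np
import pytest

from chunkopt.chunking import ChunkStructure
from chunkopt.minjerk import SequenceGeometry
from chunkopt.synthetic import DaySchedule, GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def geom() -> SequenceGeometry:
    return SequenceGeometry()


@pytest.fixture(scope="session")
def random_structures() -> list[ChunkStructure]:
    """A reproducible spread of 10-element structures."""
    rng = np.random.default_rng(1234)
    structs = [ChunkStructure(10, tuple(rng.integers(0, 2, size=9)))
               for _ in range(30)]
    structs += [ChunkStructure(10, (1,) * 9), ChunkStructure(10, (0,) * 9),
                ChunkStructure.from_lengths("3-2-3-2")]
    return structs


@pytest.fixture()
def clean_trial_factory(geom):
    """Noise-free generator trials with a planted structure."""
    cfg = GeneratorConfig(n_days=1, trials_per_day=1)

    def make(structure, noise_cm=0.0, dwell_s=0.1, suboptimality=0.0, seed=0):
        sched = DaySchedule(noise_cm=noise_cm, dwell_s=dwell_s,
                            suboptimality=suboptimality)
        rng = np.random.default_rng(seed)
        trial, truth = generate_trial(structure, cfg, sched, rng)
        return trial, truth

    return make


@pytest.fixture(scope="session")
def small_learning_dataset():
    """6-day x 30-trial synthetic learner used by several module tests."""
    from chunkopt.synthetic import generate_learning_dataset

    cfg = GeneratorConfig(n_days=6, trials_per_day=30, seed=11)
    return generate_learning_dataset(cfg)
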