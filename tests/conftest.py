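import numpy as np
import pytest
from hypothesis import settings

from ecgtf.io_cli import PipelineConfig, run_pipeline
from ecgtf.synthetic import NoiseConfig, make_record

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CLASS_PROBS = [0.5, 0.125, 0.125, 0.125, 0.125]


def mixed_sequence(n_beats: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    return [str(s) for s in rng.choice(list("NAVLR"), p=CLASS_PROBS, size=n_beats)]


@pytest.fixture(scope="session")
def clean_record_520():
    """520 mixed beats, no noise: ground truth for detector recovery."""
    return make_record(mixed_sequence(520, seed=11), noise=NoiseConfig.none(),
                       seed=11, record_id="clean520")


@pytest.fixture(scope="session")
def noisy_record_520():
    """Same beat roster under the default (moderate) noise model."""
    return make_record(mixed_sequence(520, seed=11), noise=NoiseConfig(),
                       seed=11, record_id="noisy520")


@pytest.fixture(scope="session")
def corpus_2000():
    """Four 500-beat noisy records: the desk-scale classification corpus."""
    return [
        make_record(mixed_sequence(500, seed=40 + r), noise=NoiseConfig(),
                    seed=140 + r, record_id=f"syn{r}")
        for r in range(4)
    ]


@pytest.fixture(scope="session")
def annotated_run(corpus_2000):
    """Full pipeline in annotated mode (30-epoch training); shared."""
    return run_pipeline(PipelineConfig(), corpus_2000, mode="annotated", seed=7)


@pytest.fixture(scope="session")
def detect_run(corpus_2000):
    """Full pipeline in detect mode on the same corpus; shared."""
    return run_pipeline(PipelineConfig(), corpus_2000, mode="detect", seed=7)
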