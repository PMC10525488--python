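import numpy as np
import pytest

from eegemo import SyntheticConfig, build_montage, generate_dataset
from eegemo.montage import REGION_IDS


@pytest.fixture(scope="session")
def deap32():
    return build_montage("deap32")


@pytest.fixture(scope="session")
def region_sizes(deap32):
    return deap32.region_sizes()


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 4 trials, 2 classes, short trials — for fast training tests."""
    from eegemo import build_trial_dataset
    from eegemo.train_eval import LabelScheme

    cfg = SyntheticConfig(
        n_subjects=2,
        trials_per_subject=4,
        trial_seconds=3.0,
        n_classes=2,
        scheme=LabelScheme("two_level"),
        blink_rate=0.0,
        seed=42,
    )
    ds = generate_dataset(cfg)
    td = build_trial_dataset(
        [t.recording for t in ds.trials],
        [t.rating for t in ds.trials],
        ds.montage,
        cfg.scheme,
    )
    return cfg, ds, td


def random_encoder_inputs(rng, region_sizes, d=4, T=5, batch=None):
    """Random H/U arrays shaped like real encoder inputs."""
    shape = (batch,) if batch else ()
    H = {r: rng.normal(size=shape + (d, region_sizes[r])) for r in REGION_IDS}
    U = {r: rng.normal(size=shape + (d, T)) for r in REGION_IDS}
    return H, U
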