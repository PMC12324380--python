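import numpy as np
import pytest

from sift2d.synthetic import SyntheticSpec, generate_stack
from sift2d.training import TrainingConfig, split_dataset, train


@pytest.fixture(scope="session")
def small_graded_dataset():
    """120 graded 32-px synthetic classes: (stack, records)."""
    spec = SyntheticSpec(n_classes=120, image_side=32, pixel_size=1.5, seed=11)
    return generate_stack(spec)


@pytest.fixture(scope="session")
def trained_desk_scorer(small_graded_dataset):
    """A quickly trained desk-scale scorer plus its held-out split."""
    stack, records = small_graded_dataset
    dataset = list(zip(list(stack.images), records))
    train_set, val_set = split_dataset(dataset, 0.2, seed=3)
    cfg = TrainingConfig(learning_rate=1e-3, epochs=8, seed=3)
    scorer, trace = train(train_set, cfg, net_config="desk", canonicalize_inputs=False)
    return scorer, trace, train_set, val_set


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
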