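import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import squeezevit as sv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_synth():
    """A quick low-resolution synthetic dataset for I/O and metric tests."""
    spec = sv.SyntheticSpec(n_images=40, image_side=64, n_classes=6, seed=11)
    return sv.generate_synthetic(spec)


@pytest.fixture(scope="session")
def default_model():
    """One default-config model shared by read-only tests."""
    return sv.build_squeezevit(sv.NetworkConfig(seed=7))


@pytest.fixture(scope="session")
def smoke_run():
    """The scaled-down end-to-end learning experiment, run once per session.

    200 synthetic radiograph stand-ins at noise sigma 0.1, trained for 15
    epochs with the published recipe (BCE / Adam / lr 1e-4 / batch 64).
    """
    ds = sv.generate_synthetic(
        sv.SyntheticSpec(n_images=200, noise_sigma=0.1, seed=0))
    model = sv.build_squeezevit(sv.NetworkConfig(seed=0))
    history = sv.train(
        model, ds.images, ds.label_matrix,
        sv.TrainSpec(batch_size=64, epochs=15, learning_rate=1e-4, seed=0),
        track_metrics=False)
    probs = model.predict_proba(ds.images)
    return ds, model, history, probs
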