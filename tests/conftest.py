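import numpy as np
import pytest

from igquant.core_model import ImageRecord, Particle, ProfileROI
from igquant.detection import train_classifier
from igquant.synthetic_data import RenderSpec, detection_training_set


def make_particle(pid="p0", x=100.0, y=100.0, cls=10, **kw):
    return Particle(id=pid, x_nm=x, y_nm=y, radius_nm=cls / 2.0, size_class=cls, **kw)


def make_particles(coords, cls=10, prefix="p", **kw):
    return [
        make_particle(f"{prefix}{i}", float(x), float(y), cls, **kw)
        for i, (x, y) in enumerate(coords)
    ]


@pytest.fixture
def square_roi():
    return ProfileROI(
        id="roi0",
        polygon=[(0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0)],
        compartment="spine",
    )


@pytest.fixture
def simple_record(square_roi):
    return ImageRecord(
        id="img0",
        scale_nm_per_px=1.0,
        rois=[square_roi],
        particles=make_particles([(100, 100), (130, 100), (500, 500)]),
        animal_id="a1",
    )


@pytest.fixture(scope="session")
def trained_model():
    """Classifier fitted on rendered fixtures, shared across detection tests."""
    feats, labels = detection_training_set(n_images=4, seed=40, render_spec=RenderSpec(n_artifacts=8))
    return train_classifier(feats, labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
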