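import numpy as np
import pytest

from bloomcount import classifier as clf
from bloomcount.synthfield import FieldSpec, balanced_patches, generate_field, render_views

# End-to-end tests run on reduced 3x3 layouts so the whole suite stays
# fast; every stage constant (GSD, cell size, screening thresholds,
# canopy scale) is the full-scale default.
TEST_IMAGE_SHAPE = (1400, 1800)


@pytest.fixture(scope="session")
def trained_model():
    """CNN trained on balanced synthetic patches (accuracy saturates in
    the first epochs on this separable task)."""
    patches, labels = balanced_patches(600, seed=0)
    model = clf.build_cnn(seed=0)
    clf.train(model, patches, labels, clf.TrainConfig(epochs=3, rng_seed=0))
    return model


@pytest.fixture(scope="session")
def clean_field_run():
    """Complete-cloud field: one bloom per plot, no dropout."""
    spec = FieldSpec(rows=3, cols=3, blooms_per_plot=1, dropout=0.0,
                     image_shape=TEST_IMAGE_SHAPE)
    field = generate_field(spec, seed=2)
    images, views = render_views(field)
    return field, images, views


@pytest.fixture(scope="session")
def dropout_field_run():
    """Incomplete-cloud field: 1-4 blooms per plot, 20% canopy dropout."""
    spec = FieldSpec(rows=3, cols=3, blooms_per_plot=(1, 4), dropout=0.2,
                     image_shape=TEST_IMAGE_SHAPE)
    field = generate_field(spec, seed=11)
    images, views = render_views(field)
    return field, images, views


@pytest.fixture
def nadir_view():
    """A small camera looking straight down from 15 m."""
    from bloomcount.scene_io import CameraView
    from bloomcount.synthfield import NADIR_ROTATION

    def make(width=800, height=600, position=(0.0, 0.0, 15.0)):
        return CameraView(
            image_id="V", width=width, height=height,
            focal_length=18.0, pixel_pitch=0.0038,
            principal_point=((height - 1) / 2.0, (width - 1) / 2.0),
            position=np.asarray(position, dtype=float),
            rotation=NADIR_ROTATION.copy(),
        )

    return make
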