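import numpy as np
import pytest

import fidmargin as fm


@pytest.fixture(scope="session")
def cos4_is_model():
    """10 mm peak-to-peak I-S cos^4 breathing, 4 s period."""
    return fm.MotionModel(kind="cos4", b=(0.0, 0.0, 10.0), tau=4.0)


@pytest.fixture(scope="session")
def small_phantom_spec(cos4_is_model):
    """One moving marker on a 3 mm-slice grid, phase-0 centroid between
    slice centers so the seed straddles two slices."""
    return fm.PhantomSpec(
        grid_shape=(48, 48, 44),
        spacing_mm=(1.0, 1.0, 3.0),
        marker_specs=[
            fm.MarkerSpec(rest_center_mm=(24.0, 24.0, 40.5),
                          motion=cos4_is_model)
        ],
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return fm.generate_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def three_marker_spec():
    """Three static, well-separated markers (detection-focused)."""
    return fm.PhantomSpec(
        grid_shape=(64, 64, 30),
        spacing_mm=(1.0, 1.0, 3.0),
        marker_specs=[
            fm.MarkerSpec(rest_center_mm=(20.0, 30.0, 64.5)),
            fm.MarkerSpec(rest_center_mm=(44.0, 24.0, 45.0)),
            fm.MarkerSpec(rest_center_mm=(32.0, 44.0, 22.5)),
        ],
    )


@pytest.fixture(scope="session")
def three_marker_phantom(three_marker_spec):
    return fm.generate_phantom(three_marker_spec)


def make_trace(object_id, z_values, x_values=None, y_values=None):
    """Build a MotionTrace from per-phase per-axis scalars (I-S by default)."""
    z = np.asarray(z_values, float)
    n = z.size
    x = np.zeros(n) if x_values is None else np.asarray(x_values, float)
    y = np.zeros(n) if y_values is None else np.asarray(y_values, float)
    return fm.MotionTrace(object_id=object_id,
                          displacement_mm=np.stack([x, y, z], axis=1))
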