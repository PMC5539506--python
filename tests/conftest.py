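import numpy as np
import pytest

from phstrip.calibration import ChartCapture, calibrate
from phstrip.roi import detect_scene
from phstrip.synthetic import CameraModel, default_palette, render_chart_capture


def rectangle_boundary(x0, y0, w, h, step=1.0):
    """Dense boundary points of an axis-aligned rectangle, counter-clockwise."""
    xs = np.arange(x0, x0 + w, step)
    ys = np.arange(y0, y0 + h, step)
    top = np.stack([xs, np.full_like(xs, y0)], axis=1)
    right = np.stack([np.full_like(ys, x0 + w), ys], axis=1)
    bottom = np.stack([xs[::-1] + step, np.full_like(xs, y0 + h)], axis=1)
    left = np.stack([np.full_like(ys, x0), ys[::-1] + step], axis=1)
    return np.vstack([top, right, bottom, left])


@pytest.fixture(scope="session")
def palette():
    return default_palette(7)


@pytest.fixture(scope="session")
def identity_scene(palette):
    """One noise-free identity-camera chart render plus its ground truth."""
    return render_chart_capture(palette, CameraModel(), 7, seed=1)


@pytest.fixture(scope="session")
def identity_calibration(palette):
    """CalibrationData built through the full image pipeline, identity camera."""
    captures = []
    for p in range(15):
        img, _ = render_chart_capture(palette, CameraModel(), p, seed=p)
        _, grid, target = detect_scene(img)
        captures.append(ChartCapture(ph_index=p, reference=grid, target=target))
    return calibrate(captures)
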