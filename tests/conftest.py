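import numpy as np
import pytest


@pytest.fixture
def black_image():
    return np.zeros((240, 320, 3), dtype=np.uint8)


def draw_disc(img, center, radius, color):
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    img[inside] = color
    return inside


def draw_ellipse(img, center, a, b, theta, color):
    """theta: major-axis angle in the (x=col, y=row) plane from +col."""
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    dx = cc - center[1]
    dy = rr - center[0]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1
    img[inside] = color
    return inside
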