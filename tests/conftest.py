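import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_triangle(rng, scale=10.0, min_area=1e-2):
    """A random non-degenerate triangle as a (3, 2) array."""
    while True:
        tri = rng.uniform(-scale, scale, (3, 2))
        v1, v2 = tri[1] - tri[0], tri[2] - tri[0]
        if abs(v1[0] * v2[1] - v1[1] * v2[0]) / 2 > min_area:
            return tri


def random_similarity(rng):
    """Random rotation/reflection + uniform scaling + translation."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if rng.random() < 0.5:
        rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])  # reflection
    scale = rng.uniform(0.1, 10.0)
    shift = rng.uniform(-100, 100, 2)

    def apply(pts):
        return pts @ (scale * rot).T + shift

    return apply
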