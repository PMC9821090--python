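import numpy as np
import pytest

from fazkit import SyntheticSpec, render_scene


def random_mask(rng, shape=(32, 32), p=0.3):
    """Random binary mask fixture material."""
    return rng.random(shape) < p


def random_blob(rng, shape=(64, 64), r_lo=6, r_hi=14):
    """A single connected blob (union of overlapping disks), >= 100 px."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cy, cx = h // 2, w // 2
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_lo ** 2
    for _ in range(4):
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0, r_lo)
        r = rng.uniform(r_lo * 0.6, r_hi)
        oy, ox = cy + d * np.sin(ang), cx + d * np.cos(ang)
        mask |= (yy - oy) ** 2 + (xx - ox) ** 2 <= r ** 2
    return mask


@pytest.fixture(scope="session")
def default_scene():
    """One full-size synthetic scene shared across tests (deterministic)."""
    return render_scene(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A 256 px scene for fast pipeline tests."""
    return render_scene(SyntheticSpec(seed=3, size=256))
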