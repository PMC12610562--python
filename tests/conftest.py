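import numpy as np
import pytest

from kernelpheno import synthetic_tray as st


def oracle_percentile(values, q):
    """Independent percentile oracle: sort + linear interpolation between
    order statistics (no numpy.percentile)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


@pytest.fixture(scope="session")
def small_geo():
    """Reduced capture geometry: everything scales, renders ~10x faster."""
    return st.TrayGeometry(image_w=1200, image_h=1160, tray_side=1000)


@pytest.fixture(scope="session")
def small_scene(small_geo):
    return st.random_scene(seed=7, geometry=small_geo)


@pytest.fixture(scope="session")
def small_render(small_scene):
    return st.render_tray(small_scene)


@pytest.fixture(scope="session")
def full_render():
    """One full-geometry (3300 x 3120) unrotated tray, rendered once."""
    scene = st.random_scene(seed=1)
    return scene, st.render_tray(scene)
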