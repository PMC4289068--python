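import numpy as np
import pytest

from cdrwave import Contour, PhantomParams, make_ring_stack


def circle_contour(cx, cy, r, n=64):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))


@pytest.fixture(scope="session")
def ring_phantom():
    """Noiseless parabolic ring stack (v0=0.2 µm/s, t_rev=100 s)."""
    params = PhantomParams(v0=0.2, t_rev=100.0, shape=(21, 96, 96),
                           frame_interval=10.0, pixel_size=0.8)
    stack, gt = make_ring_stack(params)
    return params, stack, gt
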