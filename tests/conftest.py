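import numpy as np
import pytest

from enthcg.cgmodel import build_enth16


@pytest.fixture(scope="session")
def topology():
    return build_enth16()


@pytest.fixture(scope="session")
def hinged_block_frames():
    """Two internally rigid 10-bead blocks hinged at the middle, aligned."""
    from enthcg.cgmodel import align_trajectory

    rng = np.random.default_rng(0)
    n = 20
    base = np.zeros((n, 3))
    base[:, 0] = np.arange(n) * 0.5
    frames = []
    for _ in range(300):
        ang = rng.normal(0.0, 0.2)
        f = base.copy()
        c, s = np.cos(ang), np.sin(ang)
        rel = f[10:] - f[10]
        f[10:, 0] = f[10, 0] + c * rel[:, 0] - s * rel[:, 1]
        f[10:, 1] = f[10, 1] + s * rel[:, 0] + c * rel[:, 1]
        f += rng.normal(0.0, 0.005, (n, 3))
        frames.append(f)
    return align_trajectory(np.array(frames))
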