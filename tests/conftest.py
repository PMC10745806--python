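import numpy as np
import pytest

from axoquant.phantom import Collateral, PhantomSpec

PX = 0.2483  # µm/px, the reference pixel size (4 px = 0.9932 µm)


def spread_collateral_spec(k: int, seed: int = 0, noise_sigma: float = 0.0,
                           length_um: float = 120.0) -> PhantomSpec:
    """Phantom with k well-separated lateral collaterals of 4-8 µm.

    Collaterals are long enough to extend past the 5 µm shaft band and the
    0.5 µm component filter, so each one yields exactly one countable mask
    component in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    shaft = tuple((20.0 + 2.0 * np.sin(np.pi * y / length_um), y)
                  for y in np.linspace(0.0, length_um, 9))
    if k:
        positions = np.sort(rng.uniform(10, length_um - 10, k))
        for i in range(1, k):
            positions[i] = max(positions[i], positions[i - 1] + 3.0)
    else:
        positions = []
    cols = tuple(
        Collateral(position_um=float(p), side=("left", "right")[i % 2],
                   length_um=float(rng.uniform(4.0, 8.0)),
                   angle_deg=float(rng.uniform(-15, 15)), intensity=150.0)
        for i, p in enumerate(positions))
    rows = int(length_um / PX) + 40
    return PhantomSpec(shape_px=(rows, 160), shaft_points_um=shaft,
                       collaterals=cols, seed=seed, noise_sigma=noise_sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
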