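import numpy as np
import pytest

from sparsecf.core import RatingsMatrix


@pytest.fixture
def small_matrix() -> RatingsMatrix:
    """4 users x 5 items with a couple of holes, scale [0, 10]."""
    v = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, np.nan, 6.0, 8.0, 10.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [np.nan, 5.0, 5.0, 5.0, np.nan],
        ]
    )
    return RatingsMatrix(["a", "b", "c", "d"], list("vwxyz"), v, scale=(0, 10))


def random_matrix(n_users, n_items, missing_frac, seed, scale=(0.0, 100.0)):
    """Seeded random matrix helper with uniform ratings and random holes."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(scale[0], scale[1], size=(n_users, n_items))
    if missing_frac > 0:
        holes = rng.random(v.shape) < missing_frac
        # keep at least one observed value
        holes.flat[0] = False
        v[holes] = np.nan
    return RatingsMatrix(
        [f"u{i}" for i in range(n_users)],
        [f"i{j}" for j in range(n_items)],
        v,
        scale=scale,
    )
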