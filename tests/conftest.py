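import numpy as np
import pytest

from panctex import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

#: Small phantom used throughout the tests — 4 slices of 32×32 keeps
#: per-subject rendering + extraction in the millisecond range.
SMALL_PHANTOM = PhantomSpec(shape=(4, 32, 32), tumor_radii=(10.0, 7.0), normal_radii=(6.0, 9.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_phantom_spec():
    return SMALL_PHANTOM


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom: (volume, tumor mask, normal mask)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def cohort30():
    """A 30-subject synthetic cohort with a real survival effect."""
    return generate_cohort(SMALL_PHANTOM, CohortSpec(n=30, effect_beta=0.8, seed=11))


def brute_force_glcm(levels, n_levels, offsets, symmetric):
    """O(N²) reference pair enumerator for co-occurrence counts.

    ``offsets`` are (drow, dcol) displacement tuples. Counts a pair only
    when both pixels lie on the grid and neither carries the sentinel.
    """
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    nrow, ncol = levels.shape
    for r in range(nrow):
        for c in range(ncol):
            if levels[r, c] < 0:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and levels[r2, c2] >= 0:
                    counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts
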