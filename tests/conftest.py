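import numpy as np
import pytest

import hemilat as hl
from hemilat.io import make_parcel_table


def toy_names(n: int) -> list[str]:
    half = n // 2
    return [f"17Networks_LH_Toy_{i + 1}" for i in range(half)] + [
        f"17Networks_RH_Toy_{i + 1}" for i in range(half)
    ]


@pytest.fixture
def toy_parcels():
    """2 left / 2 right ROIs."""
    return make_parcel_table(toy_names(4))


@pytest.fixture
def toy_connectome():
    """Within-left edge 0.8, cross edges 0.2, within-right edge 0.4."""
    m = np.array(
        [
            [1.0, 0.8, 0.2, 0.2],
            [0.8, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 0.4],
            [0.2, 0.2, 0.4, 1.0],
        ]
    )
    return hl.Connectome(matrix=m)


@pytest.fixture
def parcels40():
    return make_parcel_table(toy_names(40))


def small_spec(**kw) -> hl.CohortSpec:
    """A 40-ROI cohort spec scaled down from the defaults for fast tests."""
    defaults = dict(
        n_per_group=(8, 8, 8),
        t_per_group=(120, 120, 120),
        n_rois=40,
        signal_rois={
            "RLS": {i: "L" for i in range(3, 9)},
            "NRLS": {i + 20: "R" for i in range(3, 9)},
            "CTRL": {},
        },
        asymmetry_delta=0.2,
    )
    defaults.update(kw)
    return hl.CohortSpec(**defaults)


def random_connectome(rng: np.random.Generator, n: int) -> hl.Connectome:
    """Arbitrary nonnegative symmetric matrix with unit diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return hl.Connectome(matrix=m)


@pytest.fixture(scope="session")
def strong_cohort_profiles():
    """Shared strong-effect 40-ROI cohort with profiles (session-scoped)."""
    spec = small_spec(n_per_group=(10, 10, 10))
    subjects, truth = hl.sample_cohort(spec, seed=42)
    parcels = spec.parcel_table()
    cfg = hl.PipelineConfig()
    profiles = [hl.compute_profile(ts, parcels, cfg) for ts in subjects]
    return spec, subjects, truth, parcels, profiles
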