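import numpy as np
import pytest

from paddygrade.data import MonitoringDataset, ToxinSeries
from paddygrade.synthetic import StorageCondition, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> MonitoringDataset:
    """6 two-channel series, 30 days, default noise (seeded)."""
    return simulate_dataset(n_bins=3, n_points=2, n_days=30, seed=11)


@pytest.fixture(scope="session")
def planted_blobs():
    """3 well-separated Gaussian components in P-space (separation >> 6 sd)."""
    rng = np.random.default_rng(7)
    centers = np.array([[2.0, 2.0, 2.0], [8.0, 8.0, 8.0], [14.0, 14.0, 14.0]])
    pts = np.vstack([c + 0.5 * rng.standard_normal((50, 3)) for c in centers])
    return pts, np.repeat([0, 1, 2], 50), centers


def constant_series(value: float = 5.0, n_days: int = 30) -> ToxinSeries:
    days = np.arange(1, n_days + 1)
    return ToxinSeries("const", days,
                       np.full((n_days, 2), value), ("AFB1", "DON"),
                       StorageCondition(20.0, 0.95))
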