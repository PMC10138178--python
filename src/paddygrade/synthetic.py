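"""Synthetic paddy-storage monitoring data.

Generates daily mycotoxin trajectories (aflatoxin B1 and deoxynivalenol) for
grain bins held at fixed temperature and water activity.  Toxin accumulation
follows a logistic growth law whose rate responds to the storage condition
through Gaussian-bell factors centred at the warm/humid corner of the legal
domain (30 °C, a_w 0.98), where fungal growth is fastest.  Multiplicative
lognormal noise emulates assay variability.

The default design mirrors a storage-monitoring campaign of 9 shallow round
bins with 11 sampling points each, sampled daily for 30 days: 99 series and
2970 (series, day) records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import MonitoringDataset, ToxinSeries

__all__ = [
    "StorageCondition",
    "GrowthParams",
    "AFB1_LIMIT",
    "DON_LIMIT",
    "default_params",
    "default_condition_grid",
    "growth_rate",
    "logistic_curve",
    "simulate_series",
    "simulate_dataset",
]

#: Regulatory limits for paddy, µg/kg.
AFB1_LIMIT = 10.0
DON_LIMIT = 1250.0

TEMP_RANGE = (10.0, 30.0)
AW_RANGE = (0.92, 0.98)


@dataclass(frozen=True)
class StorageCondition:
    """A storage environment: temperature in °C and water activity (a_w)."""

    temperature: float
    water_activity: float

    def __post_init__(self):
        if not TEMP_RANGE[0] <= self.temperature <= TEMP_RANGE[1]:
            raise ValueError(
                f"temperature {self.temperature} outside [{TEMP_RANGE[0]}, {TEMP_RANGE[1]}] °C"
            )
        if not AW_RANGE[0] <= self.water_activity <= AW_RANGE[1]:
            raise ValueError(
                f"water_activity {self.water_activity} outside [{AW_RANGE[0]}, {AW_RANGE[1]}]"
            )


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters for one toxin.

    ``max_rate`` is the per-day logistic rate attained at the optimum
    (30 °C, a_w 0.98); ``temp_scale`` and ``aw_scale`` are the widths of the
    Gaussian-bell responses that attenuate the rate away from the optimum.
    ``noise_sd`` is the standard deviation of the lognormal (relative) noise.
    """

    toxin_kind: str
    initial_level: float
    carrying_capacity: float
    max_rate: float
    temp_scale: float = 20.0
    aw_scale: float = 0.05
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.toxin_kind not in ("AFB1", "DON"):
            raise ValueError(f"unknown toxin_kind {self.toxin_kind!r}")
        if self.initial_level <= 0:
            raise ValueError("initial_level must be > 0")
        if self.carrying_capacity <= self.initial_level:
            raise ValueError("carrying_capacity must exceed initial_level")
        if self.max_rate < 0:
            raise ValueError("max_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_params(toxin_kind: str, noise_sd: float = 0.05) -> GrowthParams:
    """Default growth parameters per toxin.

    Carrying capacities are twice the regulatory limit (AFB1 20 µg/kg, DON
    2500 µg/kg) so warm/humid trajectories cross the limit within a 30-day
    campaign; ``max_rate`` 0.25/day puts that crossing around mid-campaign.
    """
    if toxin_kind == "AFB1":
        return GrowthParams("AFB1", initial_level=0.5, carrying_capacity=2 * AFB1_LIMIT,
                            max_rate=0.25, noise_sd=noise_sd)
    if toxin_kind == "DON":
        return GrowthParams("DON", initial_level=60.0, carrying_capacity=2 * DON_LIMIT,
                            max_rate=0.25, noise_sd=noise_sd)
    raise ValueError(f"unknown toxin_kind {toxin_kind!r}")


def default_condition_grid() -> list[StorageCondition]:
    """3 × 3 grid of storage environments: T ∈ {10, 20, 30} × a_w ∈ {0.92, 0.95, 0.98}."""
    return [StorageCondition(t, a)
            for t in (10.0, 20.0, 30.0) for a in (0.92, 0.95, 0.98)]


def growth_rate(condition: StorageCondition, params: GrowthParams) -> float:
    """Per-day logistic rate under ``condition``.

    rate = max_rate · g_T(T) · g_aw(a_w), with each response a Gaussian bell
    centred at the domain optimum (30 °C, 0.98) so the rate is strictly
    increasing in both variables over the legal ranges and equals ``max_rate``
    exactly at the optimum.
    """
    g_t = np.exp(-((condition.temperature - TEMP_RANGE[1]) / params.temp_scale) ** 2)
    g_aw = np.exp(-((condition.water_activity - AW_RANGE[1]) / params.aw_scale) ** 2)
    return float(params.max_rate * g_t * g_aw)


def logistic_curve(t: np.ndarray, x0: float, capacity: float, rate: float) -> np.ndarray:
    """x(t) = K / (1 + ((K − x0)/x0) · exp(−r t))."""
    a = (capacity - x0) / x0
    return capacity / (1.0 + a * np.exp(-rate * np.asarray(t, dtype=float)))


def simulate_series(condition: StorageCondition, n_days: int, params: GrowthParams,
                    seed: int, sample_id: str = "s0") -> ToxinSeries:
    """One toxin trajectory on days 1..n_days under a fixed storage condition.

    Deterministic logistic growth times multiplicative lognormal noise; the
    same seed always reproduces the same series.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    days = np.arange(1, n_days + 1)
    rate = growth_rate(condition, params)
    x = logistic_curve(days, params.initial_level, params.carrying_capacity, rate)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x * np.exp(params.noise_sd * rng.standard_normal(n_days))
    return ToxinSeries(sample_id=sample_id, days=days,
                       values=x[:, None], channels=(params.toxin_kind,),
                       condition=condition)


def simulate_dataset(conditions: Sequence[StorageCondition] | None = None,
                     n_bins: int = 9, n_points: int = 11, n_days: int = 30,
                     afb1: GrowthParams | None = None,
                     don: GrowthParams | None = None,
                     seed: int = 0) -> MonitoringDataset:
    """A full monitoring campaign: n_bins × n_points two-channel series.

    Each bin takes one condition from ``conditions``, cycled; each sampling
    point within a bin gets an independent noise realization.  Defaults
    (9 bins, 11 points, 30 days) give 99 series and 2970 records.
    """
    if n_bins < 1 or n_points < 1 or n_days < 1:
        raise ValueError("n_bins, n_points and n_days must all be >= 1")
    if conditions is None:
        conditions = default_condition_grid()
    if len(conditions) == 0:
        raise ValueError("condition grid must be nonempty")
    afb1 = afb1 or default_params("AFB1")
    don = don or default_params("DON")
    ss = np.random.SeedSequence(seed)
    series = []
    for b in range(n_bins):
        cond = conditions[b % len(conditions)]
        for p in range(n_points):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(2) % (2 ** 31)
            a = simulate_series(cond, n_days, afb1, int(seeds[0]))
            d = simulate_series(cond, n_days, don, int(seeds[1]))
            series.append(ToxinSeries(
                sample_id=f"b{b:02d}p{p:02d}", days=a.days,
                values=np.column_stack([a.values[:, 0], d.values[:, 0]]),
                channels=("AFB1", "DON"), condition=cond,
                bin_id=b, point_id=p))
    return MonitoringDataset(series=series)
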