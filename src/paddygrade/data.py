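"""Series containers, CSV I/O, the train/test/validation split, and normalization.

The on-disk format is a long CSV with one row per (sample, day):

    sample_id,bin,point,day,temperature_C,water_activity,afb1_ug_kg,don_ug_kg

Days are 1-based integers; toxin levels are µg/kg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToxinSeries",
    "MonitoringDataset",
    "SplitSpec",
    "Normalizer",
    "CSV_COLUMNS",
    "read_csv",
    "write_csv",
    "split_dataset",
    "fit_normalizer",
]

CSV_COLUMNS = ["sample_id", "bin", "point", "day", "temperature_C",
               "water_activity", "afb1_ug_kg", "don_ug_kg"]

_CHANNEL_COLS = {"AFB1": "afb1_ug_kg", "DON": "don_ug_kg"}


class ParseError(ValueError):
    """CSV contents violate the format contract."""


@dataclass
class ToxinSeries:
    """One sample's daily toxin trajectory with its storage covariates.

    ``values`` has shape (n_days, n_channels); ``channels`` names each column.
    """

    sample_id: str
    days: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...]
    condition: "StorageCondition"
    bin_id: int = 0
    point_id: int = 0

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.days.shape[0]:
            raise ValueError("days and values must have equal length")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("values width must match number of channels")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("toxin values must be >= 0")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def slice_days(self, start: int, stop: int) -> "ToxinSeries":
        """Sub-series for positions [start, stop) along the day grid."""
        return ToxinSeries(self.sample_id, self.days[start:stop],
                           self.values[start:stop], self.channels,
                           self.condition, self.bin_id, self.point_id)


@dataclass
class MonitoringDataset:
    """A collection of ToxinSeries sharing a day grid."""

    series: list[ToxinSeries]

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def n_records(self) -> int:
        return sum(s.n_days for s in self.series)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for i, day in enumerate(s.days):
                rows.append({
                    "sample_id": s.sample_id, "bin": s.bin_id, "point": s.point_id,
                    "day": int(day),
                    "temperature_C": s.condition.temperature,
                    "water_activity": s.condition.water_activity,
                    "afb1_ug_kg": s.channel("AFB1")[i] if "AFB1" in s.channels else 0.0,
                    "don_ug_kg": s.channel("DON")[i] if "DON" in s.channels else 0.0,
                })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation fractions; must be in (0,1) and sum to 1."""

    train: float = 0.7
    test: float = 0.2
    validation: float = 0.1

    def __post_init__(self):
        for name, f in (("train", self.train), ("test", self.test),
                        ("validation", self.validation)):
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} fraction {f} not in (0, 1)")
        if abs(self.train + self.test + self.validation - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def write_csv(dataset: MonitoringDataset, path) -> None:
    """Serialize with 17 significant digits so a roundtrip is bit-exact."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> MonitoringDataset:
    """Read a long-format monitoring CSV back into a MonitoringDataset."""
    from .synthetic import StorageCondition  # deferred: synthetic imports this module

    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    series = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.reset_index()
        days = grp["day"].to_numpy()
        bad = np.nonzero(np.diff(days) <= 0)[0]
        if bad.size:
            row = int(grp.loc[bad[0] + 1, "index"]) + 2  # 1-based incl. header
            raise ParseError(f"non-monotone day at row {row} (sample {sid})")
        vals = grp[["afb1_ug_kg", "don_ug_kg"]].to_numpy()
        neg = np.nonzero((vals < 0).any(axis=1))[0]
        if neg.size:
            row = int(grp.loc[neg[0], "index"]) + 2
            raise ParseError(f"negative toxin value at row {row} (sample {sid})")
        cond = StorageCondition(float(grp["temperature_C"].iloc[0]),
                                float(grp["water_activity"].iloc[0]))
        series.append(ToxinSeries(
            sample_id=str(sid), days=days, values=vals,
            channels=("AFB1", "DON"), condition=cond,
            bin_id=int(grp["bin"].iloc[0]), point_id=int(grp["point"].iloc[0])))
    return MonitoringDataset(series=series)


def _series_block_sizes(n_days: int, spec: SplitSpec) -> tuple[int, int, int]:
    """floor(fraction × n) for test and validation; the remainder goes to train."""
    n_test = int(np.floor(spec.test * n_days))
    n_val = int(np.floor(spec.validation * n_days))
    return n_days - n_test - n_val, n_test, n_val


def split_dataset(dataset: MonitoringDataset, spec: SplitSpec = SplitSpec()
                  ) -> tuple[MonitoringDataset, MonitoringDataset, MonitoringDataset]:
    """Record-level split by contiguous time blocks within each series.

    Within every series the earliest block goes to train, the middle to test,
    and the latest to validation, so no model ever trains on the future of a
    series it is evaluated on.  Block sizes are floor(fraction × length) for
    test and validation with the remainder appended to train; for the
    canonical 99 × 30-day campaign at (0.7, 0.2, 0.1) the record counts are
    exactly (2079, 594, 297).  The split is deterministic.
    """
    train, test, val = [], [], []
    for s in dataset:
        n_tr, n_te, n_va = _series_block_sizes(s.n_days, spec)
        train.append(s.slice_days(0, n_tr))
        if n_te:
            test.append(s.slice_days(n_tr, n_tr + n_te))
        if n_va:
            val.append(s.slice_days(n_tr + n_te, s.n_days))
    return (MonitoringDataset(train), MonitoringDataset(test), MonitoringDataset(val))


def split_indices(dataset: MonitoringDataset, spec: SplitSpec = SplitSpec()) -> dict:
    """Global record indices (row order of ``write_csv``) for each partition."""
    out = {"train": [], "test": [], "validation": []}
    offset = 0
    for s in dataset:
        n_tr, n_te, n_va = _series_block_sizes(s.n_days, spec)
        idx = np.arange(offset, offset + s.n_days)
        out["train"].extend(idx[:n_tr].tolist())
        out["test"].extend(idx[n_tr:n_tr + n_te].tolist())
        out["validation"].extend(idx[n_tr + n_te:].tolist())
        offset += s.n_days
    return out


@dataclass
class Normalizer:
    """Per-channel affine normalizer with statistics from training data only."""

    channels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        return np.asarray(normalized, dtype=float) * self.sd + self.mean


def fit_normalizer(train: MonitoringDataset, strict: bool = True) -> Normalizer:
    """Fit per-toxin-channel mean/sd over every training record.

    A constant channel is a domain error when ``strict``; with
    ``strict=False`` its sd is replaced by 1 so degenerate inputs (e.g. a
    constant series fed to the persistence baseline) still pass through.
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    channels = train.series[0].channels
    stacked = np.concatenate([s.values for s in train], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    if strict:
        for name, s in zip(channels, sd):
            if s <= 0:
                raise ValueError(f"channel {name} is constant (sd = 0)")
    else:
        sd = np.where(sd > 0, sd, 1.0)
    return Normalizer(channels=channels, mean=mean, sd=sd)
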