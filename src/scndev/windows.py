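"""Sliding age-window construction.

Scans are pooled across participants, sorted by age, and cut into
overlapping fixed-size windows ("age-bins"). Within each window every
participant contributes at most one scan: when a participant has several
scans inside a window, the scan closest to the window's median age is
kept. Each bin is indexed by the median age of its retained scans, which
is the time axis for all downstream trajectory modelling.

The placement convention slides over the pooled scans (not participants):
windows of ``bin_size`` consecutive scans start at offsets 0, s, 2s, ...
while the window still fits, and one terminal window anchored at the
oldest ``bin_size`` scans is appended when the last regular window does
not reach the end of the pool. With a pool of 366 scans this yields 16
bins for (bin_size=80, step 25%) and bin counts between 12 and 23 across
the nine standard configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .errors import InvalidConfigError, InvalidInputError

#: the nine standard sliding-window configurations
DEFAULT_BIN_SIZES = (70, 80, 90)
DEFAULT_STEP_FRACTIONS = (0.20, 0.25, 0.30)


@dataclass(frozen=True)
class WindowConfig:
    """One sliding-window configuration.

    Parameters
    ----------
    bin_size
        Number of scans per window before deduplication.
    step_fraction
        Increment between window starts, as a fraction of ``bin_size``.
        The integer step is ``round_half_up(step_fraction * bin_size)``.
    """

    bin_size: int
    step_fraction: float

    def __post_init__(self):
        if self.bin_size < 2:
            raise InvalidConfigError(f"bin_size must be >= 2, got {self.bin_size}")
        if not (0.0 < self.step_fraction < 1.0):
            raise InvalidConfigError(
                f"step_fraction must be in (0, 1), got {self.step_fraction}"
            )
        if self.step < 1:
            raise InvalidConfigError("derived step must be >= 1")

    @property
    def step(self) -> int:
        return round_half_up(self.step_fraction * self.bin_size)

    @property
    def config_id(self) -> str:
        return f"b{self.bin_size}_s{round_half_up(self.step_fraction * 100)}"


@dataclass(frozen=True)
class AgeBin:
    """An age-bin: one scan per participant, contiguous in age pre-dedup."""

    index: int
    scan_ids: tuple
    participant_ids: tuple
    ages: tuple
    median_age: float

    def __post_init__(self):
        if len(set(self.participant_ids)) != len(self.scan_ids):
            raise InvalidInputError("participants must be unique within a bin")

    @property
    def n(self) -> int:
        return len(self.scan_ids)


def enumerate_configs(
    bin_sizes: Iterable[int] = DEFAULT_BIN_SIZES,
    step_fractions: Iterable[float] = DEFAULT_STEP_FRACTIONS,
) -> list[WindowConfig]:
    """Cartesian product of bin sizes and step fractions, ordered by both."""
    bin_sizes = sorted(set(bin_sizes))
    step_fractions = sorted(set(step_fractions))
    if not bin_sizes or not step_fractions:
        raise InvalidConfigError("bin_sizes and step_fractions must be non-empty")
    return [
        WindowConfig(b, s) for b, s in itertools.product(bin_sizes, step_fractions)
    ]


def n_bins(pool_size: int, bin_size: int, step: int) -> int:
    """Closed-form bin count for the placement convention.

    ``floor((M - bin_size)/step) + 1`` regular windows, plus one terminal
    window anchored at the end when ``(M - bin_size) mod step != 0``.
    """
    if pool_size < bin_size:
        raise InvalidInputError("pool smaller than bin_size")
    rem = pool_size - bin_size
    return rem // step + 1 + (1 if rem % step else 0)


def _window_offsets(pool_size: int, bin_size: int, step: int) -> list[int]:
    offsets = list(range(0, pool_size - bin_size + 1, step))
    if offsets[-1] != pool_size - bin_size:
        offsets.append(pool_size - bin_size)
    return offsets


def dedup_bin(window_scans: pd.DataFrame, index: int = 0) -> AgeBin:
    """Collapse a window to one scan per participant.

    The window median age is computed over *all* scans in the window;
    for each participant the scan minimising ``|age - median|`` is kept,
    ties broken by the lower ``scan_id``. The bin's ``median_age`` is then
    recomputed over the retained scans.
    """
    if len(window_scans) == 0:
        raise InvalidInputError("empty window")
    window_median = float(np.median(window_scans["age"].to_numpy()))
    df = window_scans.assign(_dist=(window_scans["age"] - window_median).abs())
    df = df.sort_values(["_dist", "scan_id"], kind="mergesort")
    kept = df.drop_duplicates("participant_id", keep="first")
    kept = kept.sort_values(["age", "scan_id"], kind="mergesort")
    return AgeBin(
        index=index,
        scan_ids=tuple(kept["scan_id"]),
        participant_ids=tuple(kept["participant_id"]),
        ages=tuple(float(a) for a in kept["age"]),
        median_age=float(np.median(kept["age"].to_numpy())),
    )


def build_bins(scan_table: pd.DataFrame, config: WindowConfig) -> list[AgeBin]:
    """Build all age-bins for one window configuration.

    Scans are sorted by age (ties by ``scan_id``); windows are placed at
    regular offsets with a terminal anchored window, then each window is
    deduplicated to one scan per participant.
    """
    required = {"participant_id", "scan_id", "age"}
    missing = required - set(scan_table.columns)
    if missing:
        raise InvalidInputError(f"scan table missing columns: {sorted(missing)}")
    pool = scan_table.sort_values(["age", "scan_id"], kind="mergesort").reset_index(
        drop=True
    )
    m = len(pool)
    if m < config.bin_size:
        raise InvalidInputError(
            f"pool of {m} scans smaller than bin_size {config.bin_size}"
        )
    bins = []
    for i, off in enumerate(_window_offsets(m, config.bin_size, config.step)):
        window = pool.iloc[off : off + config.bin_size]
        bins.append(dedup_bin(window, index=i))
    return bins


def bins_to_frame(bins: Sequence[AgeBin], config: WindowConfig) -> pd.DataFrame:
    """Tidy manifest of bins: one row per retained scan."""
    rows = []
    for b in bins:
        for sid, pid, age in zip(b.scan_ids, b.participant_ids, b.ages):
            rows.append(
                {
                    "config_id": config.config_id,
                    "bin_index": b.index,
                    "scan_id": sid,
                    "participant_id": pid,
                    "age": age,
                    "median_age": b.median_age,
                }
            )
    return pd.DataFrame(rows)
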