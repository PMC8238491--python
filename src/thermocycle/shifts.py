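"""Temperature-shift detection (the "3-over-6" rule) on daily series.

A temperature shift starts on cycle day ``d`` when three consecutive daily
values (days d, d+1, d+2) are each at least 0.2 degrees C above the highest
of the previous six days; if one of the six baseline days is missing, the
highest of the remaining five is used (at least five of the six must be
present).  To exclude rises unrelated to the menstrual rhythm (fever,
alcohol, ...), only shifts starting within the last 14 days of the cycle
count.  A curve with at least one shift is biphasic, otherwise monophasic.

Every qualifying start day is reported: detections may overlap, so one
cycle can carry several shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import DailySeries

__all__ = [
    "ShiftRuleConfig",
    "ShiftResult",
    "detect_shifts",
    "first_shift_offset",
    "shift_count_distribution",
]


@dataclass(frozen=True)
class ShiftRuleConfig:
    """Parameters of the shift rule.

    rise_threshold
        Required rise above the baseline maximum, degrees C (inclusive:
        a run value equal to baseline max + threshold qualifies); the
        comparison uses full precision, no rounding.
    run_length
        Number of consecutive non-missing elevated days (3).
    baseline_length / baseline_min_present
        The baseline is the ``baseline_length`` (6) days before the run;
        at least ``baseline_min_present`` (5) of them must be non-missing.
    window_last_n
        Shifts must start within the last ``window_last_n`` (14) days of
        the cycle.
    """

    rise_threshold: float = 0.2
    run_length: int = 3
    baseline_length: int = 6
    baseline_min_present: int = 5
    window_last_n: int = 14

    def __post_init__(self) -> None:
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if not 1 <= self.baseline_min_present <= self.baseline_length:
            raise ValueError("need 1 <= baseline_min_present <= baseline_length")
        if self.rise_threshold < 0:
            raise ValueError("rise_threshold must be non-negative")


@dataclass(frozen=True)
class ShiftResult:
    """Detected shift start days and the resulting curve pattern."""

    start_days: tuple[int, ...]
    pattern: str  # "biphasic" | "monophasic"

    def __post_init__(self) -> None:
        expected = "biphasic" if self.start_days else "monophasic"
        if self.pattern != expected:
            raise ValueError(f"pattern {self.pattern!r} inconsistent with start days")

    @property
    def n_shifts(self) -> int:
        return len(self.start_days)

    @property
    def biphasic(self) -> bool:
        return self.pattern == "biphasic"


def _as_values(series: DailySeries | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(series, DailySeries):
        return series.values
    return np.asarray(series, dtype=float)


def detect_shifts(
    series: DailySeries | np.ndarray | Sequence[float],
    cfg: ShiftRuleConfig = ShiftRuleConfig(),
) -> ShiftResult:
    """Scan a daily series for temperature-shift start days.

    Day ``d`` (1-based) starts a shift iff

    * days d .. d+run_length-1 are all non-missing,
    * of the ``baseline_length`` days before d, at least
      ``baseline_min_present`` are non-missing,
    * every run value >= max(non-missing baseline) + rise_threshold,
    * the run fits in the cycle (d + run_length - 1 <= L) and d lies in
      the last ``window_last_n`` days (d >= L - window_last_n + 1).

    A cycle too short to hold a baseline plus a run yields zero shifts.
    """
    values = _as_values(series)
    L = values.size
    starts: list[int] = []
    d_min = max(cfg.baseline_length + 1, L - cfg.window_last_n + 1)
    d_max = L - cfg.run_length + 1
    for d in range(d_min, d_max + 1):
        run = values[d - 1 : d - 1 + cfg.run_length]
        if np.isnan(run).any():
            continue
        baseline = values[d - 1 - cfg.baseline_length : d - 1]
        present = baseline[~np.isnan(baseline)]
        if present.size < cfg.baseline_min_present:
            continue
        if np.all(run >= present.max() + cfg.rise_threshold):
            starts.append(d)
    pattern = "biphasic" if starts else "monophasic"
    return ShiftResult(start_days=tuple(starts), pattern=pattern)


def first_shift_offset(result: ShiftResult, ov: int) -> Optional[int]:
    """Signed offset of the first shift start from the ovulation day.

    Positive = the shift starts after ovulation.  None for monophasic
    curves.
    """
    if not result.biphasic:
        return None
    if ov < 1:
        raise ValueError("ovulation day must be >= 1")
    return min(result.start_days) - ov


def shift_count_distribution(results: Iterable[ShiftResult]) -> dict[str, int]:
    """Histogram of shifts per cycle among biphasic cycles.

    Returns counts under keys "1", "2", "3", ">3" plus the number of
    biphasic cycles under "biphasic"; the four category counts sum to the
    biphasic count.
    """
    hist = {"1": 0, "2": 0, "3": 0, ">3": 0, "biphasic": 0}
    for res in results:
        n = res.n_shifts
        if n == 0:
            continue
        hist["biphasic"] += 1
        if n <= 3:
            hist[str(n)] += 1
        else:
            hist[">3"] += 1
    return hist
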