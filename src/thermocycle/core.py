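"""Core domain model for menstrual-cycle temperature analysis.

A cycle starts on the first day of menstrual bleeding (cycle day 1, 1-based,
all day intervals inclusive).  Each cycle carries two daily temperature
series — nocturnal wrist skin temperature reduced to one value per night,
and oral basal body temperature (BBT) taken on waking — plus a daily urine
LH test record.  The LH test is the reference standard: the day after the
LH surge is the ovulation day, a cycle with a positive test is ovulatory,
one with only negative tests is anovulatory.

Quality control drops cycles with a missing reference standard or with 30%
or more of either temperature series missing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Modality",
    "LhResult",
    "DailySeries",
    "LhSeries",
    "OvulationCall",
    "Cycle",
    "DayInterval",
    "PhaseWindows",
    "QcConfig",
    "QcDecision",
    "ReferenceStandardMissing",
    "assign_ovulation",
    "qc_cycle",
    "phase_windows",
    "follicular_luteal_split",
]

#: physiologic band for accepted daily temperatures, degrees Celsius
TEMP_MIN_C = 30.0
TEMP_MAX_C = 42.0


class Modality(str, enum.Enum):
    """Temperature measurement modality."""

    WRIST = "wrist"
    BBT = "bbt"


class LhResult(str, enum.Enum):
    """Outcome of one day's urine LH test."""

    POSITIVE = "pos"
    NEGATIVE = "neg"
    NOT_PERFORMED = "na"


class ReferenceStandardMissing(ValueError):
    """No LH test was performed in the cycle; ovulation status is unknowable."""


@dataclass(frozen=True)
class DailySeries:
    """One modality's daily temperatures over a cycle.

    ``values`` is indexed by cycle day 1..L (element 0 is day 1); missing
    days are NaN.  Non-missing values must lie in the physiologic band
    [30, 42] degrees C.
    """

    modality: Modality
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("daily series must be a non-empty 1-D vector")
        present = vals[~np.isnan(vals)]
        if present.size and (present.min() < TEMP_MIN_C or present.max() > TEMP_MAX_C):
            raise ValueError(
                f"temperatures outside physiologic band [{TEMP_MIN_C}, {TEMP_MAX_C}] C"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the day's value is missing."""
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing))

    def value_on(self, day: int) -> float:
        """Temperature on 1-based cycle ``day`` (NaN if missing)."""
        if not 1 <= day <= len(self):
            raise IndexError(f"day {day} outside cycle of length {len(self)}")
        return float(self.values[day - 1])


@dataclass(frozen=True)
class LhSeries:
    """Daily LH test results over a cycle.

    At most one positive day: testing stops at the first positive result.
    """

    results: tuple[LhResult, ...]

    def __post_init__(self) -> None:
        results = tuple(LhResult(r) for r in self.results)
        object.__setattr__(self, "results", results)
        if sum(r is LhResult.POSITIVE for r in results) > 1:
            raise ValueError("LH series cannot contain more than one positive day")

    def __len__(self) -> int:
        return len(self.results)

    @property
    def positive_day(self) -> Optional[int]:
        """1-based day of the positive test, or None."""
        for i, r in enumerate(self.results):
            if r is LhResult.POSITIVE:
                return i + 1
        return None

    @property
    def n_performed(self) -> int:
        return sum(r is not LhResult.NOT_PERFORMED for r in self.results)


@dataclass(frozen=True)
class OvulationCall:
    """Reference-standard ovulation status of one cycle."""

    ovulatory: bool
    ovulation_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ovulatory != (self.ovulation_day is not None):
            raise ValueError("ovulation_day must be present iff the cycle is ovulatory")


@dataclass(frozen=True)
class Cycle:
    """One menstrual cycle with both temperature modalities and LH record.

    ``call`` is None when no LH test was performed (reference standard
    missing); such cycles fail quality control.
    """

    participant_id: str
    cycle_index: int
    wrist: DailySeries
    bbt: DailySeries
    lh: LhSeries
    call: Optional[OvulationCall] = field(default=None)

    def __post_init__(self) -> None:
        L = len(self.wrist)
        if L < 1:
            raise ValueError("cycle length must be >= 1")
        if len(self.bbt) != L or len(self.lh) != L:
            raise ValueError("wrist, bbt and lh series must all have the cycle length")
        if self.call is not None and self.call.ovulatory:
            ov = self.call.ovulation_day
            if not 1 < ov <= L:
                raise ValueError(f"ovulation day {ov} outside (1, {L}]")

    @property
    def length(self) -> int:
        return len(self.wrist)

    @classmethod
    def from_series(
        cls,
        participant_id: str,
        cycle_index: int,
        wrist: DailySeries,
        bbt: DailySeries,
        lh: LhSeries,
    ) -> "Cycle":
        """Build a cycle, deriving the ovulation call from the LH record."""
        try:
            call = assign_ovulation(lh, len(wrist))
        except ReferenceStandardMissing:
            call = None
        return cls(participant_id, cycle_index, wrist, bbt, lh, call)

    def series(self, modality: Modality | str) -> DailySeries:
        modality = Modality(modality)
        return self.wrist if modality is Modality.WRIST else self.bbt


@dataclass(frozen=True)
class DayInterval:
    """Inclusive interval of 1-based cycle days; empty when start > end."""

    start: int
    end: int

    @property
    def empty(self) -> bool:
        return self.start > self.end

    @property
    def n_days(self) -> int:
        return 0 if self.empty else self.end - self.start + 1

    def days(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def slice(self) -> slice:
        """Slice selecting this interval from a day-1-first vector."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class PhaseWindows:
    """The three analysis phases of an ovulatory cycle.

    menstrual: days 1–5 (truncated at short cycles); preovulatory: the 10
    days before ovulation through the ovulation day; postovulatory: the 10
    days after ovulation, truncated at cycle end.  Menstrual and
    preovulatory windows may overlap when ovulation is early; the phases
    are analysed independently.
    """

    menstrual: DayInterval
    preovulatory: DayInterval
    postovulatory: DayInterval


@dataclass(frozen=True)
class QcConfig:
    """Quality-control thresholds.

    ``max_missing_fraction``: a cycle is dropped when the fraction of
    missing days in either temperature series reaches this value
    (inclusive, i.e. drop iff fraction >= threshold).
    """

    max_missing_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in (0, 1]")


@dataclass(frozen=True)
class QcDecision:
    keep: bool
    reasons: tuple[str, ...] = ()


def assign_ovulation(lh: LhSeries, L: int) -> OvulationCall:
    """Derive the reference-standard ovulation call from the LH record.

    The day after the (single) positive LH test is the ovulation day.  A
    cycle with only negative tests is anovulatory.  Raises
    :class:`ReferenceStandardMissing` when no test was performed at all.
    """
    if len(lh) != L:
        raise ValueError(f"LH series length {len(lh)} != cycle length {L}")
    p = lh.positive_day
    if p is not None:
        ov = p + 1
        if ov > L:
            raise ValueError(
                f"LH positive on the last cycle day {p}: ovulation day {ov} falls "
                f"outside the cycle"
            )
        return OvulationCall(ovulatory=True, ovulation_day=ov)
    if lh.n_performed == 0:
        raise ReferenceStandardMissing("no LH test performed in the cycle")
    return OvulationCall(ovulatory=False)


def qc_cycle(cycle: Cycle, cfg: QcConfig = QcConfig()) -> QcDecision:
    """Apply the exclusion rules to one cycle.

    Drop when the reference standard is missing or when either modality has
    at least ``cfg.max_missing_fraction`` of its days missing.
    """
    reasons: list[str] = []
    if cycle.call is None:
        reasons.append("reference standard missing")
    for name, series in (("wrist", cycle.wrist), ("bbt", cycle.bbt)):
        frac = series.missing_fraction
        if frac >= cfg.max_missing_fraction:
            reasons.append(
                f"{name} missing fraction {frac:.3f} >= {cfg.max_missing_fraction:.2f}"
            )
    return QcDecision(keep=not reasons, reasons=tuple(reasons))


def phase_windows(L: int, ov: int) -> PhaseWindows:
    """Phase windows for an ovulatory cycle of length ``L`` ovulating on ``ov``."""
    if not 1 < ov <= L:
        raise ValueError(f"ovulation day {ov} outside (1, {L}]")
    return PhaseWindows(
        menstrual=DayInterval(1, min(5, L)),
        preovulatory=DayInterval(max(1, ov - 10), ov),
        postovulatory=DayInterval(ov + 1, min(ov + 10, L)),
    )


def follicular_luteal_split(L: int, ov: int) -> tuple[DayInterval, DayInterval, int]:
    """Split the cycle at ovulation.

    Follicular phase = days 1..ov (ovulation day included), luteal phase =
    days ov+1..L, so the luteal length is ``L - ov``.  An ovulation call on
    the last cycle day leaves an empty luteal phase, which is flagged with
    a warning rather than rejected.
    """
    if not 1 < ov <= L:
        raise ValueError(f"ovulation day {ov} outside (1, {L}]")
    follicular = DayInterval(1, ov)
    luteal = DayInterval(ov + 1, L)
    if luteal.empty:
        warnings.warn(
            f"ovulation on the last cycle day ({ov}): empty luteal phase",
            stacklevel=2,
        )
    return follicular, luteal, L - ov
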