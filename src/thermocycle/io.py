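"""CSV and config I/O.

File formats (UTF-8, header row required):

``cycles.csv``
    participant_id, cycle_index, cycle_day, wrist_temp_c, bbt_c, lh_result.
    Empty temperature cells are missing days; lh_result is one of
    ``pos``/``neg``/``na``.

``nights.csv``
    participant_id, cycle_index, cycle_day, t_offset_s, temp_c, sorted by
    t_offset_s within a night.

Config files are YAML mappings, e.g. ``qc: {max_missing_fraction: 0.3}``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .core import Cycle, DailySeries, LhSeries, Modality, QcConfig
from .night import NightlyRecording

__all__ = [
    "read_cycles_csv",
    "write_cycles_csv",
    "cycles_from_frame",
    "frame_from_cycles",
    "read_nights_csv",
    "iter_nights",
    "write_nights_csv",
    "read_config",
]

CYCLE_COLUMNS = ["participant_id", "cycle_index", "cycle_day",
                 "wrist_temp_c", "bbt_c", "lh_result"]
NIGHT_COLUMNS = ["participant_id", "cycle_index", "cycle_day", "t_offset_s", "temp_c"]


def read_cycles_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily-level cycles table, validating columns and LH codes."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in CYCLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cycles file {path} lacks columns: {missing}")
    bad = set(df["lh_result"].dropna().unique()) - {"pos", "neg", "na"}
    if bad:
        raise ValueError(f"unknown lh_result codes: {sorted(bad)}")
    df["lh_result"] = df["lh_result"].fillna("na")
    return df


def write_cycles_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=CYCLE_COLUMNS)


def cycles_from_frame(df: pd.DataFrame) -> list[Cycle]:
    """Build :class:`Cycle` objects from a daily-level table.

    Days must run 1..L without gaps within each (participant, cycle); the
    ovulation call is derived from the LH record (None when no test was
    performed).
    """
    cycles = []
    for (pid, ci), g in df.groupby(["participant_id", "cycle_index"], sort=True):
        g = g.sort_values("cycle_day")
        days = g["cycle_day"].to_numpy()
        L = len(g)
        if not np.array_equal(days, np.arange(1, L + 1)):
            raise ValueError(
                f"cycle ({pid}, {ci}): days must be consecutive from 1, got "
                f"{days.min()}..{days.max()} over {L} rows"
            )
        cycles.append(Cycle.from_series(
            str(pid), int(ci),
            DailySeries(Modality.WRIST, g["wrist_temp_c"].to_numpy(float)),
            DailySeries(Modality.BBT, g["bbt_c"].to_numpy(float)),
            LhSeries(tuple(g["lh_result"].tolist())),
        ))
    return cycles


def frame_from_cycles(cycles: list[Cycle]) -> pd.DataFrame:
    rows = []
    for c in cycles:
        for day in range(1, c.length + 1):
            rows.append({
                "participant_id": c.participant_id,
                "cycle_index": c.cycle_index,
                "cycle_day": day,
                "wrist_temp_c": c.wrist.values[day - 1],
                "bbt_c": c.bbt.values[day - 1],
                "lh_result": c.lh.results[day - 1].value,
            })
    return pd.DataFrame(rows, columns=CYCLE_COLUMNS)


def iter_nights(df: pd.DataFrame, max_gap_s: float = 600.0) -> Iterator[NightlyRecording]:
    """Yield one recording per (participant, cycle, day) from a nights table.

    Sensor dropouts longer than ``max_gap_s`` split the stream; the longest
    contiguous segment is kept.
    """
    missing = [c for c in NIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"nights table lacks columns: {missing}")
    for (pid, ci, day), g in df.groupby(
        ["participant_id", "cycle_index", "cycle_day"], sort=True
    ):
        g = g.sort_values("t_offset_s")
        yield NightlyRecording.from_offsets(
            str(pid), int(ci), int(day),
            g["t_offset_s"].to_numpy(float), g["temp_c"].to_numpy(float),
            max_gap_s=max_gap_s,
        )


def read_nights_csv(path: str | Path, max_gap_s: float = 600.0) -> Iterator[NightlyRecording]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    yield from iter_nights(df, max_gap_s=max_gap_s)


def write_nights_csv(recordings, path: str | Path) -> None:
    """Write recordings to a nights table (offsets regenerated at the interval)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(NIGHT_COLUMNS) + "\n")
        for rec in recordings:
            offs = np.arange(rec.n_samples) * rec.sample_interval_s
            for o, temp in zip(offs, rec.samples):
                fh.write(f"{rec.participant_id},{rec.cycle_index},"
                         f"{rec.cycle_day},{o:g},{temp:.4f}\n")


def read_config(path: str | Path) -> dict:
    """Read a YAML config mapping; returns {} for an empty file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def qc_config_from_mapping(data: dict) -> QcConfig:
    qc = data.get("qc", {})
    return QcConfig(max_missing_fraction=float(qc.get("max_missing_fraction", 0.30)))
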