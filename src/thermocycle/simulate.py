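"""Synthetic cohort generator for the two-modality ovulation-detection pipeline.

Emulates a prospective cohort of healthy women each contributing several
menstrual cycles, with (a) nightly 10-second wrist-temperature streams,
(b) one oral BBT value per day, and (c) a daily urine LH test record.
Defaults reproduce the cohort structure and temperature levels the
analysis assumes: cycle length ~ N(29.5, 4.5) days truncated to [21, 60],
luteal length ~ N(12.2, 1.9) truncated to [3, 20], 1-6 cycles per woman
(mean 3.5), ~12% anovulatory cycles, wrist follicular plateau 35.78 C
(between-participant SD 0.30) with a mean luteal elevation of 0.29 C
(between-cycle SD 0.21), BBT follicular level 36.25 C (SD 0.15) with
elevation 0.26 C (SD 0.10).

The luteal elevation switches on as a logistic ramp centred at the
ovulation day.  LH testing starts at (mean cycle length - 17) days per the
scheduling rule and runs daily until the first positive (the day before
ovulation) or the end of the cycle.

Randomness is hierarchical: one root seed spawns independent substreams
per participant, cycle and night, so enlarging the cohort never perturbs
already-generated participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.special import expit

from .core import LhResult
from .night import NightlyRecording, ReductionConfig, reduce_night

__all__ = ["SimConfig", "SimulatedCohort", "generate_cohort", "generate_night", "degrade"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study-anchored conditions."""

    n_participants: int = 57
    #: P(1..6 cycles per woman); cohort-distribution weights, mean 3.5
    cycles_per_participant_probs: tuple[float, ...] = (
        2 / 57, 5 / 57, 23 / 57, 17 / 57, 9 / 57, 1 / 57,
    )
    p_anovulatory: float = 0.12

    cycle_length_mean: float = 29.5
    cycle_length_sd: float = 4.5
    cycle_length_min: int = 21
    cycle_length_max: int = 60

    luteal_length_mean: float = 12.2
    luteal_length_sd: float = 1.9
    luteal_length_min: int = 3
    luteal_length_max: int = 20

    wrist_follicular_mean: float = 35.78
    wrist_participant_sd: float = 0.30
    wrist_elevation_mean: float = 0.29
    wrist_elevation_sd: float = 0.21
    wrist_day_noise_sd: float = 0.10

    bbt_follicular_mean: float = 36.25
    bbt_participant_sd: float = 0.15
    bbt_elevation_mean: float = 0.26
    bbt_elevation_sd: float = 0.10
    bbt_day_noise_sd: float = 0.15

    #: logistic scale (days) of the luteal elevation onset; 0.5 puts the
    #: 10-90% transition over ~2.2 days around ovulation
    ramp_half_width_days: float = 0.5

    #: nightly stream shape
    sample_interval_s: float = 10.0
    sleep_hours_mean: float = 7.5
    sleep_hours_sd: float = 1.0
    sleep_hours_min: float = 4.0
    sleep_hours_max: float = 10.0
    ramp_minutes: float = 90.0
    ramp_depth_c: float = 1.5
    decline_minutes: float = 20.0
    decline_depth_c: float = 0.8
    night_noise_sd: float = 0.05
    night_noise_rho: float = 0.95

    p_missing_night: float = 0.10
    p_missing_bbt: float = 0.10

    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.cycles_per_participant_probs, float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("cycles-per-participant probabilities must sum to 1")
        for name in ("p_anovulatory", "p_missing_night", "p_missing_bbt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "cycle_length_sd", "luteal_length_sd", "wrist_participant_sd",
            "wrist_elevation_sd", "wrist_day_noise_sd", "bbt_participant_sd",
            "bbt_elevation_sd", "bbt_day_noise_sd", "night_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # an ovulation day needs room: luteal length is capped at L - 2
        if self.luteal_length_min > self.cycle_length_min - 2:
            raise ValueError(
                "luteal_length_min exceeds cycle_length_min - 2: no valid "
                "ovulation day exists for the shortest cycles"
            )
        if not -1.0 < self.night_noise_rho < 1.0:
            raise ValueError("night_noise_rho must be in (-1, 1)")

    @property
    def lh_start_day(self) -> int:
        """Scheduled first LH test day: mean cycle length minus 17 days."""
        return max(1, int(round(self.cycle_length_mean - 17.0)))


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated cohort: daily-level data plus the generating truth."""

    cycles: pd.DataFrame  # participant_id, cycle_index, cycle_day, wrist_temp_c, bbt_c, lh_result
    truth: pd.DataFrame   # per-cycle generating parameters


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: Optional[int] = None):
    if sd == 0:
        value = np.clip(mean, lo, hi)
        return value if size is None else np.full(size, value)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -rho], innov)


def generate_night(
    day_mean: float, cfg: SimConfig, rng: np.random.Generator,
    participant_id: str = "P000", cycle_index: int = 0, cycle_day: int = 1,
    max_retries: int = 10,
) -> NightlyRecording:
    """One night's 10-second stream whose sleep plateau sits at ``day_mean``.

    The stream rises from ``day_mean - ramp_depth_c`` to the plateau over
    the first ``ramp_minutes`` (a logistic ramp rescaled to reach the
    plateau exactly), holds the plateau with stationary AR(1) noise, and
    declines linearly over the final ``decline_minutes`` — so the standard
    90/30-minute trim isolates the plateau.
    """
    dur_h = 0.0
    for _ in range(max_retries):
        dur_h = float(_trunc_normal(rng, cfg.sleep_hours_mean, cfg.sleep_hours_sd,
                                    cfg.sleep_hours_min, cfg.sleep_hours_max))
        if dur_h >= 1.0:
            break
    else:
        raise ValueError("could not draw a sleep duration of at least 1 hour")
    n = max(2, int(round(dur_h * 3600.0 / cfg.sample_interval_s)))
    t = np.arange(n) * cfg.sample_interval_s
    temps = np.full(n, day_mean, dtype=float)

    ramp_s = min(cfg.ramp_minutes * 60.0, t[-1])
    in_ramp = t < ramp_s
    if ramp_s > 0 and in_ramp.any():
        # logistic shape rescaled to run exactly from 0 to 1 over the ramp
        a = 10.0
        u = t[in_ramp] / ramp_s
        s = (expit(a * (u - 0.5)) - expit(-a / 2)) / (expit(a / 2) - expit(-a / 2))
        temps[in_ramp] = day_mean - cfg.ramp_depth_c * (1.0 - s)

    decline_n = int(round(cfg.decline_minutes * 60.0 / cfg.sample_interval_s))
    if 0 < decline_n < n:
        frac = np.linspace(0.0, 1.0, decline_n)
        temps[n - decline_n:] -= cfg.decline_depth_c * frac

    temps = temps + _ar1(n, cfg.night_noise_sd, cfg.night_noise_rho, rng)
    return NightlyRecording(
        participant_id, cycle_index, cycle_day,
        np.clip(temps, 25.0, 42.0), cfg.sample_interval_s,
    )


def _elevation_profile(L: int, ov: Optional[int], width: float) -> np.ndarray:
    """Logistic ramp 0 -> 1 centred at the ovulation day; zeros if anovulatory."""
    days = np.arange(1, L + 1, dtype=float)
    if ov is None:
        return np.zeros(L)
    if width <= 0:
        return (days > ov).astype(float)
    return expit((days - ov) / width)


def _lh_results(L: int, surge_day: Optional[int], start_day: int) -> list[str]:
    """Daily LH record: not-performed before testing starts, negative until
    the surge, positive on the surge day, nothing after (testing stops)."""
    results = [LhResult.NOT_PERFORMED.value] * L
    if surge_day is not None:
        # ensure the reference standard captures the surge
        start = min(start_day, surge_day)
        for d in range(start, surge_day):
            results[d - 1] = LhResult.NEGATIVE.value
        results[surge_day - 1] = LhResult.POSITIVE.value
    else:
        for d in range(start_day, L + 1):
            results[d - 1] = LhResult.NEGATIVE.value
    return results


def generate_cohort(
    cfg: SimConfig = SimConfig(),
    reduction: Optional[ReductionConfig] = None,
    night_sink: Optional[Callable[[NightlyRecording], None]] = None,
) -> SimulatedCohort:
    """Generate a full cohort of daily-level cycle data.

    When ``reduction`` is given, each non-missing night's 10-second stream
    is generated and reduced with the full nightly pipeline to produce the
    daily wrist value; otherwise the daily wrist value is the plateau level
    itself (fast path — the nightly reduction recovers the plateau up to a
    small constant offset).  ``night_sink`` receives every generated
    :class:`NightlyRecording` (e.g. to write a nights file); passing a sink
    forces night generation even without a reduction config.

    Fully reproducible: the same config (including seed) yields identical
    output, and participant substreams are independent of cohort size.
    """
    cycle_rows: list[dict] = []
    truth_rows: list[dict] = []
    make_nights = reduction is not None or night_sink is not None
    red_cfg = reduction if reduction is not None else ReductionConfig()

    for pi in range(cfg.n_participants):
        pid = f"P{pi + 1:03d}"
        rng_p = np.random.default_rng([cfg.seed, pi])
        n_cycles = int(rng_p.choice(
            np.arange(1, len(cfg.cycles_per_participant_probs) + 1),
            p=cfg.cycles_per_participant_probs,
        ))
        wrist_base = float(rng_p.normal(cfg.wrist_follicular_mean, cfg.wrist_participant_sd))
        bbt_base = float(rng_p.normal(cfg.bbt_follicular_mean, cfg.bbt_participant_sd))

        for ci in range(1, n_cycles + 1):
            rng_c = np.random.default_rng([cfg.seed, pi, ci])
            L = int(round(float(_trunc_normal(
                rng_c, cfg.cycle_length_mean, cfg.cycle_length_sd,
                cfg.cycle_length_min, cfg.cycle_length_max))))
            L = int(np.clip(L, cfg.cycle_length_min, cfg.cycle_length_max))
            anovulatory = bool(rng_c.random() < cfg.p_anovulatory)
            if anovulatory:
                ov = surge = None
                luteal = None
                w_elev = b_elev = 0.0
            else:
                luteal = int(round(float(_trunc_normal(
                    rng_c, cfg.luteal_length_mean, cfg.luteal_length_sd,
                    cfg.luteal_length_min, cfg.luteal_length_max))))
                luteal = int(np.clip(luteal, cfg.luteal_length_min,
                                     min(cfg.luteal_length_max, L - 2)))
                ov = L - luteal
                surge = ov - 1
                w_elev = float(rng_c.normal(cfg.wrist_elevation_mean, cfg.wrist_elevation_sd))
                b_elev = float(rng_c.normal(cfg.bbt_elevation_mean, cfg.bbt_elevation_sd))

            prof = _elevation_profile(L, ov, cfg.ramp_half_width_days)
            wrist_daily = (wrist_base + w_elev * prof
                           + rng_c.normal(0.0, cfg.wrist_day_noise_sd, L))
            bbt_daily = (bbt_base + b_elev * prof
                         + rng_c.normal(0.0, cfg.bbt_day_noise_sd, L))

            miss_night = rng_c.random(L) < cfg.p_missing_night
            miss_bbt = rng_c.random(L) < cfg.p_missing_bbt
            lh = _lh_results(L, surge, cfg.lh_start_day)

            for day in range(1, L + 1):
                if miss_night[day - 1]:
                    wrist_val = np.nan
                elif make_nights:
                    rng_n = np.random.default_rng([cfg.seed, pi, ci, day])
                    rec = generate_night(float(wrist_daily[day - 1]), cfg, rng_n,
                                         pid, ci, day)
                    if night_sink is not None:
                        night_sink(rec)
                    wrist_val = (reduce_night(rec, red_cfg)
                                 if reduction is not None
                                 else float(wrist_daily[day - 1]))
                else:
                    wrist_val = float(wrist_daily[day - 1])
                cycle_rows.append({
                    "participant_id": pid,
                    "cycle_index": ci,
                    "cycle_day": day,
                    "wrist_temp_c": wrist_val,
                    "bbt_c": np.nan if miss_bbt[day - 1] else float(bbt_daily[day - 1]),
                    "lh_result": lh[day - 1],
                })
            truth_rows.append({
                "participant_id": pid,
                "cycle_index": ci,
                "length": L,
                "ovulatory": not anovulatory,
                "ovulation_day": ov if ov is not None else pd.NA,
                "lh_surge_day": surge if surge is not None else pd.NA,
                "luteal_length": luteal if luteal is not None else pd.NA,
                "wrist_elevation": w_elev,
                "bbt_elevation": b_elev,
                "wrist_baseline": wrist_base,
                "bbt_baseline": bbt_base,
            })

    cycles = pd.DataFrame(cycle_rows)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(cycles=cycles, truth=truth)


def degrade(
    cycles: pd.DataFrame,
    p_missing_night: float,
    p_missing_bbt: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Apply independent per-day Bernoulli dropout to each modality.

    Returns a copy of the daily table with additional wrist / BBT values
    set to missing.  With p = 0 the data are unchanged; with p = 1 every
    day is missing and every cycle fails quality control downstream.
    """
    for name, p in (("p_missing_night", p_missing_night),
                    ("p_missing_bbt", p_missing_bbt)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    out = cycles.copy()
    n = len(out)
    drop_w = rng.random(n) < p_missing_night
    drop_b = rng.random(n) < p_missing_bbt
    out.loc[drop_w, "wrist_temp_c"] = np.nan
    out.loc[drop_b, "bbt_c"] = np.nan
    return out
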