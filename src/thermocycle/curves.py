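"""Phase-level curve statistics for ovulatory cycles.

Covers per-cycle follicular/luteal means and the between-phase change,
repeated-measures correlation (implemented from its ANCOVA definition),
mixed-model estimation of daily temperature curves within a phase, daily
differences between modality curves, and the cross-tabulation of
biphasic/monophasic patterns between the two modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cycle, Modality, follicular_luteal_split, phase_windows
from .night import ReductionConfig, smooth_stream
from .shifts import ShiftResult

__all__ = [
    "PhaseSummary",
    "RmcorrResult",
    "DailyCurve",
    "AgreementCategories",
    "phase_summary",
    "rmcorr",
    "estimate_daily_curve",
    "daily_difference",
    "agreement_categories",
    "smooth_display_curve",
]


@dataclass(frozen=True)
class PhaseSummary:
    """Per-cycle phase means for one modality (non-missing days only)."""

    participant_id: str
    cycle_index: int
    modality: Modality
    follicular_mean: float
    luteal_mean: float

    @property
    def between_phase_change(self) -> float:
        return self.luteal_mean - self.follicular_mean


def phase_summary(cycle: Cycle, modality: Modality | str) -> Optional[PhaseSummary]:
    """Follicular and luteal means of one modality for an ovulatory cycle.

    Returns None when either phase has no non-missing day (the summary is
    absent for that cycle).  Raises for anovulatory cycles, whose phases
    are undefined.
    """
    if cycle.call is None or not cycle.call.ovulatory:
        raise ValueError("phase summary requires an ovulatory cycle")
    modality = Modality(modality)
    series = cycle.series(modality)
    foll, lut, _ = follicular_luteal_split(cycle.length, cycle.call.ovulation_day)
    means = []
    for interval in (foll, lut):
        vals = series.values[interval.slice()]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return None
        means.append(float(vals.mean()))
    return PhaseSummary(
        participant_id=cycle.participant_id,
        cycle_index=cycle.cycle_index,
        modality=modality,
        follicular_mean=means[0],
        luteal_mean=means[1],
    )


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures correlation: the common within-participant association."""

    r: float
    df: int
    p: float
    ci95: tuple[float, float]
    n_obs: int
    n_participants: int


def rmcorr(
    participants: Sequence,
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
) -> RmcorrResult:
    """Repeated-measures correlation from its ANCOVA definition.

    Fits the common-slope model y ~ participant intercepts + x by centering
    x and y within participant; with SS_x the covariate sum of squares
    explained by the common slope and SS_e the residual sum of squares,

        r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_e)),  df = N - k - 1,

    where N is the number of paired observations and k the number of
    participants.  p comes from F(1, df) = r^2 / (1 - r^2) * df, and the
    CI from the Fisher z-transform with standard error 1/sqrt(df - 1).

    Participants with fewer than 2 observations carry no within-participant
    information and are dropped with a warning.  A single participant
    degenerates to the Pearson correlation of that participant's points
    (df = N - 2), allowed with a warning.
    """
    df_in = pd.DataFrame(
        {"pid": list(participants), "x": np.asarray(x, float), "y": np.asarray(y, float)}
    ).dropna()
    sizes = df_in.groupby("pid")["x"].size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(
            f"dropping {len(small)} participant(s) with fewer than 2 observations",
            stacklevel=2,
        )
        df_in = df_in[~df_in["pid"].isin(small)]
    if df_in.empty:
        raise ValueError("no participant has 2 or more paired observations")
    k = df_in["pid"].nunique()
    N = len(df_in)
    if k == 1:
        warnings.warn(
            "single participant: repeated-measures correlation degenerates to "
            "the Pearson correlation",
            stacklevel=2,
        )
    xc = df_in["x"] - df_in.groupby("pid")["x"].transform("mean")
    yc = df_in["y"] - df_in.groupby("pid")["y"].transform("mean")
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("x has no within-participant variation")
    slope = float(np.sum(xc * yc)) / sxx
    ss_x = slope**2 * sxx
    resid = yc - slope * xc
    ss_e = float(np.sum(resid**2))
    dof = N - k - 1
    if dof < 1:
        raise ValueError(f"non-positive degrees of freedom (N={N}, k={k})")
    denom = ss_x + ss_e
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_x / denom)
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - r**2 <= 0:
        p = 0.0
    else:
        f_stat = r**2 / (1.0 - r**2) * dof
        p = float(stats.f.sf(f_stat, 1, dof))
    ci = _fisher_ci(r, dof, alpha)
    return RmcorrResult(r=r, df=dof, p=p, ci95=ci, n_obs=N, n_participants=k)


def _fisher_ci(r: float, dof: int, alpha: float) -> tuple[float, float]:
    if abs(r) >= 1.0 or dof <= 1:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(dof - 1)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))


@dataclass(frozen=True)
class DailyCurve:
    """Estimated mean temperature per phase-relative day, with 95% CI."""

    phase: str
    modality: Modality
    days: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    model: str  # which model variant produced the estimates

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.estimate) == len(self.ci_low) == len(self.ci_high) == n):
            raise ValueError("curve arrays must have equal length")
        if np.any(self.ci_low > self.estimate + 1e-12) or np.any(
            self.ci_high < self.estimate - 1e-12
        ):
            raise ValueError("CI must contain the estimate")


def estimate_daily_curve(
    observations: pd.DataFrame,
    phase: str,
    modality: Modality | str,
    min_participants: int = 5,
    min_cycles_per_day: int = 3,
) -> DailyCurve:
    """Estimate the mean daily temperature curve within a phase.

    ``observations`` needs columns ``participant``, ``cycle``,
    ``phase_day`` (integer, phase-relative) and ``temp``.  Day is modeled
    as categorical, so each day's fixed effect is directly the estimated
    mean temperature on that day.  The hierarchy — days within cycles
    within participants — enters through a participant random intercept
    and slope (on the numeric day) plus a cycle-within-participant random
    intercept.  A singular fit falls back to random intercepts only, then
    to a participant-intercept-only model; degenerate zero-variance data
    return the exact day means with zero-width CIs.
    """
    modality = Modality(modality)
    df = observations.dropna(subset=["temp"]).copy()
    if df["participant"].nunique() < min_participants:
        raise ValueError(f"need at least {min_participants} participants")
    per_day = df.groupby("phase_day")["cycle"].count()
    if (per_day < min_cycles_per_day).any():
        thin = per_day[per_day < min_cycles_per_day].index.tolist()
        raise ValueError(f"phase days {thin} observed in fewer than "
                         f"{min_cycles_per_day} cycles")
    days = np.sort(df["phase_day"].unique())

    if np.ptp(df["temp"].to_numpy()) == 0.0:
        # no variance anywhere: the day means are exact, CIs are degenerate
        est = df.groupby("phase_day")["temp"].mean().reindex(days).to_numpy()
        return DailyCurve(phase, modality, days, est, est.copy(), est.copy(),
                          model="degenerate")

    import statsmodels.formula.api as smf

    df["day_cat"] = pd.Categorical(df["phase_day"], categories=days)
    df["day_num"] = df["phase_day"] - df["phase_day"].mean()
    df["cycle_label"] = df["cycle"].astype(str)

    attempts = [
        ("ri+rs participant, ri cycle", "1 + day_num", {"cyc": "0 + C(cycle_label)"}),
        ("ri participant, ri cycle", "1", {"cyc": "0 + C(cycle_label)"}),
        ("ri participant", "1", None),
    ]
    fit = None
    used = None
    for label, re_formula, vc in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "temp ~ 0 + day_cat",
                    df,
                    groups=df["participant"],
                    re_formula=re_formula,
                    vc_formula=vc,
                )
                cand = model.fit(reml=True, method="lbfgs")
            if np.all(np.isfinite(cand.bse_fe)):
                fit, used = cand, label
                break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        # last resort: raw means with normal-theory CIs
        g = df.groupby("phase_day")["temp"]
        est = g.mean().reindex(days).to_numpy()
        se = (g.std(ddof=1) / np.sqrt(g.count())).reindex(days).to_numpy()
        se = np.nan_to_num(se)
        return DailyCurve(phase, modality, days, est, est - 1.96 * se,
                          est + 1.96 * se, model="raw means")

    names = [f"day_cat[{d}]" for d in days]
    est = np.array([fit.fe_params[n] for n in names])
    se = np.array([fit.bse_fe[n] for n in names])
    return DailyCurve(
        phase,
        modality,
        days,
        est,
        est - 1.96 * se,
        est + 1.96 * se,
        model=used,
    )


def daily_difference(a: DailyCurve, b: DailyCurve) -> tuple[pd.DataFrame, float]:
    """Elementwise curve difference a - b and its mean over days."""
    if a.phase != b.phase:
        raise ValueError(f"phases differ: {a.phase!r} vs {b.phase!r}")
    if len(a.days) != len(b.days) or np.any(a.days != b.days):
        raise ValueError("curves are indexed by different days")
    diff = a.estimate - b.estimate
    out = pd.DataFrame({"phase_day": a.days, "difference": diff})
    return out, float(diff.mean())


@dataclass(frozen=True)
class AgreementCategories:
    """Cross-tabulation of curve patterns between the two modalities."""

    both_monophasic: int
    wrist_only_biphasic: int
    bbt_only_biphasic: int
    both_biphasic: int

    @property
    def total(self) -> int:
        return (
            self.both_monophasic
            + self.wrist_only_biphasic
            + self.bbt_only_biphasic
            + self.both_biphasic
        )

    @property
    def wrist_biphasic(self) -> int:
        return self.wrist_only_biphasic + self.both_biphasic

    @property
    def bbt_biphasic(self) -> int:
        return self.bbt_only_biphasic + self.both_biphasic


def agreement_categories(
    wrist_results: Sequence[ShiftResult], bbt_results: Sequence[ShiftResult]
) -> AgreementCategories:
    """Count cycles by (wrist pattern, BBT pattern) over the same cycle set."""
    if len(wrist_results) != len(bbt_results):
        raise ValueError("need one wrist and one BBT result per cycle")
    counts = {"mm": 0, "wm": 0, "mb": 0, "bb": 0}
    for w, b in zip(wrist_results, bbt_results):
        if w.biphasic and b.biphasic:
            counts["bb"] += 1
        elif w.biphasic:
            counts["wm"] += 1
        elif b.biphasic:
            counts["mb"] += 1
        else:
            counts["mm"] += 1
    return AgreementCategories(
        both_monophasic=counts["mm"],
        wrist_only_biphasic=counts["wm"],
        bbt_only_biphasic=counts["mb"],
        both_biphasic=counts["bb"],
    )


def smooth_display_curve(days: np.ndarray, temps: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """LOWESS display smoothing of a cycle-level curve (not used in statistics)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    days = np.asarray(days, float)
    temps = np.asarray(temps, float)
    return lowess(temps, days, frac=frac, it=0, return_sorted=False)
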