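"""Diagnostic accuracy of a shift-based temperature test against the LH standard.

A cycle tests positive when its daily temperature curve shows at least one
temperature shift; the condition is ovulation by the LH reference
standard.  Sensitivity, specificity and predictive values come with 95%
binomial confidence intervals (Clopper-Pearson by default, Wilson as an
option).  Because cycles are nested within participants, a cluster
bootstrap resampling participants is available as a sensitivity analysis,
and paired comparisons between the two modalities on the same cycles use
the exact McNemar test on discordant pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "MeasureWithCI",
    "AccuracyMeasures",
    "build_confusion",
    "accuracy_measures",
    "proportion_ci",
    "compare_paired",
    "cluster_bootstrap_ci",
]

_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: test = ">=1 temperature shift", condition = "ovulatory by LH"."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one cycle")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MeasureWithCI:
    """A proportion with its 95% CI and the (k, n) it came from."""

    value: float
    ci_low: float
    ci_high: float
    k: int
    n: int


@dataclass(frozen=True)
class AccuracyMeasures:
    """Derived accuracy measures; a measure is None when its denominator is 0."""

    sensitivity: Optional[MeasureWithCI]
    specificity: Optional[MeasureWithCI]
    ppv: Optional[MeasureWithCI]
    npv: Optional[MeasureWithCI]
    tp_rate: float
    fp_rate: float
    table: ConfusionTable


def build_confusion(flags: Sequence[tuple[bool, bool]]) -> ConfusionTable:
    """Cross-tabulate per-cycle (has_shift, ovulatory) flags."""
    if len(flags) == 0:
        raise ValueError("cannot build a confusion table from no cycles")
    tp = fp = tn = fn = 0
    for has_shift, ovulatory in flags:
        if has_shift and ovulatory:
            tp += 1
        elif has_shift:
            fp += 1
        elif ovulatory:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def proportion_ci(
    k: int, n: int, method: str = "clopper_pearson", alpha: float = 0.05
) -> tuple[float, float]:
    """95% (by default) binomial CI for a proportion k/n.

    ``method`` is "clopper_pearson" (exact, beta quantiles) or "wilson"
    (score interval).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=_CI_METHODS[method])
    return float(lo), float(hi)


def _measure(k: int, n: int, ci_method: str) -> Optional[MeasureWithCI]:
    if n == 0:
        return None
    lo, hi = proportion_ci(k, n, ci_method)
    return MeasureWithCI(value=k / n, ci_low=lo, ci_high=hi, k=k, n=n)


def accuracy_measures(
    t: ConfusionTable, ci_method: str = "clopper_pearson"
) -> AccuracyMeasures:
    """Sensitivity, specificity, PPV, NPV with CIs, plus TP/FP rates.

    Ratios are kept at full precision; rounding happens only at
    presentation.  A measure whose denominator is zero is reported as
    absent (None), never coerced to 0.
    """
    return AccuracyMeasures(
        sensitivity=_measure(t.tp, t.tp + t.fn, ci_method),
        specificity=_measure(t.tn, t.tn + t.fp, ci_method),
        ppv=_measure(t.tp, t.tp + t.fp, ci_method),
        npv=_measure(t.tn, t.tn + t.fn, ci_method),
        tp_rate=t.tp / t.total,
        fp_rate=t.fp / t.total,
        table=t,
    )


def compare_paired(
    outcomes_a: Sequence[bool],
    outcomes_b: Sequence[bool],
    condition: Sequence[bool],
    stratum: str = "positives",
) -> float:
    """Exact McNemar p-value comparing two tests on the same cycles.

    ``stratum`` selects which cycles enter the comparison: "positives"
    (ovulatory cycles — compares sensitivities) or "negatives"
    (anovulatory — compares specificities).  With discordant counts (b, c)
    the two-sided exact p is min(1, 2 P[Bin(b+c, 1/2) <= min(b, c)]);
    with no discordant pairs p = 1.
    """
    a = np.asarray(outcomes_a, dtype=bool)
    b_arr = np.asarray(outcomes_b, dtype=bool)
    cond = np.asarray(condition, dtype=bool)
    if not (a.size == b_arr.size == cond.size):
        raise ValueError("outcome and condition vectors must have equal length")
    if stratum == "positives":
        sel = cond
    elif stratum == "negatives":
        sel = ~cond
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    b = int(np.sum(a[sel] & ~b_arr[sel]))
    c = int(np.sum(~a[sel] & b_arr[sel]))
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)
    return float(min(1.0, p))


_MEASURE_NUM_DEN = {
    "sensitivity": lambda t: (t.tp, t.tp + t.fn),
    "specificity": lambda t: (t.tn, t.tn + t.fp),
    "ppv": lambda t: (t.tp, t.tp + t.fp),
    "npv": lambda t: (t.tn, t.tn + t.fn),
}


def cluster_bootstrap_ci(
    participant_ids: Sequence,
    has_shift: Sequence[bool],
    ovulatory: Sequence[bool],
    measure: str = "sensitivity",
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI respecting the nested design.

    Participants are resampled with replacement (each drawn participant
    contributes all of their cycles), the measure is recomputed on each of
    ``B`` resamples, and the (alpha/2, 1-alpha/2) percentiles are the
    interval.  Replicates whose denominator is empty are skipped; the
    number skipped is returned as the third element.
    """
    if measure not in _MEASURE_NUM_DEN:
        raise ValueError(f"unknown measure {measure!r}")
    if B < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    df = pd.DataFrame(
        {
            "pid": list(participant_ids),
            "shift": np.asarray(has_shift, dtype=bool),
            "ov": np.asarray(ovulatory, dtype=bool),
        }
    )
    pids = df["pid"].unique()
    if pids.size < 2:
        raise ValueError("cluster bootstrap needs at least 2 participants")
    groups = {pid: g[["shift", "ov"]].to_numpy() for pid, g in df.groupby("pid")}
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    num_den = _MEASURE_NUM_DEN[measure]
    values = []
    skipped = 0
    for _ in range(B):
        draw = rng.choice(pids, size=pids.size, replace=True)
        rows = np.concatenate([groups[pid] for pid in draw])
        t = _table_from_rows(rows)
        if t is None:
            skipped += 1
            continue
        k, n = num_den(t)
        if n == 0:
            skipped += 1
            continue
        values.append(k / n)
    if not values:
        raise ValueError("all bootstrap replicates had empty denominators")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), skipped


def _table_from_rows(rows: np.ndarray) -> Optional[ConfusionTable]:
    shift = rows[:, 0].astype(bool)
    ov = rows[:, 1].astype(bool)
    if rows.shape[0] == 0:
        return None
    return ConfusionTable(
        tp=int(np.sum(shift & ov)),
        fp=int(np.sum(shift & ~ov)),
        tn=int(np.sum(~shift & ~ov)),
        fn=int(np.sum(~shift & ov)),
    )
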