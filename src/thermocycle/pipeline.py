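"""End-to-end composition of the analysis stages.

Glue used by the command line and by scripted analyses: apply quality
control, run shift detection per cycle and modality, assemble the
diagnostic-accuracy summary (the full two-modality table with CIs and
paired tests), and the phase-level curve statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import accuracy as acc
from .core import Cycle, Modality, QcConfig, follicular_luteal_split, phase_windows, qc_cycle
from .curves import (
    agreement_categories,
    daily_difference,
    estimate_daily_curve,
    phase_summary,
    rmcorr,
)
from .shifts import (
    ShiftResult,
    ShiftRuleConfig,
    detect_shifts,
    first_shift_offset,
    shift_count_distribution,
)

__all__ = [
    "apply_qc",
    "detect_all",
    "shift_table",
    "evaluate_accuracy",
    "phase_observations",
    "curve_analysis",
]


def apply_qc(cycles: Sequence[Cycle], qc: QcConfig = QcConfig()) -> tuple[list[Cycle], pd.DataFrame]:
    """Split cycles into kept and a per-cycle QC log."""
    kept, log = [], []
    for c in cycles:
        decision = qc_cycle(c, qc)
        log.append({
            "participant_id": c.participant_id,
            "cycle_index": c.cycle_index,
            "keep": decision.keep,
            "reasons": "; ".join(decision.reasons),
        })
        if decision.keep:
            kept.append(c)
    return kept, pd.DataFrame(log)


def detect_all(
    cycles: Sequence[Cycle],
    modality: Modality | str,
    cfg: ShiftRuleConfig = ShiftRuleConfig(),
) -> list[ShiftResult]:
    modality = Modality(modality)
    return [detect_shifts(c.series(modality), cfg) for c in cycles]


def shift_table(
    cycles: Sequence[Cycle],
    results: Sequence[ShiftResult],
    modality: Modality | str,
) -> pd.DataFrame:
    """Per-cycle shift-detection output table."""
    modality = Modality(modality)
    rows = []
    for c, r in zip(cycles, results):
        rows.append({
            "participant_id": c.participant_id,
            "cycle_index": c.cycle_index,
            "modality": modality.value,
            "n_shifts": r.n_shifts,
            "start_days": ";".join(str(d) for d in r.start_days),
            "pattern": r.pattern,
        })
    return pd.DataFrame(rows)


def _measure_dict(m) -> Optional[dict]:
    if m is None:
        return None
    return {"value": m.value, "ci95": [m.ci_low, m.ci_high], "k": m.k, "n": m.n}


def evaluate_accuracy(
    cycles: Sequence[Cycle],
    wrist_results: Sequence[ShiftResult],
    bbt_results: Sequence[ShiftResult],
    ci_method: str = "clopper_pearson",
    cluster_bootstrap: bool = False,
    bootstrap_B: int = 2000,
    seed: int = 0,
) -> dict:
    """Full diagnostic-accuracy summary for both modalities.

    Cycles must already be QC-passed (each has a reference-standard call).
    Returns a JSON-serialisable dict: per-modality confusion counts,
    accuracy measures with CIs, shift histograms and first-shift offsets
    (ovulatory cycles), plus paired McNemar p-values between modalities.
    """
    if not (len(cycles) == len(wrist_results) == len(bbt_results)):
        raise ValueError("need one wrist and one BBT result per cycle")
    ovulatory = np.array([c.call.ovulatory for c in cycles])
    out: dict = {"n_cycles": len(cycles), "n_ovulatory": int(ovulatory.sum())}
    flags = {}
    for name, results in (("wrist", wrist_results), ("bbt", bbt_results)):
        has_shift = np.array([r.biphasic for r in results])
        flags[name] = has_shift
        table = acc.build_confusion(list(zip(has_shift, ovulatory)))
        measures = acc.accuracy_measures(table, ci_method)
        offsets = [
            first_shift_offset(r, c.call.ovulation_day)
            for c, r in zip(cycles, results)
            if c.call.ovulatory and r.biphasic
        ]
        section = {
            "confusion": {"tp": table.tp, "fp": table.fp,
                          "tn": table.tn, "fn": table.fn},
            "sensitivity": _measure_dict(measures.sensitivity),
            "specificity": _measure_dict(measures.specificity),
            "ppv": _measure_dict(measures.ppv),
            "npv": _measure_dict(measures.npv),
            "tp_rate": measures.tp_rate,
            "fp_rate": measures.fp_rate,
            "shift_histogram_ovulatory": shift_count_distribution(
                r for c, r in zip(cycles, results) if c.call.ovulatory
            ),
            "shift_histogram_anovulatory": shift_count_distribution(
                r for c, r in zip(cycles, results) if not c.call.ovulatory
            ),
            "first_shift_offset_mean": float(np.mean(offsets)) if offsets else None,
            "first_shift_offset_sd": (
                float(np.std(offsets, ddof=1)) if len(offsets) > 1 else None
            ),
        }
        if cluster_bootstrap:
            pids = [c.participant_id for c in cycles]
            section["cluster_bootstrap_ci"] = {}
            for measure in ("sensitivity", "specificity", "ppv", "npv"):
                lo, hi, skipped = acc.cluster_bootstrap_ci(
                    pids, has_shift, ovulatory, measure, B=bootstrap_B, seed=seed,
                )
                section["cluster_bootstrap_ci"][measure] = {
                    "ci95": [lo, hi], "skipped_replicates": skipped,
                }
        out[name] = section
    out["paired_p_sensitivity"] = acc.compare_paired(
        flags["wrist"], flags["bbt"], ovulatory, "positives")
    out["paired_p_specificity"] = acc.compare_paired(
        flags["wrist"], flags["bbt"], ovulatory, "negatives")
    return out


_PHASES = ("menstrual", "preovulatory", "postovulatory")


def phase_observations(
    cycles: Sequence[Cycle], phase: str, modality: Modality | str
) -> pd.DataFrame:
    """Long-format phase-relative observations for curve estimation.

    Phase days are numbered from 1 within each window (for the
    postovulatory phase, day 1 = first day after ovulation).  Only
    ovulatory cycles contribute.
    """
    if phase not in _PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    modality = Modality(modality)
    rows = []
    for c in cycles:
        if c.call is None or not c.call.ovulatory:
            continue
        windows = phase_windows(c.length, c.call.ovulation_day)
        interval = getattr(windows, phase)
        series = c.series(modality)
        for rel, day in enumerate(interval.days(), start=1):
            v = series.values[day - 1]
            if not np.isnan(v):
                rows.append({
                    "participant": c.participant_id,
                    "cycle": f"{c.participant_id}/{c.cycle_index}",
                    "phase_day": rel,
                    "temp": float(v),
                })
    return pd.DataFrame(rows, columns=["participant", "cycle", "phase_day", "temp"])


def curve_analysis(
    cycles: Sequence[Cycle],
    wrist_results: Sequence[ShiftResult],
    bbt_results: Sequence[ShiftResult],
    fit_daily_curves: bool = True,
) -> dict:
    """Phase-level statistics over ovulatory QC-passed cycles.

    Per-modality phase means and between-phase changes, repeated-measures
    correlations of the phase means between modalities, pattern-agreement
    counts, and (optionally) mixed-model daily curves per phase with the
    wrist-minus-BBT daily differences.
    """
    ovulatory = [c for c in cycles if c.call is not None and c.call.ovulatory]
    ov_wrist = [r for c, r in zip(cycles, wrist_results)
                if c.call is not None and c.call.ovulatory]
    ov_bbt = [r for c, r in zip(cycles, bbt_results)
              if c.call is not None and c.call.ovulatory]
    out: dict = {"n_ovulatory": len(ovulatory)}

    summaries: dict[str, dict] = {"wrist": {}, "bbt": {}}
    for name in ("wrist", "bbt"):
        per_cycle = []
        for c in ovulatory:
            s = phase_summary(c, name)
            if s is not None:
                per_cycle.append(s)
        foll = np.array([s.follicular_mean for s in per_cycle])
        lut = np.array([s.luteal_mean for s in per_cycle])
        chg = np.array([s.between_phase_change for s in per_cycle])
        out[name] = {
            "n_cycles_with_phase_means": len(per_cycle),
            "follicular_mean": _mean_sd(foll),
            "luteal_mean": _mean_sd(lut),
            "between_phase_change": _mean_sd(chg),
        }
        summaries[name] = {(s.participant_id, s.cycle_index): s for s in per_cycle}

    # repeated-measures correlations of phase means between modalities
    out["rmcorr"] = {}
    for quantity, attr in (
        ("follicular", "follicular_mean"),
        ("luteal", "luteal_mean"),
        ("between_phase_change", "between_phase_change"),
    ):
        keys = sorted(set(summaries["wrist"]) & set(summaries["bbt"]))
        pids = [k[0] for k in keys]
        x = [getattr(summaries["wrist"][k], attr) for k in keys]
        y = [getattr(summaries["bbt"][k], attr) for k in keys]
        try:
            res = rmcorr(pids, x, y)
            out["rmcorr"][quantity] = {
                "r": res.r, "df": res.df, "p": res.p, "ci95": list(res.ci95),
            }
        except ValueError as exc:
            out["rmcorr"][quantity] = {"error": str(exc)}

    out["agreement"] = _agreement_dict(ov_wrist, ov_bbt)

    if fit_daily_curves:
        out["daily_curves"] = {}
        for phase in _PHASES:
            entry: dict = {}
            curves = {}
            for name in ("wrist", "bbt"):
                obs = phase_observations(ovulatory, phase, name)
                try:
                    curve = estimate_daily_curve(obs, phase, name)
                except ValueError as exc:
                    entry[name] = {"error": str(exc)}
                    continue
                curves[name] = curve
                entry[name] = {
                    "days": curve.days.tolist(),
                    "estimate": np.round(curve.estimate, 4).tolist(),
                    "ci_low": np.round(curve.ci_low, 4).tolist(),
                    "ci_high": np.round(curve.ci_high, 4).tolist(),
                    "model": curve.model,
                }
            if "wrist" in curves and "bbt" in curves:
                common = np.intersect1d(curves["wrist"].days, curves["bbt"].days)
                if common.size:
                    a, b = (_subset_curve(curves["wrist"], common),
                            _subset_curve(curves["bbt"], common))
                    diff, mean_diff = daily_difference(a, b)
                    entry["wrist_minus_bbt"] = {
                        "days": diff["phase_day"].tolist(),
                        "difference": np.round(diff["difference"], 4).tolist(),
                        "mean": mean_diff,
                    }
            out["daily_curves"][phase] = entry
    return out


def _subset_curve(curve, days):
    from .curves import DailyCurve

    idx = np.isin(curve.days, days)
    return DailyCurve(curve.phase, curve.modality, curve.days[idx],
                      curve.estimate[idx], curve.ci_low[idx],
                      curve.ci_high[idx], curve.model)


def _agreement_dict(wrist_results, bbt_results) -> dict:
    cats = agreement_categories(wrist_results, bbt_results)
    return {
        "both_monophasic": cats.both_monophasic,
        "wrist_only_biphasic": cats.wrist_only_biphasic,
        "bbt_only_biphasic": cats.bbt_only_biphasic,
        "both_biphasic": cats.both_biphasic,
    }


def _mean_sd(values: np.ndarray) -> Optional[dict]:
    if values.size == 0:
        return None
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else None,
        "n": int(values.size),
    }
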