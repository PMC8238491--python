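# thermocycle

Detecting ovulation from two temperature modalities: nocturnal **wrist skin
temperature** recorded every 10 seconds by a wearable, and daily oral
**basal body temperature** (BBT) taken on waking. The package implements the
complete comparison pipeline used in diagnostic-accuracy studies of
temperature-based ovulation detection, with urine LH tests as the reference
standard, and ships a synthetic-cohort generator so the whole pipeline can be
exercised end-to-end without any clinical data.

## What it computes

- **Nightly reduction** — each night's 10-s stream is trimmed (first 90 min,
  last 30 min), LOWESS-smoothed, and reduced to its 99th percentile (the
  "stable maxima"), giving one wrist temperature per cycle day. Nights
  shorter than 4 h are unusable.
- **Temperature-shift rule (3-over-6)** — cycle day *d* starts a shift when
  days *d*, *d*+1, *d*+2 are each ≥ 0.2 °C above the highest of the previous
  six days (five-of-six allowed with a missing baseline day), restricted to
  shifts starting in the last 14 days of the cycle. A curve with ≥ 1 shift is
  *biphasic*, otherwise *monophasic*.
- **Reference standard** — the day after the first positive LH test is the
  ovulation day; cycles with only negative tests are anovulatory; cycles with
  no tests, or ≥ 30 % missing days in either modality, are excluded.
- **Diagnostic accuracy** — sensitivity, specificity, PPV, NPV with 95 %
  Clopper–Pearson (or Wilson) CIs; exact McNemar tests for paired modality
  comparisons; an optional cluster bootstrap (resampling participants) that
  respects cycles being nested within women.
- **Curve statistics** — per-cycle follicular/luteal means and between-phase
  change; repeated-measures correlation *r*<sub>rm</sub> implemented from its
  ANCOVA definition (common slope over participant-specific intercepts,
  *r*<sub>rm</sub> = sign(b)·√(SS<sub>x</sub>/(SS<sub>x</sub>+SS<sub>e</sub>)),
  df = N − k − 1); mixed-model daily temperature curves per phase (menstrual
  days 1–5, preovulatory ov−10…ov, postovulatory ov+1…ov+10) and their daily
  differences; pattern-agreement counts between the modalities.
- **Synthetic cohorts** — nested women/cycles/nights with realistic cycle and
  luteal lengths, anovulatory cycles, LH scheduling (testing starts at mean
  cycle length − 17 days), a logistic luteal temperature onset, and
  configurable missingness.

## Worked example

```python
import thermocycle as tc
from thermocycle.io import cycles_from_frame
from thermocycle.pipeline import apply_qc, detect_all, evaluate_accuracy

cohort = tc.generate_cohort(tc.SimConfig(n_participants=57, seed=1),
                            reduction=tc.ReductionConfig())
cycles = cycles_from_frame(cohort.cycles)
kept, _ = apply_qc(cycles)
report = evaluate_accuracy(kept, detect_all(kept, "wrist"), detect_all(kept, "bbt"))
print(report["n_cycles"], report["n_ovulatory"])
print(round(report["wrist"]["sensitivity"]["value"], 3),
      round(report["bbt"]["sensitivity"]["value"], 3))
print(round(report["paired_p_sensitivity"], 3))
```

prints

```
193 170
0.082 0.041
0.118
```

i.e. this seed yields 193 QC-passed cycles of which 170 are ovulatory; the
wrist curve flags a shift in 8.2 % of ovulatory cycles versus 4.1 % for BBT
(wrist more sensitive, exact McNemar p = 0.118 at this cohort size). Under
the generator's default day-to-day noise the 3-over-6 rule fires rarely —
see `docs/methods.md` for why detection rates are governed by the gap
between the 0.2 °C threshold and the luteal elevation relative to the noise.

The same analyses are available from the shell:

```bash
thermocycle simulate --out-dir data/ --seed 1
thermocycle detect   --cycles data/cycles.csv --modality wrist --out shifts_wrist.csv
thermocycle evaluate --cycles data/cycles.csv --out accuracy.json
thermocycle curves   --cycles data/cycles.csv --out curves.json
```

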