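# lumirhythm

Rhythmicity analysis for bioluminescence reporter recordings.

Cultured cells carrying a clock-gene luciferase reporter (e.g. Per2::luc),
synchronized with a dexamethasone pulse and read in a plate luminometer every
12 minutes for three days or more, produce damped ~24 h oscillations riding
on a decaying baseline. `lumirhythm` turns such plate recordings into the
standard circadian readouts — **period**, **amplitude**, **phase**, and an
**R² rhythmicity score** — and ships a synthetic plate generator so the whole
pipeline can be exercised and validated without any instrument data.

## The model

Each well's conditioned trace is fitted with a constant plus one sinusoid,

```
y(t) = c + a·sin(2πt/T) + b·cos(2πt/T)
```

which at fixed period `T` is linear in `(c, a, b)` and solved exactly by
ordinary least squares. The period is profiled: the residual sum of squares
is scanned over `T ∈ [16, 40] h` in 0.05 h steps and the best bracket is
refined by golden-section search to 0.001 h. Reported are

* `period_h = T` (hours),
* `amplitude = √(a² + b²)` (counts; the pipeline additionally reports this
  corrected for the known attenuation of the conditioning filters),
* `phase_h` — the hour in `[0, T)` of the fitted sinusoid's first ascending
  zero-crossing,
* `R² = 1 − SSE/SST` — how closely the trace follows a sinusoid.

Before fitting, each trace is **detrended** (minus a centered 24 h running
mean, removing proliferation and signal-decline baseline) and **denoised**
(2 h centered moving average). Technical replicates can be averaged per
condition, and condition summaries are reported as mean ± SEM.

## Worked example

```python
from lumirhythm import get_preset, run_pipeline, simulate_plate

plate = simulate_plate(get_preset("NIH3T3", n_wells=3, seed=1))
result = run_pipeline(plate)
(summary,) = result.summaries
print(f"{summary.condition}: period {summary.period_mean_h:.2f} "
      f"± {summary.period_sem_h:.2f} h, R² {summary.r2_mean:.3f}")
```

prints

```
NIH3T3: period 23.92 ± 0.02 h, R² 0.988
```

— three simulated fibroblast replicate wells (true period 24 h, SNR 5,
gentle damping) recover the period to within 0.1 h with near-perfect
rhythmicity. The cell-line presets `MC38` (26.3 h), `E0771` (27.2 h) and
`LLC` (28.3 h) are anchored to reported cancer-line periods; running
`examples/02_cell_line_comparison.py` recovers 26.33 ± 0.07, 27.29 ± 0.07
and 28.33 ± 0.06 h from 12 noisy wells each, preserving the ordering
MC38 < E0771 < LLC. `examples/03_knockdown_contrast.py` shows the
siPer1+siPer2 knockdown scenario dropping mean R² from 0.989 to 0.931
(one-sided Wilcoxon rank-sum p ≈ 2·10⁻⁵).

More narrative scripts live in `examples/`; a thin CLI mirrors the library
(`lumirhythm simulate|fit|report`, see `lumirhythm --help`).

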