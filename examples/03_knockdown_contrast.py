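"""Per1/Per2 knockdown flattens the rhythm: R² contrast with control.

Simulates siControl and combined siPer1+siPer2 plates (12 wells each),
fits every well, and compares rhythmicity scores with a one-sided
Wilcoxon rank-sum test.
"""

import numpy as np
import scipy.stats as st

from lumirhythm import get_preset, rhythmicity_score, run_pipeline, simulate_plate

scores = {}
for name, seed in (("siControl", 1), ("siPer1Per2", 2)):
    res = run_pipeline(simulate_plate(get_preset(name, n_wells=12, seed=seed)))
    scores[name] = [rhythmicity_score(w.fit) for w in res.well_fits]
    print(f"{name:12s} mean R² = {np.mean(scores[name]):.3f} "
          f"(n={len(scores[name])})")

p = st.mannwhitneyu(scores["siPer1Per2"], scores["siControl"],
                    alternative="less").pvalue
print(f"\none-sided Wilcoxon rank-sum p = {p:.2e}")
print("Knocking down the core clock genes lowers every well's rhythmicity "
      "score: the\noscillation loses amplitude, damps faster and drifts in "
      "phase, so the trace\nresembles a sinusoid less closely.")
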