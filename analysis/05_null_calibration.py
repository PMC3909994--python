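#!/usr/bin/env python
"""Null calibration of the 9-network metastability test under placebo.

Repeats the full pipeline — generate a 15-subject placebo-like cohort,
compute per-network metastability percent change, test each network against
zero at the Bonferroni threshold 0.05/9 — over 500 independent root seeds,
and reports the familywise false-positive rate with its binomial 95%
interval around the nominal 0.05. Percent change is a ratio statistic with
a small positive null bias; the two-tailed test largely absorbs it, and the
empirical rate should sit inside the binomial bounds.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neuroentropy import cohort as co
from neuroentropy.config import GeneratorConfig

N_REP = 500
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    rejections = np.array([
        co.placebo_familywise_rejection(GeneratorConfig(seed=s), n_subjects=15,
                                        mode="amplitude")
        for s in range(N_REP)
    ])
    rate = rejections.mean()
    half = 1.96 * np.sqrt(0.05 * 0.95 / N_REP)
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "n_replicates": [N_REP], "familywise_rate": [rate],
        "nominal": [0.05], "ci_low": [0.05 - half], "ci_high": [0.05 + half],
        "within_bounds": [0.05 - half <= rate <= 0.05 + half],
    }).to_csv(RESULTS / "null_calibration.tsv", sep="\t", index=False)
    print(f"familywise false-positive rate over {N_REP} placebo replicates: "
          f"{rate:.3f} (nominal 0.05, binomial bounds "
          f"[{0.05 - half:.3f}, {0.05 + half:.3f}])")


if __name__ == "__main__":
    main()
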