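"""Recovery study for the across-subject congruence <-> ITPC correlation.

Draws 50 replicate cohorts of n = 18 subject index tables with a generative
congruence <-> ITPC correlation of r = 0.65, runs the regression-based
Cook's-distance exclusion and the Bonferroni-corrected Pearson analysis on
each, and reports the distribution of recovered coefficients.  Writes
results/brain_behavior_recovery.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from duplescales.behavior import brain_behavior
from duplescales.synth import synth_subject_indices

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

R_TRUE = 0.65
rows = []
for seed in range(50):
    idx = synth_subject_indices(18, r_congruence_itpc=R_TRUE, seed=seed)
    res = brain_behavior(idx)
    (r,) = [c["r"] for c in res["correlations"]
            if c["pair"] == "itpc_index__congruence_index"]
    rows.append({"replicate": seed, "r_recovered": r,
                 "n_excluded": res["n_excluded"]})
table = pd.DataFrame(rows)
table.to_csv(OUT / "brain_behavior_recovery.tsv", sep="\t", index=False)

mean_r = table["r_recovered"].mean()
print(f"generative r = {R_TRUE}; recovered mean r = {mean_r:.3f} "
      f"(SD {table['r_recovered'].std():.3f}) over 50 replicates")
print(f"mean outliers excluded per replicate: "
      f"{table['n_excluded'].mean():.2f}")
print(f"|bias| = {abs(mean_r - R_TRUE):.3f} (recovery tolerance 0.15)")
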