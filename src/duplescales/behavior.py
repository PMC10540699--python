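"""Scoring and statistics for the repetition-detection task, plus the
brain-behavior correlation analysis.

Accuracy is the hit rate on repetition (decoy) trials; reaction times longer
than 2 s are excluded from the RT analysis and mean RTs (correct trials
only) are log-transformed before testing.  Group statistics: one-way
within-subject ANOVA over the three timing conditions with FDR-corrected
paired post-hocs; Wilcoxon signed-rank tests across experiment halves; and
an across-subject analysis regressing the behavioral accuracy benefit on
three neural indices with Cook's-distance outlier exclusion followed by
Bonferroni-corrected Pearson correlations among all measures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster_stats import rm_anova_1way

logger = logging.getLogger(__name__)

RT_MAX_S = 2.0
CONDITIONS = ("isochronous", "interval_based", "beat_based")


# ---------------------------------------------------------------------------
# scoring

def score_and_filter(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition accuracy (%) and mean log-RT.

    Accuracy counts all hits; RTs > 2 s are excluded from the RT average,
    which uses correct trials only.  A subject x condition cell with no
    correct trial yields a missing log-RT (logged).
    """
    rows = []
    for (subject, cond), grp in responses.groupby(["subject", "condition"]):
        acc = 100.0 * grp["hit"].mean()
        rts = grp.loc[grp["hit"], "rt_s"].dropna()
        rts = rts[rts <= RT_MAX_S]
        if len(rts) == 0:
            logger.warning("subject %s, %s: no usable correct RTs", subject,
                           cond)
            mean_rt = np.nan
        else:
            mean_rt = rts.mean()
        rows.append({"subject": subject, "condition": cond,
                     "accuracy_pct": acc, "mean_rt_s": mean_rt,
                     "log_mean_rt": np.log(mean_rt) if mean_rt == mean_rt
                     else np.nan, "n_trials": len(grp)})
    return pd.DataFrame(rows)


def _condition_matrix(scores: pd.DataFrame, value: str) -> np.ndarray:
    wide = scores.pivot(index="subject", columns="condition", values=value)
    missing = wide.isna().any(axis=None)
    if missing:
        raise ValueError(f"missing {value} cells in the condition matrix")
    return wide[list(CONDITIONS)].to_numpy()


def rm_anova_time(scores: pd.DataFrame, value: str = "accuracy_pct") -> dict:
    """One-way within-subject ANOVA over timing conditions with
    FDR-corrected paired t post-hocs (3 comparisons)."""
    x = _condition_matrix(scores, value)
    f, (df1, df2) = rm_anova_1way(x)
    p = float(stats.f.sf(f, df1, df2))
    pairs = list(itertools.combinations(range(3), 2))
    raw = []
    for i, j in pairs:
        t, pt = stats.ttest_rel(x[:, i], x[:, j])
        raw.append({"pair": f"{CONDITIONS[i]}_vs_{CONDITIONS[j]}",
                    "t": float(t), "p": float(pt)})
    rej, p_fdr = multipletests([r["p"] for r in raw], alpha=0.05,
                               method="fdr_bh")[:2]
    for r, q, sig in zip(raw, p_fdr, rej):
        r["p_fdr"] = float(q)
        r["significant_fdr"] = bool(sig)
    return {"F": float(f), "df": (df1, df2), "p": p, "posthoc": raw,
            "condition_means": dict(zip(CONDITIONS, x.mean(axis=0)))}


def halves_tests(responses: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of first vs second half, per condition,
    separately for accuracy and (filtered, correct-trial) mean RT."""
    rows = []
    for cond in CONDITIONS:
        sub = responses[responses["condition"] == cond]
        for measure in ("accuracy", "rt"):
            per_half = {}
            for half in ("first", "second"):
                h = sub[sub["half"] == half]
                if measure == "accuracy":
                    v = h.groupby("subject")["hit"].mean() * 100
                else:
                    ok = h[h["hit"] & (h["rt_s"] <= RT_MAX_S)]
                    v = ok.groupby("subject")["rt_s"].mean()
                per_half[half] = v
            paired = pd.concat(per_half, axis=1).dropna()
            diff = paired["second"] - paired["first"]
            if np.allclose(diff, 0):
                stat_w, p = 0.0, 1.0
                logger.warning("all-zero differences for %s %s", cond, measure)
            else:
                mode = "exact" if len(diff) <= 25 else "approx"
                stat_w, p = stats.wilcoxon(diff, zero_method="wilcox",
                                           mode=mode)
            rows.append({"condition": cond, "measure": measure,
                         "n": len(diff), "median_diff": float(diff.median()),
                         "W": float(stat_w), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain-behavior

NEURAL_INDICES = ("itpc_index", "congruence_index", "mismatch_index")


def behavioral_index(scores: pd.DataFrame) -> pd.Series:
    """Accuracy(interval_based) - accuracy(beat_based), % per subject."""
    wide = scores.pivot(index="subject", columns="condition",
                        values="accuracy_pct")
    return wide["interval_based"] - wide["beat_based"]


def brain_behavior(indices: pd.DataFrame, cooks_factor: float = 5.0,
                   alpha: float = 0.05) -> dict:
    """Regression + correlation analysis of the subject index table.

    ``indices`` columns: behavioral_index plus the three neural indices.
    Subjects whose Cook's distance in the linear regression of the
    behavioral index on the neural indices exceeds ``cooks_factor`` times
    the mean are excluded; Pearson correlations among all measure pairs are
    then Bonferroni-corrected over the tested pairs.
    """
    cols = ["behavioral_index", *NEURAL_INDICES]
    data = indices[cols].dropna()
    if len(data) < 5:
        raise ValueError("need at least 5 complete subjects")
    y = data["behavioral_index"].to_numpy()
    x = sm.add_constant(data[list(NEURAL_INDICES)].to_numpy())
    fit = sm.OLS(y, x).fit()
    cooks = fit.get_influence().cooks_distance[0]
    keep = cooks <= cooks_factor * cooks.mean()
    excluded = data.index[~keep].tolist()
    clean = data.loc[keep]
    pairs = list(itertools.combinations(cols, 2))
    rows = []
    for a, b in pairs:
        r, p = stats.pearsonr(clean[a], clean[b])
        rows.append({"pair": f"{a}__{b}", "r": float(r), "p": float(p)})
    p_bonf = np.minimum(1.0, np.array([r["p"] for r in rows]) * len(pairs))
    for row, pb in zip(rows, p_bonf):
        row["p_bonferroni"] = float(pb)
        row["significant"] = bool(pb < alpha)
    return {
        "n_total": int(len(data)), "n_excluded": len(excluded),
        "excluded_subjects": excluded,
        "regression_coef": dict(zip(("const", *NEURAL_INDICES), fit.params)),
        "regression_r2": float(fit.rsquared),
        "cooks_distance": cooks.tolist(),
        "correlations": rows,
    }
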