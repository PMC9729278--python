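"""Thin statistical layer: t-tests with Bonferroni thresholds and
repeated-measures ANOVA with Tukey post-hoc comparisons."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    corrected_threshold: float
    n_a: int
    n_b: int
    paired: bool

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_threshold

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def compare_groups(a, b, paired: bool = False, corrections: int = 1
                   ) -> ComparisonResult:
    """Student's t-test with a Bonferroni-adjusted significance threshold
    (0.05 / corrections)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length groups")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = _stats.ttest_rel(a, b)
    else:
        stat, p = _stats.ttest_ind(a, b)
    return ComparisonResult(
        test="paired t" if paired else "two-sample t",
        statistic=float(stat), p_value=float(p),
        corrected_threshold=0.05 / corrections,
        n_a=int(a.size), n_b=int(b.size), paired=paired)


def repeated_measures_anova(data: np.ndarray | pd.DataFrame) -> dict:
    """Within-subject ANOVA over subjects x timepoints, with Tukey HSD
    pairwise comparisons between timepoints.

    ``data`` is a (n_subjects, n_timepoints) array (or DataFrame with
    timepoints as columns). Returns the F statistic, its p-value, and a
    pairwise table with Tukey-corrected rejection flags.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    arr = data.to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 timepoints")
    n_sub, n_tp = arr.shape
    if np.allclose(arr.var(axis=0).sum(), 0.0):
        raise ValueError("degenerate variance: all observations equal")
    if np.allclose(arr, arr[:, [0]]):
        # no within-subject change at all: F is 0 by convention
        return {"f_statistic": 0.0, "p_value": 1.0, "pairwise": pd.DataFrame()}
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_tp),
        "timepoint": np.tile(np.arange(n_tp), n_sub),
        "value": arr.ravel(),
    })
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=["timepoint"]).fit()
    f_stat = float(res.anova_table["F Value"].iloc[0])
    p_val = float(res.anova_table["Pr > F"].iloc[0])
    tk = pairwise_tukeyhsd(long["value"], long["timepoint"])
    pairwise = pd.DataFrame(tk.summary().data[1:],
                            columns=tk.summary().data[0])
    return {"f_statistic": f_stat, "p_value": p_val, "pairwise": pairwise}
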