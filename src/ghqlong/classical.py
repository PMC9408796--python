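"""Complete-data descriptive inference: wave ANOVA and paired t-tests.

These are the conventional complements to the Bayesian analysis: a one-way
fixed-effects linear model (ANOVA F-test) of GHQ-12 sum differences across
the three waves treating person-waves as independent complete cases, and
paired t-tests between pairs of waves on within-person differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WaveTestResult", "wave_anova", "paired_wave_test", "all_wave_tests"]


@dataclass
class WaveTestResult:
    comparison: str
    statistic: float
    df1: float
    df2: float | None
    p_value: float

    def as_dict(self):
        return {
            "comparison": self.comparison,
            "statistic": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
        }


def wave_anova(scored: pd.DataFrame, score: str = "likert_sum") -> WaveTestResult:
    """One-way fixed-effects F-test of wave mean differences on complete cases."""
    groups = []
    for w in sorted(scored["wave"].unique()):
        vals = scored.loc[scored["wave"] == w, score].dropna().to_numpy(float)
        if len(vals) >= 2:
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two waves with two or more complete scores")
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        raise ValueError("degenerate input: zero residual variance across waves")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return WaveTestResult("anova_waves", float(f), float(df1), float(df2), float(p))


def paired_wave_test(
    scored: pd.DataFrame, wave_a: int, wave_b: int, score: str = "likert_sum"
) -> WaveTestResult:
    """Paired t-test between two waves on within-person differences.

    Persons missing either wave's score are excluded.  Two-sided p-value.
    """
    wide = scored.pivot(index="person_id", columns="wave", values=score)
    if wave_a not in wide.columns or wave_b not in wide.columns:
        raise ValueError(f"waves {wave_a}/{wave_b} not both present")
    pairs = wide[[wave_a, wave_b]].dropna()
    if len(pairs) < 2:
        raise ValueError("fewer than two complete pairs")
    a = pairs[wave_a].to_numpy(float)
    b = pairs[wave_b].to_numpy(float)
    if np.allclose(a, b):
        # identical vectors: no evidence of any difference
        return WaveTestResult(
            f"paired_w{wave_a}_w{wave_b}", 0.0, float(len(pairs) - 1), None, 1.0
        )
    t, p = stats.ttest_rel(a, b)
    return WaveTestResult(
        f"paired_w{wave_a}_w{wave_b}", float(t), float(len(pairs) - 1), None, float(p)
    )


def all_wave_tests(scored: pd.DataFrame, score: str = "likert_sum") -> pd.DataFrame:
    """ANOVA across all waves plus every pairwise paired t-test, as a table."""
    results = [wave_anova(scored, score=score)]
    waves = sorted(scored["wave"].unique())
    for i, wa in enumerate(waves):
        for wb in waves[i + 1 :]:
            results.append(paired_wave_test(scored, wa, wb, score=score))
    return pd.DataFrame([r.as_dict() for r in results])
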