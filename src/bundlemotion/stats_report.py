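"""Group comparisons and report assembly for pre/post drug experiments.

The experimental design compares each preparation's measurement before and
after blocker injection (paired), or treated preparations against
vehicle-injected controls (unpaired with Welch's correction).  Normality is
screened with a Kolmogorov–Smirnov test against a normal law with
sample-estimated parameters (Lilliefors), and grids of level × frequency
measurements are analyzed with two-way fixed-effects ANOVA followed by
Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "significance_stars",
    "ks_normality",
    "compare",
    "anova2_bonferroni",
    "build_report",
]


def significance_stars(p: float) -> str:
    """Conventional star annotation; monotone in p."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class ComparisonResult:
    """A two-group comparison with group summaries and star annotation."""

    test: str
    statistic: float
    df: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "stars": self.stars,
                "groups": self.group_summaries}


def ks_normality(sample, estimated: bool = True) -> tuple[float, float]:
    """Kolmogorov–Smirnov test of normality; returns (statistic, p).

    With ``estimated`` (the default) the normal law's mean and sd are taken
    from the sample and the Lilliefors correction is applied; otherwise a
    plain KS test against N(sample mean, sample sd) is run (whose p-values
    are conservative when parameters are estimated).
    """
    x = np.asarray(sample, float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample: normality test undefined")
    if estimated:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    res = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def _summary(x: np.ndarray) -> dict:
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)),
            "sem": float(x.std(ddof=1) / np.sqrt(x.size)), "n": int(x.size)}


def compare(pre, post, design: str = "paired") -> ComparisonResult:
    """Two-tailed t-test of pre vs post under the stated design.

    ``design`` is "paired" (same preparations before/after, equal lengths)
    or "welch_unpaired" (independent groups, unequal variances allowed).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if min(pre.size, post.size) < 3:
        raise ValueError("need n >= 3 per group")
    if design == "paired":
        if pre.size != post.size:
            raise ValueError(
                f"paired design needs equal lengths ({pre.size} vs {post.size})"
            )
        if np.all(pre == post):
            # zero differences everywhere: no evidence of change (t = 0)
            return ComparisonResult(test="paired t-test (two-tailed)",
                                    statistic=0.0, df=float(pre.size - 1),
                                    p_value=1.0,
                                    group_summaries={"pre": _summary(pre),
                                                     "post": _summary(post)})
        res = stats.ttest_rel(pre, post)
        name = "paired t-test (two-tailed)"
    elif design == "welch_unpaired":
        res = stats.ttest_ind(pre, post, equal_var=False)
        name = "Welch unpaired t-test (two-tailed)"
    else:
        raise ValueError(f"unknown design {design!r}")
    return ComparisonResult(test=name, statistic=float(res.statistic),
                            df=float(res.df), p_value=float(res.pvalue),
                            group_summaries={"pre": _summary(pre),
                                             "post": _summary(post)})


def anova2_bonferroni(
    values,
    factor_a,
    factor_b,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way fixed-effects ANOVA plus Bonferroni post hoc comparisons.

    ``factor_a`` is typically the treatment, ``factor_b`` the stimulus level
    or frequency.  Returns (anova_table, posthoc): the type-II ANOVA table
    (main effects and interaction) and pairwise treatment comparisons within
    each level of factor_b, with p-values multiplied by the number of
    comparisons and capped at 1.  Cells must be complete, with at least two
    replicates each; nothing is imputed.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "a": np.asarray(factor_a),
                       "b": np.asarray(factor_b)})
    counts = df.groupby(["a", "b"], sort=True).size()
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 levels per factor")
    if len(counts) < n_a * n_b:
        raise ValueError("empty cells in the design; no imputation performed")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per cell")

    model = ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    a_levels = sorted(df["a"].unique())
    b_levels = sorted(df["b"].unique())
    pairs = [(a1, a2) for i, a1 in enumerate(a_levels) for a2 in a_levels[i + 1:]]
    rows = []
    for b in b_levels:
        sub = df[df["b"] == b]
        for a1, a2 in pairs:
            g1 = sub.loc[sub["a"] == a1, "value"].to_numpy()
            g2 = sub.loc[sub["a"] == a2, "value"].to_numpy()
            res = stats.ttest_ind(g1, g2)
            rows.append({"b": b, "a1": a1, "a2": a2,
                         "t": float(res.statistic), "p_raw": float(res.pvalue)})
    posthoc = pd.DataFrame(rows)
    m = len(posthoc)
    posthoc["p_bonferroni"] = np.minimum(1.0, posthoc["p_raw"] * m)
    posthoc["stars"] = posthoc["p_bonferroni"].map(significance_stars)
    return table, posthoc


def build_report(sections: dict, out_path: Optional[str] = None) -> dict:
    """Assemble pre/post comparisons into a single JSON-serializable report.

    ``sections`` maps a panel name to a dict with keys ``pre``, ``post``
    (arrays) and ``design``; each is run through :func:`compare`.  The report
    is returned and, if ``out_path`` is given, written as JSON.
    """
    report = {}
    for name, spec in sections.items():
        result = compare(spec["pre"], spec["post"],
                         design=spec.get("design", "paired"))
        report[name] = result.to_dict()
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
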