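"""Linear dose–response screening of lipid concentrations against dietary
ruminant-fat content.

Each lipid's four diet-group mean concentrations are regressed on the beef
tallow percentage of the diet (3.6 / 6.3 / 9.0 / 11.7 %) by ordinary least
squares.  The slope's significance is a two-sided Student-t test with
df = n_groups − 2 (df = 2 for a complete row).  A lipid is called a candidate
intake biomarker when all three criteria hold:

* slope p-value < 0.05,
* R² > 0.75 (strict), and
* strictly monotone (successively increasing or decreasing) group means.

A group mean that is missing (ND, not detected) is treated as a censored
observation, not zero: the trend is fitted on the remaining points when at
least three groups are present, and the successive-change criterion fails
(an undetected group cannot be ordered), so only complete rows are flaggable.
No multiple-testing correction is applied; the number of tests is reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStats",
    "RegressionFit",
    "BiomarkerCall",
    "group_stats",
    "fit_trend",
    "slope_p_value",
    "successive_change",
    "flag_biomarker",
    "screen_table",
    "compare_groups",
    "STUDY_DOSES",
]

#: Beef tallow as % of diet for the four experimental diets.
STUDY_DOSES = (3.6, 6.3, 9.0, 11.7)


@dataclass(frozen=True)
class GroupStats:
    """Per-diet-group summary of one analyte: mean ± sample SD over n animals."""

    group: str
    dose: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of group means on dose, with slope inference at df = n − 2."""

    slope: float
    intercept: float
    slope_se: float
    r2: float
    t_stat: float
    p_value: float
    df: int


@dataclass(frozen=True)
class BiomarkerCall:
    direction: str  # "increasing" | "decreasing" | "none"
    passes: bool
    reasons: frozenset[str] = frozenset()


def group_stats(
    per_sample: Mapping[str, float],
    groups: Mapping[str, str],
    doses: Mapping[str, float],
) -> list[GroupStats]:
    """Per-group mean, sample SD (n − 1 denominator) and n, ordered by dose."""
    by_group: dict[str, list[float]] = {}
    for sample, value in per_sample.items():
        by_group.setdefault(groups[sample], []).append(value)
    out = []
    for group in sorted(by_group, key=lambda g: doses[g]):
        values = np.asarray(by_group[group], dtype=float)
        if values.size == 0:
            raise ValueError(f"empty group {group!r}")
        if values.size == 1:
            import warnings

            warnings.warn(f"group {group!r} has n=1; SD recorded as 0")
            sd = 0.0
        else:
            sd = float(values.std(ddof=1))
        out.append(GroupStats(group, doses[group], float(values.mean()), sd, values.size))
    return out


def fit_trend(doses: Sequence[float], means: Sequence[float]) -> RegressionFit:
    """OLS of group means on dose; slope SE from residual variance at df = n − 2."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 dose points required")
    if np.ptp(x) == 0:
        raise ValueError("doses must not all be equal")
    df = x.size - 2
    if np.ptp(y) == 0:
        # degenerate all-equal means: flat line, no explainable variance
        return RegressionFit(0.0, float(y[0]), 0.0, 0.0, 0.0, 1.0, df)
    res = stats.linregress(x, y)
    slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
    r2 = float(res.rvalue) ** 2
    if se > 0:
        t = slope / se
        p = slope_p_value(slope, se, df)
    else:  # exact fit: infinite t, p -> 0
        t = math.inf if slope > 0 else -math.inf if slope < 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    return RegressionFit(slope, intercept, se, r2, t, p, df)


def slope_p_value(slope: float, slope_se: float, df: int) -> float:
    """Two-sided Student-t tail probability for a slope estimate."""
    if slope_se <= 0:
        raise ValueError("slope_se must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(slope / slope_se), df))


def successive_change(means: Sequence[float]) -> str:
    """Strict monotone direction across ordered group means, else "none".

    Any NaN (missing / ND group) yields "none": a censored group breaks the
    succession.
    """
    y = np.asarray(means, dtype=float)
    if y.size < 2:
        raise ValueError("at least 2 means required")
    if np.isnan(y).any():
        return "none"
    diffs = np.diff(y)
    if np.all(diffs > 0):
        return "increasing"
    if np.all(diffs < 0):
        return "decreasing"
    return "none"


def flag_biomarker(
    fit: RegressionFit,
    change: str,
    r2_min: float = 0.75,
    alpha: float = 0.05,
) -> BiomarkerCall:
    """Apply the three-criterion rule (p < alpha, R² > r2_min strictly,
    successive change present)."""
    reasons = set()
    if not (fit.p_value < alpha):
        reasons.add("slope_not_significant")
    if not (fit.r2 > r2_min):
        reasons.add("r2_below_threshold")
    if change == "none":
        reasons.add("no_successive_change")
    passes = not reasons
    return BiomarkerCall(direction=change if passes else change,
                         passes=passes, reasons=frozenset(reasons))


def screen_table(
    table: pd.DataFrame,
    doses: Sequence[float] = STUDY_DOSES,
    r2_min: float = 0.75,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Screen a per-lipid group-mean table for dose–response biomarkers.

    ``table`` is indexed by lipid with columns ``mean1..meanK`` (NaN = ND) for
    the K ordered dose groups.  Rows with fewer than three observed group means
    are excluded from fitting and reported.  Returns (per-lipid report, summary).
    """
    doses = np.asarray(doses, dtype=float)
    k = doses.size
    mean_cols = [f"mean{i}" for i in range(1, k + 1)]
    missing_cols = [c for c in mean_cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks column(s): {missing_cols}")

    rows = []
    excluded = []
    for lipid, row in table.iterrows():
        y = row[mean_cols].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < 3:
            excluded.append(lipid)
            rows.append(dict(lipid=lipid, n_groups=int(obs.sum()), slope=np.nan,
                             intercept=np.nan, slope_se=np.nan, r2=np.nan,
                             p_value=np.nan, direction="none", flagged=False))
            continue
        fit = fit_trend(doses[obs], y[obs])
        change = successive_change(y)
        call = flag_biomarker(fit, change, r2_min=r2_min, alpha=alpha)
        rows.append(dict(lipid=lipid, n_groups=int(obs.sum()), slope=fit.slope,
                         intercept=fit.intercept, slope_se=fit.slope_se, r2=fit.r2,
                         p_value=fit.p_value, direction=change, flagged=call.passes))
    report = pd.DataFrame(rows).set_index("lipid")
    flagged = report[report["flagged"]]
    summary = dict(
        n_rows=int(len(report)),
        n_tested=int((report["n_groups"] >= 3).sum()),
        n_excluded=int(len(excluded)),
        excluded=list(map(str, excluded)),
        n_flagged=int(len(flagged)),
        n_increasing=int((flagged["direction"] == "increasing").sum()),
        n_decreasing=int((flagged["direction"] == "decreasing").sum()),
    )
    return report, summary


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-group comparison: percent difference of means, CVs, Welch p, stars."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    mean_a, mean_b = a.mean(), b.mean()
    out = dict(
        percent_difference=np.nan,
        cv_a=100.0 * a.std(ddof=1) / mean_a if mean_a != 0 else np.nan,
        cv_b=100.0 * b.std(ddof=1) / mean_b if mean_b != 0 else np.nan,
    )
    if mean_b == 0:
        out["percent_difference_defined"] = False
    else:
        out["percent_difference"] = 100.0 * (mean_a - mean_b) / mean_b
        out["percent_difference_defined"] = True
    if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_a == mean_b:
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    out["p_value"] = p
    out["stars"] = _stars(p)
    return out
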