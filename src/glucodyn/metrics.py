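"""Agreement metrics and the statistical comparison suite.

Error metrics are signed and evaluated per time point on the confluence
scale: ``error = predicted - measured`` (confluence points) and
``percent error = 100 * error / measured``; "mean" averages over the time
course and "at end" takes the final time point.  Time points where the
measured value is exactly 0 are excluded from percent metrics, with the
exclusion count reported — a small denominator is also why dead-cell
percent errors run large: a 1-point error at 5% measured confluence is a
20% percent error.

Curve agreement uses Lin's concordance correlation coefficient (CCC) with
population (1/n) moments, which penalizes both dispersion and location
shifts, so CCC <= |Pearson r| with equality only for perfectly calibrated
agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import TimeCourse

__all__ = [
    "error_metrics",
    "summarize_metrics",
    "r_squared",
    "ccc",
    "match_accessible_level",
    "partial_correlation",
    "relative_improvement",
    "anova_oneway",
    "anova_twoway",
    "two_sample_ttest",
    "bonferroni",
    "pairwise_comparisons",
    "ks_normality",
]

METRIC_NAMES = ("mean_percent_error", "percent_error_at_end", "mean_error", "error_at_end")


def error_metrics(predicted: TimeCourse, measured: TimeCourse) -> dict:
    """Four signed error metrics per channel for one well.

    Returns ``{channel: {metric: value}, "skipped_zero_measured": {channel: n}}``.
    """
    if predicted.times.shape != measured.times.shape or not np.allclose(
        predicted.times, measured.times
    ):
        raise ValueError("predicted and measured time grids differ")
    out: dict = {"skipped_zero_measured": {}}
    for channel in ("live", "dead"):
        pred = getattr(predicted, channel)
        meas = getattr(measured, channel)
        err = pred - meas
        nonzero = meas != 0
        out["skipped_zero_measured"][channel] = int((~nonzero).sum())
        pct = 100.0 * err[nonzero] / meas[nonzero]
        out[channel] = {
            "mean_percent_error": float(pct.mean()) if pct.size else np.nan,
            "percent_error_at_end": float(100.0 * err[-1] / meas[-1]) if meas[-1] != 0 else np.nan,
            "mean_error": float(err.mean()),
            "error_at_end": float(err[-1]),
        }
    return out


def summarize_metrics(per_well: Sequence[dict], level: float = 0.95) -> pd.DataFrame:
    """Mean +/- CI of each error metric over wells, per channel.

    Rows are metrics, columns a MultiIndex (channel, {mean, ci_half}).
    """
    records = {}
    for channel in ("live", "dead"):
        for metric in METRIC_NAMES:
            vals = np.array([w[channel][metric] for w in per_well], float)
            vals = vals[np.isfinite(vals)]
            n = vals.size
            mean = float(vals.mean()) if n else np.nan
            if n > 1:
                half = float(stats.t.ppf(0.5 + level / 2, n - 1) * vals.std(ddof=1) / np.sqrt(n))
            else:
                half = np.nan
            records[(channel, "mean")] = records.get((channel, "mean"), {})
            records[(channel, "mean")][metric] = mean
            records[(channel, "ci_half")] = records.get((channel, "ci_half"), {})
            records[(channel, "ci_half")][metric] = half
    return pd.DataFrame(records).loc[list(METRIC_NAMES)]


def r_squared(predicted, observed) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Computed against the observation mean; can be negative for predictors
    worse than the mean.  Zero-variance observations are rejected.
    """
    predicted = np.asarray(predicted, float).ravel()
    observed = np.asarray(observed, float).ravel()
    if observed.size < 2 or predicted.shape != observed.shape:
        raise ValueError("need >= 2 paired observations")
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R^2 undefined")
    ss_res = float(((observed - predicted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with 1/n moments.

    ``2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("curves must have equal length >= 2")
    mx, my = x.mean(), y.mean()
    vx = float(((x - mx) ** 2).mean())
    vy = float(((y - my) ** 2).mean())
    cov = float(((x - mx) * (y - my)).mean())
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("both curves are the same constant; CCC undefined")
    return 2.0 * cov / denom


def match_accessible_level(
    treated: TimeCourse,
    untreated_by_level: Mapping[float, TimeCourse],
    channel: str = "live",
) -> tuple[float, dict[float, float]]:
    """Best untreated-equivalent glucose level for a treated curve.

    Computes the CCC between the treated confluence curve and the
    untreated curve at each glucose level; the argmax level estimates the
    accessible glucose of the treated well.  Returns (best level, full
    CCC table).
    """
    if not untreated_by_level:
        raise ValueError("no untreated reference curves supplied")
    table = {}
    tx = getattr(treated, channel)
    for level, course in untreated_by_level.items():
        table[float(level)] = ccc(tx, getattr(course, channel))
    best = max(table, key=table.get)
    return best, table


def partial_correlation(x, y, control) -> tuple[float, float]:
    """Pearson correlation of x and y after removing a linear control.

    Both variables are regressed on the control; the residuals are
    correlated.  Returns ``(r, p)`` with the p-value on n - 3 degrees of
    freedom.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    control = np.asarray(control, float).ravel()
    if not (x.size == y.size == control.size) or x.size < 4:
        raise ValueError("need >= 4 complete (x, y, control) triples")
    if np.std(control) == 0:
        warnings.warn("constant control variable; no adjustment performed", stacklevel=2)
        rx, ry = x, y
    else:
        A = np.column_stack([np.ones_like(control), control])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    # a variable fully explained by the control leaves only roundoff in its
    # residuals; its partial correlation with anything is 0 by convention
    for res, orig in ((rx, x), (ry, y)):
        scale = float(((orig - orig.mean()) ** 2).sum())
        if float(res @ res) <= 1e-20 * max(scale, 1.0):
            return 0.0, 1.0
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    dof = x.size - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def relative_improvement(start: float, end: float) -> float:
    """Percent change ``100 (end - start) / start``, to one decimal."""
    if start == 0:
        raise ValueError("start score must be nonzero")
    return round(100.0 * (end - start) / start, 1)


# ---------------------------------------------------------------------------
# statistical comparison suite
# ---------------------------------------------------------------------------

def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    f, p = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(f), float(p)


def anova_twoway(df: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA table (type II) via an OLS fit with both factors."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    model = ols(f"Q('{response}') ~ C(Q('{factor_a}')) + C(Q('{factor_b}'))", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Student's two-sample t-test (equal variance)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 observations")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni family-wise correction.

    Returns adjusted p-values (``min(1, m p)``) and the per-comparison
    alpha (``alpha / m``), so per-comparison alpha times m is exactly the
    nominal alpha.
    """
    p = np.asarray(p_values, float)
    m = p.size
    if m == 0:
        raise ValueError("no p-values supplied")
    return np.minimum(1.0, p * m), alpha / m


def pairwise_comparisons(scores: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise t-tests with Bonferroni-adjusted p-values."""
    names = sorted(scores)
    if len(names) < 2:
        raise ValueError("need >= 2 groups to compare")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = two_sample_ttest(scores[a], scores[b])
            rows.append({"a": a, "b": b, "t": t, "p": p})
    df = pd.DataFrame(rows)
    adj, per_alpha = bonferroni(df["p"].to_numpy(), alpha)
    df["p_bonferroni"] = adj
    df["significant"] = df["p"] < per_alpha
    return df


def ks_normality(x) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against a fitted normal."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample with zero variance")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)
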