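"""Phenomics statistics around the growth model.

Per-timepoint treatment tests with Bonferroni control, two-way
treatment x accession ANOVA, the 1.5x-IQR outlier rule used for image
QC, sliding-window Spearman correlations between daily traits and a
scalar phenotype, prediction evaluation (Pearson r, RMSE, relative
RMSE), and drought/control ratio traits.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .growth_core import CONTROL, DROUGHT, PlantTrajectory

__all__ = [
    "bonferroni_threshold",
    "timepoint_ttests",
    "timepoint_anova",
    "iqr_outlier_flags",
    "sliding_spearman",
    "evaluate_predictions",
    "derived_ratio_traits",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _day_matrix(trajectories: List[PlantTrajectory], variable: str) -> np.ndarray:
    if variable == "fc":
        # pot water content of a rewatered pot is its maintained
        # (post-watering) level; unwatered pots have no distinction
        return np.array(
            [tr.fc_post if tr.fc_post is not None else tr.fc for tr in trajectories]
        )
    return np.array([getattr(tr, variable) for tr in trajectories])


def timepoint_ttests(
    trajectories: List[PlantTrajectory],
    variable: str = "fc",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per imaging day, drought vs control.

    Flags significance at the Bonferroni threshold alpha / D where D is
    the number of imaging days.  Days with fewer than 2 plants in
    either group are skipped with a warning.
    """
    ctrl = [tr for tr in trajectories if tr.treatment == CONTROL]
    drt = [tr for tr in trajectories if tr.treatment == DROUGHT]
    if not ctrl or not drt:
        raise ValueError("both treatments must be present")
    xc = _day_matrix(ctrl, variable)
    xd = _day_matrix(drt, variable)
    D = xc.shape[1]
    thr = bonferroni_threshold(alpha, D)
    rows = []
    for d in range(D):
        a = xc[:, d][np.isfinite(xc[:, d])]
        b = xd[:, d][np.isfinite(xd[:, d])]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"day {d + 1}: fewer than 2 plants per group, skipped")
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "day": d + 1,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "n_control": len(a),
                "n_drought": len(b),
                "significant": bool(res.pvalue < thr),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thr
    return out


def timepoint_anova(trajectories: List[PlantTrajectory], variable: str = "psa") -> pd.DataFrame:
    """Per-day two-way fixed-effects ANOVA.

    Model (sequential, Type-I sums of squares, in this order):
    ``value ~ treatment + accession + treatment:accession``.  Requires
    replication for the interaction to be estimable; without it the
    interaction p-value is reported as NaN.
    """
    df = pd.DataFrame(
        {
            "accession": [tr.accession for tr in trajectories],
            "treatment": [tr.treatment for tr in trajectories],
        }
    )
    mat = _day_matrix(trajectories, variable)
    D = mat.shape[1]
    counts = df.groupby(["accession", "treatment"]).size()
    replicated = bool((counts > 1).any())
    rows = []
    for d in range(D):
        work = df.assign(value=mat[:, d]).dropna(subset=["value"])
        model = smf.ols(
            "value ~ C(treatment) + C(accession) + C(treatment):C(accession)", data=work
        ).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(model, typ=1)
        rows.append(
            {
                "day": d + 1,
                "p_treatment": float(table.loc["C(treatment)", "PR(>F)"]),
                "p_accession": float(table.loc["C(accession)", "PR(>F)"]),
                "p_interaction": (
                    float(table.loc["C(treatment):C(accession)", "PR(>F)"])
                    if replicated
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def iqr_outlier_flags(
    values: Sequence[float], k: float = 1.5, method: str = "linear"
) -> np.ndarray:
    """1.5x interquartile-range outlier rule at one timepoint.

    Flags x with ``x < Q1 - k*IQR`` or ``x > Q3 + k*IQR``; quartiles by
    linear interpolation between order statistics by default (the
    ``method`` string is passed to ``numpy.percentile``).  Fewer than 4
    values: nothing is flagged, with a warning.
    """
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 values; no outlier flags produced")
        return flags
    q1, q3 = np.percentile(x[finite], [25, 75], method=method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags[finite] = (x[finite] < lo) | (x[finite] > hi)
    return flags


def sliding_spearman(
    daily: np.ndarray,
    y: Sequence[float],
    window: int = 3,
) -> pd.DataFrame:
    """Spearman correlation between a windowed daily trait and a scalar.

    ``daily`` is (plants x days); for each window of ``window``
    consecutive days the trait is averaged within plant across the
    window, then rank-correlated against ``y`` (one value per plant,
    e.g. TOI).  Windows advance one day at a time and are labeled by
    their start and end day.  Ties get average ranks (Spearman's
    default).
    """
    daily = np.asarray(daily, dtype=float)
    y = np.asarray(y, dtype=float)
    n, D = daily.shape
    if window > D:
        raise ValueError("window exceeds number of days")
    if len(y) != n:
        raise ValueError("y must have one value per plant")
    rows = []
    for s in range(D - window + 1):
        xm = daily[:, s : s + window].mean(axis=1)
        keep = np.isfinite(xm) & np.isfinite(y)
        rho = stats.spearmanr(xm[keep], y[keep]).statistic if keep.sum() > 1 else np.nan
        rows.append(
            {
                "day_start": s + 1,
                "day_end": s + window,
                "rho": float(rho),
                "n": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)


def evaluate_predictions(predicted: np.ndarray, observed: np.ndarray) -> pd.DataFrame:
    """Per-day agreement between predicted and observed PSA.

    Both arrays are (plants x days).  Per day: Pearson r across plants,
    RMSE, and relative RMSE = RMSE / mean(predicted) on that day.
    Pearson r is NaN when either side has zero variance.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal shape")
    rows = []
    for d in range(predicted.shape[1]):
        p, o = predicted[:, d], observed[:, d]
        keep = np.isfinite(p) & np.isfinite(o)
        p, o = p[keep], o[keep]
        rmse = float(np.sqrt(np.mean((p - o) ** 2)))
        mean_pred = float(np.mean(p))
        if len(p) > 1 and p.std() > 0 and o.std() > 0:
            r = float(stats.pearsonr(p, o).statistic)
        else:
            r = np.nan
        rows.append(
            {
                "day": d + 1,
                "pearson_r": r,
                "rmse": rmse,
                "rrmse": rmse / mean_pred if mean_pred != 0 else np.nan,
                "n": len(p),
            }
        )
    return pd.DataFrame(rows)


def derived_ratio_traits(trajectories: List[PlantTrajectory], variable: str = "psa") -> pd.DataFrame:
    """Per-accession drought/control ratio per day (e.g. PSA_dr).

    Accession means are taken within treatment first; accessions
    missing either treatment are excluded (count logged via attrs).
    Zero control means yield NaN for that day.
    """
    by_key: dict = {}
    for tr in trajectories:
        by_key.setdefault((tr.accession, tr.treatment), []).append(getattr(tr, variable))
    accessions = sorted({a for a, _ in by_key})
    rows = []
    n_excluded = 0
    for acc in accessions:
        if (acc, CONTROL) not in by_key or (acc, DROUGHT) not in by_key:
            n_excluded += 1
            continue
        ctrl = np.nanmean(by_key[(acc, CONTROL)], axis=0)
        drt = np.nanmean(by_key[(acc, DROUGHT)], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ctrl != 0, drt / ctrl, np.nan)
        for d, val in enumerate(ratio):
            rows.append({"accession": acc, "day": d + 1, "ratio": float(val)})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out
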