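"""Survey-side indices and stationarity-aware rank correlation.

The reference survey asks a single happiness item with answers Yes /
Rather Yes / Rather No / No (plus "don't know").  In points:

    PA  = 100 * (yes + rather_yes)
    NA  = 100 * (no + rather_no)
    Net = PA - NA                       (range -100 .. 100)

Reliability of a tweet-derived indicator is its Spearman rank
correlation with the survey series.  Monthly well-being series are
typically non-stationary (trends, regime shifts), which inflates
spurious correlation, so each series is checked with the augmented
Dickey-Fuller test and both series are first-differenced before
correlating when either fails it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .indices import INDICATOR_KINDS, OSWBIndexSeries

SURVEY_KINDS = ("Net", "PA", "NA")


def compute_survey_indices(shares: pd.DataFrame) -> dict[str, pd.Series]:
    """PA/NA/Net series in points from monthly response-category shares.

    *shares* columns: month, yes, rather_yes, rather_no, no, dont_know.
    """
    cols = ["yes", "rather_yes", "rather_no", "no", "dont_know"]
    tot = shares[cols].sum(axis=1)
    if (shares[cols] < -1e-12).any().any() or (tot > 1 + 1e-9).any():
        raise ValueError("response shares must be non-negative and sum to <= 1")
    idx = shares["month"].astype(str)
    pa = pd.Series((100 * (shares["yes"] + shares["rather_yes"])).to_numpy(),
                   index=idx, name="PA")
    na = pd.Series((100 * (shares["no"] + shares["rather_no"])).to_numpy(),
                   index=idx, name="NA")
    return {"PA": pa, "NA": na, "Net": (pa - na).rename("Net")}


def adf_check(series: pd.Series, alpha: float = 0.05) -> tuple[bool, float, float]:
    """Augmented Dickey-Fuller unit-root test.

    Returns (stationary?, statistic, p-value); stationary means the unit
    root is rejected at *alpha*.  Constant series are a hard error.
    """
    values = np.asarray(series, dtype=float)
    if len(values) < 8:
        raise ValueError("ADF check needs at least 8 observations")
    if np.ptp(values) == 0:
        raise ValueError("ADF check is undefined for a constant series")
    stat, pvalue, *_ = adfuller(values, autolag="AIC")
    return pvalue < alpha, float(stat), float(pvalue)


def difference_series(series: pd.Series) -> pd.Series:
    """First differences between consecutive *available* observations in
    chronological order (gaps in the calendar are differenced across)."""
    if len(series) < 2:
        raise ValueError("differencing needs at least 2 observations")
    s = series.sort_index()
    return s.diff().iloc[1:]


@dataclass
class CorrelationReport:
    pair: tuple[str, str]
    n_months: int
    differenced: bool
    spearman_r: float
    p_value: float
    adf: dict[str, tuple[float, float]]  # series id -> (stat, p)


def correlate(a: pd.Series, b: pd.Series, difference: bool | str = "auto",
              alpha: float = 0.05,
              ids: tuple[str, str] = ("a", "b")) -> CorrelationReport:
    """Spearman correlation of two monthly series aligned on shared months.

    difference: True / False, or "auto" to difference both series when
    either fails the ADF stationarity check.
    """
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 5:
        raise ValueError(
            f"need at least 5 shared months, have {len(shared)}")
    a_al, b_al = a.loc[shared].astype(float), b.loc[shared].astype(float)
    adf_stats: dict[str, tuple[float, float]] = {}
    if difference == "auto":
        flags = []
        for name, s in zip(ids, (a_al, b_al)):
            stationary, stat, p = adf_check(s, alpha)
            adf_stats[name] = (stat, p)
            flags.append(stationary)
        difference = not all(flags)
    if difference:
        a_al, b_al = difference_series(a_al), difference_series(b_al)
    r, p = stats.spearmanr(a_al, b_al)
    return CorrelationReport(pair=ids, n_months=len(a_al),
                             differenced=bool(difference),
                             spearman_r=float(r), p_value=float(p),
                             adf=adf_stats)


def reliability_report(oswb: Mapping[tuple[str, str], OSWBIndexSeries],
                       survey: Mapping[str, pd.Series],
                       difference: bool | str = "auto",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Full cross of tweet indicators x survey indices x variants.

    One row per (OSWB indicator, variant, survey index) with the
    Spearman coefficient, p-value and a significance flag at *alpha*.
    """
    rows = []
    for (kind, variant), series in sorted(oswb.items()):
        for sk in SURVEY_KINDS:
            if sk not in survey:
                continue
            rep = correlate(series.values, survey[sk], difference, alpha,
                            ids=(f"OSWB_{kind}:{variant}", f"survey_{sk}"))
            rows.append({
                "oswb_indicator": kind,
                "variant": variant,
                "survey_index": sk,
                "n_months": rep.n_months,
                "differenced": rep.differenced,
                "spearman_r": rep.spearman_r,
                "p_value": rep.p_value,
                "significant": rep.p_value < alpha,
            })
    if not rows:
        raise ValueError("no overlapping series to correlate")
    return pd.DataFrame(rows)
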