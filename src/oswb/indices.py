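"""Observable subjective well-being (OSWB) indicators from labelled posts.

The measurement unit is the *user-month*: within each calendar month every
user's tweets are collapsed to a single sentiment class by majority vote,
and the indicators are shares of users (optionally post-stratified by
gender) rather than shares of tweets.  Seven indicators are supported:

====  =========================================
PA    POS / (POS + NEG + NEU + SA + SKIP)
PA_Neu  POS / NEU
NA    NEG / total
NA_Neu  NEG / NEU
Net   (POS - NEG) / total
Net_Neu (POS - NEG) / NEU
SA    SA / total
====  =========================================

Post-stratification assigns each known-gender user the weight
w_g = census_share_g / sample_share_g before tallying, the standard
post-stratification estimator for a convenience sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SentimentLabel(str, Enum):
    POS = "POS"
    NEG = "NEG"
    NEU = "NEU"
    SA = "SA"
    SKIP = "SKIP"


LABELS: tuple[str, ...] = tuple(l.value for l in SentimentLabel)

#: Tie-break precedence for majority voting among classes tied for the
#: top count (after the Neutral-first rules have not applied).
TIE_PRECEDENCE: tuple[str, ...] = ("NEU", "SKIP", "SA", "POS", "NEG")

INDICATOR_KINDS: tuple[str, ...] = (
    "PA", "PA_Neu", "NA", "NA_Neu", "Net", "Net_Neu", "SA",
)


class UndefinedIndicatorError(ValueError):
    """Raised when an indicator's denominator is zero."""


@dataclass
class SentimentCounts:
    """Tallies of the five sentiment classes for one stratum-month.

    Components are reals, not integers, because post-stratification
    reweights each user's unit mass.
    """

    POS: float = 0.0
    NEG: float = 0.0
    NEU: float = 0.0
    SA: float = 0.0
    SKIP: float = 0.0

    def __post_init__(self) -> None:
        for lab in LABELS:
            if getattr(self, lab) < 0:
                raise ValueError(f"negative count for class {lab}")

    @property
    def total(self) -> float:
        return self.POS + self.NEG + self.NEU + self.SA + self.SKIP

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, lab) for lab in LABELS], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SentimentCounts":
        return cls(**dict(zip(LABELS, map(float, arr))))

    @classmethod
    def from_labels(cls, labels: Iterable[str],
                    weights: Iterable[float] | None = None) -> "SentimentCounts":
        counts = dict.fromkeys(LABELS, 0.0)
        if weights is None:
            for lab in labels:
                counts[str(lab)] += 1.0
        else:
            for lab, w in zip(labels, weights):
                counts[str(lab)] += float(w)
        return cls(**counts)

    def __add__(self, other: "SentimentCounts") -> "SentimentCounts":
        return SentimentCounts(*(self.as_array() + other.as_array()))


@dataclass(frozen=True)
class UserMonthLabel:
    """One user's aggregated sentiment class in one calendar month."""

    user_id: str
    month: str
    label: str
    n_tweets: int

    def __post_init__(self) -> None:
        if self.n_tweets < 1:
            raise ValueError("a user-month record needs at least one tweet")
        if self.label not in LABELS:
            raise ValueError(f"unknown sentiment label {self.label!r}")


def majority_label(labels: Sequence[str]) -> str:
    """Collapse a user's tweet labels for one month to a single class.

    The most frequent class wins.  Ties for the top count resolve toward
    Neutral: a tie involving NEU gives NEU, and a tie between POS and
    NEG — conflicting affect — also collapses to NEU rather than
    injecting either sign.  Any remaining tie is broken by the fixed
    precedence SKIP > SA > POS > NEG.
    """
    if not labels:
        raise ValueError("empty label sequence")
    counts = Counter(str(l) for l in labels)
    unknown = set(counts) - set(LABELS)
    if unknown:
        raise ValueError(f"unlabelled or unknown classes: {sorted(unknown)}")
    top = max(counts.values())
    tied = [lab for lab in TIE_PRECEDENCE if counts.get(lab, 0) == top]
    if len(tied) == 1:
        return tied[0]
    if "NEU" in tied or {"POS", "NEG"} <= set(tied):
        return "NEU"
    return tied[0]


def aggregate_user_month(tweets: pd.DataFrame, month: str) -> list[UserMonthLabel]:
    """Majority-vote tweet labels to user level for one month.

    Parameters
    ----------
    tweets : DataFrame with columns ``user_id`` and ``label``, all rows
        belonging to *month*.
    """
    if tweets["label"].isna().any():
        raise ValueError("unlabelled tweet encountered")
    out = []
    for user_id, grp in tweets.groupby("user_id", sort=True):
        labs = grp["label"].tolist()
        out.append(UserMonthLabel(str(user_id), month, majority_label(labs),
                                  len(labs)))
    return out


def count_by_stratum(
    labels: Sequence[UserMonthLabel],
    genders: Mapping[str, str],
) -> tuple[dict[str, SentimentCounts], int]:
    """Tally user-month labels per gender stratum.

    The counting unit is the user.  Users whose stratum is missing or
    "unknown" are excluded; their number is returned alongside.
    """
    per_stratum: dict[str, SentimentCounts] = {}
    n_unknown = 0
    for rec in labels:
        stratum = genders.get(rec.user_id, "unknown")
        if stratum == "unknown":
            n_unknown += 1
            continue
        per_stratum.setdefault(stratum, SentimentCounts())
        cur = per_stratum[stratum]
        setattr(cur, rec.label, getattr(cur, rec.label) + 1.0)
    return per_stratum, n_unknown


def check_min_sample(labels: Sequence[UserMonthLabel],
                     threshold: int = 1600) -> tuple[bool, int]:
    """Minimum-sample rule: a month is usable iff it has at least
    *threshold* distinct users (default 1,600, the typical single-wave
    size of the reference telephone survey)."""
    n = len({rec.user_id for rec in labels})
    return n >= threshold, n


@dataclass(frozen=True)
class GenderDistribution:
    """Gender shares with their provenance (census or sample)."""

    shares: Mapping[str, float]
    provenance: str = "sample"

    def __post_init__(self) -> None:
        tot = sum(self.shares.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {tot}, expected 1")
        if any(s < 0 for s in self.shares.values()):
            raise ValueError("negative share")


def poststratification_weights(sample: GenderDistribution,
                               census: GenderDistribution) -> dict[str, float]:
    """w_g = census share / sample share, per stratum.

    Raises if a stratum with positive census mass has zero sample mass
    (degenerate reweighting).
    """
    if set(sample.shares) != set(census.shares):
        raise ValueError("sample and census cover different strata")
    weights = {}
    for g, pi in census.shares.items():
        p = sample.shares[g]
        if p <= 0:
            if pi > 0:
                raise ValueError(
                    f"stratum {g!r} absent from sample but present in census")
            continue
        weights[g] = pi / p
    return weights


def compute_indicator(counts: SentimentCounts, kind: str,
                      month: str | None = None) -> float:
    """Evaluate one OSWB indicator on a counts object."""
    if kind not in INDICATOR_KINDS:
        raise ValueError(f"unknown indicator kind {kind!r}")
    where = f" in month {month}" if month else ""
    if kind.endswith("_Neu"):
        if counts.NEU <= 0:
            raise UndefinedIndicatorError(
                f"{kind} undefined{where}: NEU count is zero")
        denom = counts.NEU
    else:
        if counts.total <= 0:
            raise UndefinedIndicatorError(
                f"{kind} undefined{where}: no posts")
        denom = counts.total
    base = kind.split("_")[0]
    if base == "PA":
        num = counts.POS
    elif base == "NA":
        num = counts.NEG
    elif base == "Net":
        num = counts.POS - counts.NEG
    elif base == "SA":
        num = counts.SA
    return num / denom


@dataclass
class OSWBIndexSeries:
    """A monthly time series of one indicator, raw or post-stratified."""

    kind: str
    variant: str  # "raw" or "poststratified"
    values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if self.kind not in INDICATOR_KINDS:
            raise ValueError(f"unknown indicator kind {self.kind!r}")
        if self.variant not in ("raw", "poststratified"):
            raise ValueError(f"unknown variant {self.variant!r}")


def compute_series(
    labels_by_month: Mapping[str, Sequence[UserMonthLabel]],
    genders: Mapping[str, str],
    census: GenderDistribution,
    kinds: Sequence[str] = INDICATOR_KINDS,
) -> dict[tuple[str, str], OSWBIndexSeries]:
    """Monthly indicator series in both variants.

    Per month: the raw variant tallies every user with unit mass; the
    post-stratified variant recomputes the sample gender distribution from
    that month's known-gender users, reweights each user by
    census/sample, and tallies the weighted mass.  Unknown-gender users
    enter only the raw variant.
    """
    months = sorted(labels_by_month)
    raw_vals: dict[str, dict[str, float]] = {k: {} for k in kinds}
    ps_vals: dict[str, dict[str, float]] = {k: {} for k in kinds}
    for month in months:
        recs = labels_by_month[month]
        raw_counts = SentimentCounts.from_labels([r.label for r in recs])
        per_stratum, _ = count_by_stratum(recs, genders)
        n_known = sum(c.total for c in per_stratum.values())
        if n_known == 0:
            raise ValueError(f"no known-gender users in month {month}")
        sample_shares = {g: c.total / n_known for g, c in per_stratum.items()}
        missing = [g for g, pi in census.shares.items()
                   if pi > 0 and g not in sample_shares]
        if missing:
            raise ValueError(
                f"month {month}: census strata {missing} have no sampled users")
        weights = {g: census.shares.get(g, 0.0) / p
                   for g, p in sample_shares.items()}
        weighted = SentimentCounts()
        for g, c in per_stratum.items():
            weighted = weighted + SentimentCounts.from_array(
                c.as_array() * weights[g])
        for kind in kinds:
            raw_vals[kind][month] = compute_indicator(raw_counts, kind, month)
            ps_vals[kind][month] = compute_indicator(weighted, kind, month)
    out: dict[tuple[str, str], OSWBIndexSeries] = {}
    for kind in kinds:
        out[(kind, "raw")] = OSWBIndexSeries(
            kind, "raw", pd.Series(raw_vals[kind], dtype=float))
        out[(kind, "poststratified")] = OSWBIndexSeries(
            kind, "poststratified", pd.Series(ps_vals[kind], dtype=float))
    return out


def series_frame(series: Mapping[tuple[str, str], OSWBIndexSeries],
                 n_users: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Tidy long-format view: month, indicator, variant, value[, n_users]."""
    rows = []
    for (kind, variant), s in series.items():
        for month, value in s.values.items():
            row = {"month": month, "indicator": kind, "variant": variant,
                   "value": value}
            if n_users is not None:
                row["n_users"] = n_users.get(month)
            rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["indicator", "variant", "month"]).reset_index(drop=True)
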