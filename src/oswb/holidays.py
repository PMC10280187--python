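"""Day-level speech-act shares and holiday ranking.

Greetings and congratulation posts (the Speech Act class) spike on
holidays, so the daily share of SA tweets is a proxy for how widely a
day is celebrated.  Shares are computed at the *tweet* level per gender,
days are ranked within each gender (rank 1 = highest share, competition
ranking for ties), and an aggregate ranking orders days by the mean of
their per-gender ranks, reporting ties as rank ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailySAShare:
    date: str
    stratum: str
    sa_share: float
    n_tweets: int

    def __post_init__(self) -> None:
        if not 0 <= self.sa_share <= 1:
            raise ValueError("sa_share must lie in [0, 1]")


def daily_sa_share(tweets: pd.DataFrame,
                   genders: Mapping[str, str] | None = None,
                   stratum: str | None = None) -> list[DailySAShare]:
    """Per-day share of SA tweets, optionally restricted to one gender.

    *tweets* needs columns date, user_id, label.  Days with zero tweets
    simply do not appear (logged).
    """
    df = tweets
    if stratum is not None:
        if genders is None:
            raise ValueError("stratum filtering needs a gender mapping")
        keep = df["user_id"].map(lambda u: genders.get(u) == stratum)
        df = df[keep]
    out = []
    for date, grp in df.groupby("date", sort=True):
        n = len(grp)
        out.append(DailySAShare(str(date), stratum or "all",
                                float((grp["label"] == "SA").sum()) / n, n))
    if not out:
        logger.info("no tweets for stratum %r; no daily shares emitted", stratum)
    return out


def rank_days(shares: Sequence[DailySAShare]) -> pd.DataFrame:
    """Rank days by SA share, rank 1 = highest, competition ranking on ties."""
    if len(shares) < 2:
        raise ValueError("ranking needs at least 2 days")
    df = pd.DataFrame({"date": [s.date for s in shares],
                       "sa_share": [s.sa_share for s in shares],
                       "n_tweets": [s.n_tweets for s in shares]})
    df["rank"] = df["sa_share"].rank(method="min", ascending=False).astype(int)
    return df.sort_values(["rank", "date"]).reset_index(drop=True)


def aggregate_ranking(per_stratum: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Order days by the mean of their per-stratum ranks.

    All strata must cover the same day set.  Days with equal mean rank
    share an aggregate rank reported as a range string ("2-4").
    """
    strata = sorted(per_stratum)
    day_sets = [set(per_stratum[g]["date"]) for g in strata]
    if any(s != day_sets[0] for s in day_sets):
        raise ValueError("per-stratum rankings cover different day sets")
    merged = None
    for g in strata:
        cols = per_stratum[g].rename(
            columns={"sa_share": f"{g}_sa_share", "rank": f"{g}_rank",
                     "n_tweets": f"{g}_n_tweets"})
        merged = cols if merged is None else merged.merge(cols, on="date")
    rank_cols = [f"{g}_rank" for g in strata]
    merged["mean_rank"] = merged[rank_cols].mean(axis=1)
    merged = merged.sort_values(["mean_rank", "date"]).reset_index(drop=True)
    # positions are 1-based; ties on mean rank become ranges like "2-4"
    positions = range(1, len(merged) + 1)
    merged["position"] = list(positions)
    labels = []
    for _, grp in merged.groupby("mean_rank", sort=True):
        lo, hi = grp["position"].min(), grp["position"].max()
        lab = str(lo) if lo == hi else f"{lo}-{hi}"
        labels.extend([lab] * len(grp))
    merged["aggregate_rank"] = labels
    return merged.drop(columns=["position"])
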