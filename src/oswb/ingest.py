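"""Tweet-stream ingestion: parse newline-delimited JSON, filter, bin by month.

The accepted dialect is the public "Spritzer"-stream tweet object:
``id_str``, ``user.id_str``, ``user.name``, ``lang``, ``created_at``
(RFC-822-style, e.g. ``Wed Oct 10 20:19:24 +0000 2018``), an optional
``retweeted_status`` member marking retweets, and — for pre-labelled
streams — an optional ``sentiment_label``.  Labels may instead come from
a sidecar CSV of (tweet_id, label).

Inclusion rules follow the measurement design: keep original tweets in
the target language, drop retweets, and keep only months in which tweets
were available for at least 80% of days.
"""

from __future__ import annotations

import gzip
import json
import logging
from calendar import monthrange
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_TWITTER_TS = "%a %b %d %H:%M:%S %z %Y"


@dataclass(frozen=True)
class RawTweet:
    tweet_id: str
    user_id: str
    user_name: str
    lang: str
    created_at: datetime
    is_retweet: bool
    label: str | None = None


@dataclass
class MonthWindow:
    month: str
    days_present: int
    days_in_month: int

    def __post_init__(self) -> None:
        if not 0 <= self.days_present <= self.days_in_month:
            raise ValueError(
                f"{self.month}: days_present={self.days_present} outside "
                f"[0, {self.days_in_month}]")

    @property
    def coverage(self) -> float:
        return self.days_present / self.days_in_month


@dataclass
class ParseStats:
    emitted: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return self.emitted + sum(self.skipped.values())


def parse_timestamp(value: str) -> datetime:
    """Parse the stream's RFC-822-style timestamp (ISO-8601 also accepted);
    naive inputs are taken as UTC."""
    try:
        return datetime.strptime(value, _TWITTER_TS)
    except (ValueError, TypeError):
        pass
    dt = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    return dt if dt.tzinfo else dt.replace(tzinfo=timezone.utc)


def _open_maybe_gzip(source: str | Path) -> IO[bytes]:
    fh = open(source, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(fh)
    return fh


def parse_stream(source: str | Path | Iterable[bytes | str],
                 stats: ParseStats | None = None) -> Iterator[RawTweet]:
    """Yield RawTweets from an NDJSON stream (path, gz path or line iterable).

    Deletion notices (records with a ``delete`` member) and malformed
    lines are skipped; counts land in *stats* per skip reason.
    """
    stats = stats if stats is not None else ParseStats()
    if isinstance(source, (str, Path)):
        lines: Iterable[bytes | str] = _open_maybe_gzip(source)
    else:
        lines = source
    for line in lines:
        if isinstance(line, bytes):
            line = line.decode("utf-8", errors="replace")
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError:
            stats.skip("malformed")
            continue
        if not isinstance(rec, dict):
            stats.skip("malformed")
            continue
        if "delete" in rec:
            stats.skip("deletion_notice")
            continue
        try:
            ts = parse_timestamp(rec["created_at"])
            tweet = RawTweet(
                tweet_id=str(rec["id_str"]),
                user_id=str(rec["user"]["id_str"]),
                user_name=str(rec["user"].get("name", "")),
                lang=str(rec.get("lang", "")),
                created_at=ts,
                is_retweet="retweeted_status" in rec,
                label=rec.get("sentiment_label"),
            )
        except (KeyError, TypeError, ValueError):
            stats.skip("malformed")
            continue
        stats.emitted += 1
        yield tweet
    if stats.skipped:
        logger.info("parse_stream skipped records: %s", stats.skipped)


def filter_corpus(tweets: Iterable[RawTweet], language: str) -> list[RawTweet]:
    """Keep original (non-retweet) tweets whose language tag matches exactly."""
    if not language:
        raise ValueError("language tag must be non-empty")
    return [t for t in tweets if t.lang == language and not t.is_retweet]


def assign_month(tweet: RawTweet) -> str:
    """Calendar month of the timestamp, interpreted in UTC, as 'YYYY-MM'."""
    dt = tweet.created_at.astimezone(timezone.utc)
    return f"{dt.year:04d}-{dt.month:02d}"


def month_windows(tweets: Sequence[RawTweet]) -> list[MonthWindow]:
    """Observed day coverage per calendar month (UTC)."""
    days: dict[str, set[int]] = {}
    for t in tweets:
        dt = t.created_at.astimezone(timezone.utc)
        days.setdefault(f"{dt.year:04d}-{dt.month:02d}", set()).add(dt.day)
    out = []
    for month in sorted(days):
        y, m = map(int, month.split("-"))
        out.append(MonthWindow(month, len(days[month]), monthrange(y, m)[1]))
    return out


def month_coverage_filter(windows: Iterable[MonthWindow],
                          threshold: float = 0.8) -> list[str]:
    """Months retained under the at-least-``threshold``-of-days rule."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return [w.month for w in windows if w.coverage >= threshold]


def attach_labels(tweets: Sequence[RawTweet],
                  labels_csv: str | Path) -> list[RawTweet]:
    """Attach sidecar labels (CSV columns tweet_id, label) to a stream."""
    table = pd.read_csv(labels_csv, dtype=str)
    mapping = dict(zip(table["tweet_id"], table["label"]))
    out = []
    for t in tweets:
        lab = mapping.get(t.tweet_id, t.label)
        out.append(RawTweet(t.tweet_id, t.user_id, t.user_name, t.lang,
                            t.created_at, t.is_retweet, lab))
    return out


def to_frame(tweets: Sequence[RawTweet]) -> pd.DataFrame:
    """Tabular view with assigned months, ready for user-level aggregation."""
    return pd.DataFrame({
        "tweet_id": [t.tweet_id for t in tweets],
        "user_id": [t.user_id for t in tweets],
        "user_name": [t.user_name for t in tweets],
        "month": [assign_month(t) for t in tweets],
        "date": [t.created_at.astimezone(timezone.utc).date().isoformat()
                 for t in tweets],
        "label": [t.label for t in tweets],
    })
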