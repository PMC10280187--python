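"""Synthetic world generator: latent affect, users, tweets, survey waves.

The generator emulates the joint data-generating process the measurement
pipeline assumes: a latent monthly population-affect signal h_t drives
both (a) the positive/negative balance of tweets and (b) the answers of
monthly telephone-survey waves, so the pipeline's output can be checked
against a known ground truth.

Mechanism
---------
* h_t follows a clipped AR(1) on [-1, 1]:  h_t = rho*h_{t-1} + eps_t.
* Each user has a gender (platform shares, default 59% male / 41% female)
  and a full name drawn from a gendered Cyrillic lexicon, so downstream
  name-based gender inference has something to work with.
* In each month a user is active with probability ``activity_prob``;
  active users post a zero-truncated-Poisson number of tweets.
* A tweet's true class is drawn from the base class distribution with
  probability mass delta = sensitivity * (h_t + offset_g) * min(POS,NEG)/2
  moved from NEG to POS; NEU/SA/SKIP stay at base.  The observed class is
  then drawn from the confusion row of the true class, emulating an
  imperfect sentiment classifier.
* Survey waves ask a 4-category happiness item plus "don't know":
  P(happy) = logistic(survey_slope * h_t); happy answers split
  Yes / Rather Yes, unhappy answers No / Rather No.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .biassim import ConfusionMatrix
from .indices import LABELS

_POS, _NEG, _NEU, _SA, _SKIP = range(5)

DEFAULT_BASE_CLASS_PROBS = (0.18, 0.17, 0.40, 0.05, 0.20)
DEFAULT_CONFUSION_DIAGONAL = 0.85


def diagonal_confusion(diag: float = DEFAULT_CONFUSION_DIAGONAL) -> ConfusionMatrix:
    """Symmetric confusion matrix with *diag* on the diagonal and the
    remaining mass spread evenly over the other four classes."""
    off = (1.0 - diag) / 4.0
    m = np.full((5, 5), off)
    np.fill_diagonal(m, diag)
    return ConfusionMatrix(m)


@dataclass
class GeneratorConfig:
    n_months: int = 24
    n_users: int = 5000
    platform_gender_shares: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.59, "female": 0.41})
    census_gender_shares: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.46, "female": 0.54})
    tweets_per_user_month: float = 5.5  # rate of the underlying Poisson
    activity_prob: float = 0.35
    latent_ar_coefficient: float = 0.6
    latent_noise_sd: float = 0.25
    affect_sensitivity: float = 1.0
    base_class_probs: tuple[float, ...] = DEFAULT_BASE_CLASS_PROBS
    confusion: ConfusionMatrix = field(default_factory=diagonal_confusion)
    stratum_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": 0.0})
    survey_n: int = 1600
    survey_slope: float = 2.0
    dont_know_prob: float = 0.05
    strong_answer_prob: float = 0.6  # Yes vs Rather-Yes split (and No vs Rather-No)
    start_month: str = "2019-01"
    sa_day_multipliers: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ValueError("n_months must be at least 2")
        if self.survey_n < 1:
            raise ValueError("survey_n must be at least 1")
        if not -1 < self.latent_ar_coefficient < 1:
            raise ValueError("latent_ar_coefficient must lie in (-1, 1)")
        if self.latent_noise_sd < 0:
            raise ValueError("latent_noise_sd must be non-negative")
        if self.tweets_per_user_month <= 0:
            raise ValueError("tweets_per_user_month must be positive")
        if not 0 < self.activity_prob <= 1:
            raise ValueError("activity_prob must lie in (0, 1]")
        for name, shares in (("platform_gender_shares", self.platform_gender_shares),
                             ("census_gender_shares", self.census_gender_shares)):
            if abs(sum(shares.values()) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")
        probs = np.asarray(self.base_class_probs, dtype=float)
        if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("base_class_probs must be a 5-vector summing to 1")

    @property
    def months(self) -> list[str]:
        start = pd.Period(self.start_month, freq="M")
        return [str(start + i) for i in range(self.n_months)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("generator config must set a seed")
        if "confusion" in raw:
            raw["confusion"] = ConfusionMatrix(np.asarray(raw["confusion"], float))
        if "base_class_probs" in raw:
            raw["base_class_probs"] = tuple(raw["base_class_probs"])
        return cls(**raw)


@dataclass
class LatentAffectSeries:
    """Monthly latent affect h_t in [-1, 1], plus per-gender level offsets."""

    h: np.ndarray
    stratum_offsets: Mapping[str, float]

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if np.any(np.abs(self.h) > 1 + 1e-12):
            raise ValueError("latent values must lie in [-1, 1]")


@dataclass
class SyntheticCorpus:
    users: pd.DataFrame   # user_id, full_name, gender
    tweets: pd.DataFrame  # tweet_id, user_id, month, date, true_label, label
    survey: pd.DataFrame  # month, yes, rather_yes, rather_no, no, dont_know
    latent: LatentAffectSeries
    months: list[str]


def generate_latent_series(cfg: GeneratorConfig,
                           h0: float | None = None) -> LatentAffectSeries:
    """Clipped AR(1) recursion, deterministic given the config seed.

    The series starts at *h0* when given; otherwise at a draw from the
    stationary distribution Normal(0, sd/sqrt(1-rho^2)) so the whole
    series is (approximately) stationary.
    """
    rng = np.random.default_rng(cfg.seed)
    rho, sd = cfg.latent_ar_coefficient, cfg.latent_noise_sd
    h = np.empty(cfg.n_months)
    if h0 is None:
        h0 = rng.normal(0.0, sd / np.sqrt(1.0 - rho ** 2)) if sd > 0 else 0.0
    h[0] = float(np.clip(h0, -1.0, 1.0))
    for t in range(1, cfg.n_months):
        eps = rng.normal(0.0, sd) if sd > 0 else 0.0
        h[t] = float(np.clip(rho * h[t - 1] + eps, -1.0, 1.0))
    return LatentAffectSeries(h=h, stratum_offsets=dict(cfg.stratum_offsets))


def tilted_class_probs(cfg: GeneratorConfig, h_t: float, offset: float,
                       month: str | None = None,
                       stratum: str | None = None) -> np.ndarray:
    """Base class distribution with mass moved from NEG to POS.

    delta = sensitivity * (h_t + offset) * min(base_POS, base_NEG) / 2.
    A tilt that would push a class probability negative is a hard error
    naming the month and stratum.
    """
    base = np.asarray(cfg.base_class_probs, dtype=float)
    delta = (cfg.affect_sensitivity * (h_t + offset)
             * 0.5 * min(base[_POS], base[_NEG]))
    probs = base.copy()
    probs[_POS] += delta
    probs[_NEG] -= delta
    if np.any(probs < 0):
        raise ValueError(
            f"affect tilt produced a negative class probability "
            f"(month={month}, stratum={stratum}, delta={delta:.4f})")
    return probs / probs.sum()


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via inverse CDF on U(P(0), 1)."""
    if size == 0:
        return np.zeros(0, dtype=int)
    from scipy import stats
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(int)


# -- gendered Cyrillic name lexicon ------------------------------------------

_FEMALE_FIRST = (
    "Анна Мария Елена Ольга Наталья Ирина Татьяна Светлана Екатерина Юлия "
    "Дарья Алина Ксения Полина Вера Надежда Любовь Галина Валентина Оксана "
    "Марина Людмила Алла Евгения Виктория Софья Варвара Алиса Кира Лидия"
).split()
_MALE_FIRST = (
    "Александр Дмитрий Сергей Андрей Алексей Максим Иван Михаил Николай "
    "Владимир Пётр Павел Егор Никита Артём Роман Виктор Олег Игорь Юрий "
    "Василий Григорий Степан Фёдор Борис Константин Денис Антон Илья Глеб"
).split()
_SURNAME_STEMS = (
    "Иван Петр Сидор Кузнец Смирн Попов Соколов Лебед Козлов Новик Морозов "
    "Волков Зайцев Павлов Семён Голуб Виноград Богдан Воробь Фёдоров Михайлов "
    "Беляев Тарасов Беляк Комаров Орлов Киселёв Макаров Андреев Ковалёв"
).split()
_MALE_SUFFIXES = ("ов", "ев", "ин")
_FEMALE_SUFFIXES = ("ова", "ева", "ина")


def generate_name(rng: np.random.Generator, gender: str) -> str:
    """A synthetic gendered full name (Cyrillic first name + surname whose
    suffix carries the gender, as Russian surnames do)."""
    stem = _SURNAME_STEMS[rng.integers(len(_SURNAME_STEMS))]
    if gender == "female":
        first = _FEMALE_FIRST[rng.integers(len(_FEMALE_FIRST))]
        suffix = _FEMALE_SUFFIXES[rng.integers(len(_FEMALE_SUFFIXES))]
    else:
        first = _MALE_FIRST[rng.integers(len(_MALE_FIRST))]
        suffix = _MALE_SUFFIXES[rng.integers(len(_MALE_SUFFIXES))]
    return f"{first} {stem}{suffix}"


def generate_name_lexicon(n: int, seed: int,
                          female_share: float = 0.54) -> pd.DataFrame:
    """Synthetic labelled name collection for training the gender model."""
    rng = np.random.default_rng(seed)
    genders = np.where(rng.uniform(size=n) < female_share, "female", "male")
    names = [generate_name(rng, g) for g in genders]
    return pd.DataFrame({"full_name": names, "gender": genders})


# -- corpus -------------------------------------------------------------------

def generate_corpus(cfg: GeneratorConfig,
                    latent: LatentAffectSeries) -> SyntheticCorpus:
    """Users, tweets (true + observed labels) and survey waves.

    Deterministic given the config: all randomness flows from
    ``default_rng(cfg.seed)`` streams derived per component.
    """
    if len(latent.h) != cfg.n_months:
        raise ValueError("latent series length must equal n_months")
    ss = np.random.SeedSequence(cfg.seed)
    rng_users, rng_tweets, _rng_survey = (
        np.random.default_rng(s) for s in ss.spawn(3))

    strata = list(cfg.platform_gender_shares)
    shares = np.array([cfg.platform_gender_shares[g] for g in strata])
    gidx = rng_users.choice(len(strata), size=cfg.n_users, p=shares)
    genders = np.array(strata, dtype=object)[gidx]
    names = [generate_name(rng_users, g) for g in genders]
    user_ids = [f"u{i:07d}" for i in range(cfg.n_users)]
    users = pd.DataFrame(
        {"user_id": user_ids, "full_name": names, "gender": genders})

    months = cfg.months
    cm_rows = cfg.confusion.matrix
    tw_user, tw_month, tw_date, tw_true, tw_obs = [], [], [], [], []
    for t, month in enumerate(months):
        period = pd.Period(month, freq="M")
        n_days = calendar.monthrange(period.year, period.month)[1]
        day_strings = [f"{period.year:04d}-{period.month:02d}-{d:02d}"
                       for d in range(1, n_days + 1)]
        boosts = np.array([cfg.sa_day_multipliers.get(d, 1.0)
                           for d in day_strings])
        for g in strata:
            uids = users.loc[users["gender"] == g, "user_id"].to_numpy()
            active = uids[rng_tweets.uniform(size=len(uids)) < cfg.activity_prob]
            if len(active) == 0:
                continue
            counts = _zt_poisson(rng_tweets, cfg.tweets_per_user_month,
                                 len(active))
            n_tw = int(counts.sum())
            probs = tilted_class_probs(
                cfg, float(latent.h[t]), latent.stratum_offsets.get(g, 0.0),
                month=month, stratum=g)
            days = rng_tweets.integers(0, n_days, size=n_tw)
            if cfg.sa_day_multipliers:
                true_idx = np.empty(n_tw, dtype=int)
                for d in range(n_days):
                    mask = days == d
                    if not mask.any():
                        continue
                    p = probs.copy()
                    p[_SA] = min(p[_SA] * boosts[d], 0.95)
                    p[np.arange(5) != _SA] *= (1 - p[_SA]) / (
                        1 - probs[_SA]) if probs[_SA] < 1 else 1.0
                    p = p / p.sum()
                    true_idx[mask] = rng_tweets.choice(5, size=mask.sum(), p=p)
            else:
                true_idx = rng_tweets.choice(5, size=n_tw, p=probs)
            # classifier noise: observed class from the confusion row
            u = rng_tweets.uniform(size=n_tw)
            cum = np.cumsum(cm_rows, axis=1)
            obs_idx = (u[:, None] > cum[true_idx]).sum(axis=1)
            tw_user.append(np.repeat(active, counts))
            tw_month.append(np.full(n_tw, month, dtype=object))
            tw_date.append(np.array(day_strings, dtype=object)[days])
            tw_true.append(true_idx)
            tw_obs.append(obs_idx)

    label_arr = np.array(LABELS, dtype=object)
    tweets = pd.DataFrame({
        "user_id": np.concatenate(tw_user),
        "month": np.concatenate(tw_month),
        "date": np.concatenate(tw_date),
        "true_label": label_arr[np.concatenate(tw_true)],
        "label": label_arr[np.concatenate(tw_obs)],
    })
    tweets.insert(0, "tweet_id", [f"t{i:09d}" for i in range(len(tweets))])

    survey = generate_survey(cfg, latent)
    return SyntheticCorpus(users=users, tweets=tweets, survey=survey,
                           latent=latent, months=months)


def generate_survey(cfg: GeneratorConfig,
                    latent: LatentAffectSeries) -> pd.DataFrame:
    """Monthly survey waves of ``survey_n`` respondents.

    Each respondent answers "don't know" with a small fixed probability;
    otherwise they are happy with probability logistic(slope * h_t) and
    give the strong form of their answer (Yes / No rather than
    Rather Yes / Rather No) with probability ``strong_answer_prob``.
    """
    if len(latent.h) != cfg.n_months:
        raise ValueError("latent series length must equal n_months")
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    rows = []
    for month, h_t in zip(cfg.months, latent.h):
        p_happy = 1.0 / (1.0 + np.exp(-cfg.survey_slope * h_t))
        u = rng.uniform(size=cfg.survey_n)
        dk = u < cfg.dont_know_prob
        happy = ~dk & (rng.uniform(size=cfg.survey_n) < p_happy)
        unhappy = ~dk & ~happy
        strong = rng.uniform(size=cfg.survey_n) < cfg.strong_answer_prob
        n = cfg.survey_n
        rows.append({
            "month": month,
            "yes": (happy & strong).sum() / n,
            "rather_yes": (happy & ~strong).sum() / n,
            "rather_no": (unhappy & ~strong).sum() / n,
            "no": (unhappy & strong).sum() / n,
            "dont_know": dk.sum() / n,
        })
    return pd.DataFrame(rows)


# -- serialization ------------------------------------------------------------

_WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_MONTHS_ABBR = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def _created_at(date: str, rng: np.random.Generator) -> str:
    """Twitter-dialect RFC-822-style timestamp for a calendar date (UTC)."""
    y, m, d = map(int, date.split("-"))
    wd = _WEEKDAYS[calendar.weekday(y, m, d)]
    hh, mm, sec = rng.integers(0, 24), rng.integers(0, 60), rng.integers(0, 60)
    return f"{wd} {_MONTHS_ABBR[m-1]} {d:02d} {hh:02d}:{mm:02d}:{sec:02d} +0000 {y}"


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path,
                 seed: int = 0, lang: str = "ru",
                 retweet_fraction: float = 0.0,
                 foreign_fraction: float = 0.0) -> dict[str, Path]:
    """Write the corpus in the ingest dialect.

    tweets.ndjson carries the observed label embedded as
    ``sentiment_label``; optional fractions of retweets and foreign-
    language tweets are injected as *extra* records so filtering has
    something to remove.  Ground truth and the survey go to CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    name_of = dict(zip(corpus.users["user_id"], corpus.users["full_name"]))
    paths = {
        "tweets": out / "tweets.ndjson",
        "survey": out / "survey.csv",
        "users": out / "users_truth.csv",
        "tweets_truth": out / "tweets_truth.csv",
    }
    with open(paths["tweets"], "w", encoding="utf-8") as fh:
        for row in corpus.tweets.itertuples(index=False):
            rec = {
                "id_str": row.tweet_id,
                "user": {"id_str": row.user_id,
                         "name": name_of[row.user_id]},
                "lang": lang,
                "created_at": _created_at(row.date, rng),
                "sentiment_label": row.label,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            if retweet_fraction and rng.uniform() < retweet_fraction:
                rt = dict(rec, id_str="r" + row.tweet_id[1:],
                          retweeted_status={"id_str": row.tweet_id})
                fh.write(json.dumps(rt, ensure_ascii=False) + "\n")
            if foreign_fraction and rng.uniform() < foreign_fraction:
                fo = dict(rec, id_str="f" + row.tweet_id[1:], lang="en")
                fh.write(json.dumps(fo, ensure_ascii=False) + "\n")
    corpus.survey.to_csv(paths["survey"], index=False)
    corpus.users.to_csv(paths["users"], index=False)
    corpus.tweets.to_csv(paths["tweets_truth"], index=False)
    return paths
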