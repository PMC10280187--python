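"""End-to-end orchestration: stream -> filters -> gender -> indices -> reliability.

`run_pipeline` drives the five measurement steps on serialized inputs;
`run_demo` generates the default synthetic scenario, runs the pipeline
on it, and reports how well the measured indicator series recover the
known latent ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import biassim, demographics, indices, ingest, reliability, synthgen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    stream_path: str | Path
    survey_path: str | Path
    labels_path: str | Path | None = None
    name_lexicon_path: str | Path | None = None  # training CSV for the gender model
    census_gender_shares: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.46, "female": 0.54})
    language: str = "ru"
    coverage_threshold: float = 0.8
    min_sample: int = 1600
    alpha: float = 0.05
    difference: bool | str = "auto"
    kinds: tuple[str, ...] = indices.INDICATOR_KINDS
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must lie in (0, 1]")
        if self.min_sample < 0:
            raise ValueError("min_sample must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineResult:
    indices: dict[tuple[str, str], indices.OSWBIndexSeries]
    index_frame: pd.DataFrame
    report: pd.DataFrame
    n_users: dict[str, int]
    dropped_months: dict[str, str]
    parse_stats: ingest.ParseStats
    genders: dict[str, str]


def measure_from_tweets(
    tweets: pd.DataFrame,
    genders: Mapping[str, str],
    census: indices.GenderDistribution,
    min_sample: int = 1600,
    kinds: tuple[str, ...] = indices.INDICATOR_KINDS,
) -> tuple[dict[tuple[str, str], indices.OSWBIndexSeries],
           dict[str, int], dict[str, str]]:
    """User-level aggregation + indices for a labelled tweet table.

    Returns (series dict, users-per-month, dropped months with reasons).
    """
    labels_by_month: dict[str, list[indices.UserMonthLabel]] = {}
    n_users: dict[str, int] = {}
    dropped: dict[str, str] = {}
    for month, grp in tweets.groupby("month", sort=True):
        recs = indices.aggregate_user_month(grp, str(month))
        ok, n = indices.check_min_sample(recs, min_sample)
        n_users[str(month)] = n
        if not ok:
            dropped[str(month)] = f"below minimum sample ({n} < {min_sample})"
            logger.info("month %s dropped: %s", month, dropped[str(month)])
            continue
        labels_by_month[str(month)] = recs
    if not labels_by_month:
        raise ValueError("no month passed the minimum-sample rule")
    series = indices.compute_series(labels_by_month, genders, census, kinds)
    return series, n_users, dropped


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute ingest -> gender inference -> aggregation -> indices ->
    reliability on serialized inputs, logging every exclusion."""
    stats = ingest.ParseStats()
    tweets = list(ingest.parse_stream(cfg.stream_path, stats))
    tweets = ingest.filter_corpus(tweets, cfg.language)
    if cfg.labels_path:
        tweets = ingest.attach_labels(tweets, cfg.labels_path)
    windows = ingest.month_windows(tweets)
    kept_months = set(ingest.month_coverage_filter(windows,
                                                   cfg.coverage_threshold))
    dropped_cov = {w.month: f"day coverage {w.coverage:.2f} below "
                            f"{cfg.coverage_threshold}"
                   for w in windows if w.month not in kept_months}
    frame = ingest.to_frame(tweets)
    frame = frame[frame["month"].isin(kept_months)]
    if frame["label"].isna().any():
        raise ValueError("tweets without sentiment labels after ingest")

    # gender inference from display names
    if cfg.name_lexicon_path:
        lexicon = pd.read_csv(cfg.name_lexicon_path)
    else:
        lexicon = synthgen.generate_name_lexicon(10000, seed=cfg.seed)
    model, metrics = demographics.train_and_evaluate(lexicon, seed=cfg.seed)
    logger.info("gender model held-out F1: %s", metrics)
    users = frame[["user_id", "user_name"]].drop_duplicates("user_id")
    predicted = demographics.predict_gender(model,
                                            users["user_name"].tolist())
    genders = dict(zip(users["user_id"], predicted))

    census = indices.GenderDistribution(dict(cfg.census_gender_shares),
                                        provenance="census")
    series, n_users, dropped_min = measure_from_tweets(
        frame, genders, census, cfg.min_sample, cfg.kinds)
    dropped = {**dropped_cov, **dropped_min}

    survey_shares = pd.read_csv(cfg.survey_path)
    survey = reliability.compute_survey_indices(survey_shares)
    report = reliability.reliability_report(series, survey,
                                            cfg.difference, cfg.alpha)
    index_frame = indices.series_frame(series, n_users)
    if cfg.out_dir:
        _write_outputs(cfg, index_frame, report)
    return PipelineResult(indices=series, index_frame=index_frame,
                          report=report, n_users=n_users,
                          dropped_months=dropped, parse_stats=stats,
                          genders=genders)


def _config_hash(cfg: PipelineConfig) -> str:
    payload = {k: str(v) for k, v in cfg.__dict__.items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_outputs(cfg: PipelineConfig, index_frame: pd.DataFrame,
                   report: pd.DataFrame) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_frame.to_csv(out / "indices.csv", index=False,
                       float_format="%.10g")
    report.to_csv(out / "reliability.csv", index=False, float_format="%.10g")
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "n_index_rows": len(index_frame)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


# -- synthetic end-to-end scenarios ------------------------------------------

def default_scenario(seed: int = 42, **overrides) -> synthgen.GeneratorConfig:
    """The standard recovery scenario: 24 months, 5,000 users, affect
    sensitivity 1, diagonal-0.85 confusion."""
    params = dict(n_months=24, n_users=5000, affect_sensitivity=1.0,
                  confusion=synthgen.diagonal_confusion(0.85), seed=seed)
    params.update(overrides)
    return synthgen.GeneratorConfig(**params)


def gender_skew_scenario(seed: int = 42, **overrides) -> synthgen.GeneratorConfig:
    """Platform gender mix skewed against the census and genders differing
    in affect level, so the raw series is demographically biased.  Runs
    with an identity confusion matrix to isolate the skew effect."""
    params = dict(n_months=24, n_users=5000, affect_sensitivity=1.0,
                  confusion=biassim.ConfusionMatrix.identity(),
                  stratum_offsets={"male": -0.2, "female": 0.2},
                  platform_gender_shares={"male": 0.59, "female": 0.41},
                  seed=seed)
    params.update(overrides)
    return synthgen.GeneratorConfig(**params)


@dataclass
class RecoveryResult:
    recovery_spearman: float        # poststratified PA vs survey PA
    recovery_p: float
    report: pd.DataFrame
    series: dict[tuple[str, str], indices.OSWBIndexSeries]
    survey: dict[str, pd.Series]
    gender_metrics: dict[str, float]
    n_users: dict[str, int]


def run_synthetic_recovery(cfg: synthgen.GeneratorConfig,
                           min_sample: int = 1600,
                           difference: bool | str = False) -> RecoveryResult:
    """Generate a synthetic world, run measurement on its *observed*
    labels with *predicted* genders, and correlate against its survey.

    The headline number is Spearman(poststratified PA, survey PA): how
    well the tweet side recovers the latent affect the survey also sees.
    """
    latent = synthgen.generate_latent_series(cfg)
    corpus = synthgen.generate_corpus(cfg, latent)

    lexicon = synthgen.generate_name_lexicon(10000, seed=cfg.seed + 1)
    model, metrics = demographics.train_and_evaluate(lexicon, seed=1)
    predicted = demographics.predict_gender(
        model, corpus.users["full_name"].tolist())
    genders = dict(zip(corpus.users["user_id"], predicted))

    census = indices.GenderDistribution(dict(cfg.census_gender_shares),
                                        provenance="census")
    series, n_users, _dropped = measure_from_tweets(
        corpus.tweets, genders, census, min_sample)
    survey = reliability.compute_survey_indices(corpus.survey)
    report = reliability.reliability_report(series, survey, difference)
    rep = reliability.correlate(series[("PA", "poststratified")].values,
                                survey["PA"], difference,
                                ids=("OSWB_PA:poststratified", "survey_PA"))
    return RecoveryResult(recovery_spearman=rep.spearman_r,
                          recovery_p=rep.p_value, report=report,
                          series=series, survey=survey,
                          gender_metrics=metrics, n_users=n_users)


def skew_comparison(cfg: synthgen.GeneratorConfig,
                    min_sample: int = 1600) -> dict[str, float]:
    """Mean absolute error of the raw vs post-stratified PA series against
    the census-weighted *true* PA series (true labels, true genders)."""
    latent = synthgen.generate_latent_series(cfg)
    corpus = synthgen.generate_corpus(cfg, latent)

    lexicon = synthgen.generate_name_lexicon(10000, seed=cfg.seed + 1)
    model, _ = demographics.train_and_evaluate(lexicon, seed=1)
    predicted = demographics.predict_gender(
        model, corpus.users["full_name"].tolist())
    genders_pred = dict(zip(corpus.users["user_id"], predicted))
    genders_true = dict(zip(corpus.users["user_id"], corpus.users["gender"]))
    census = indices.GenderDistribution(dict(cfg.census_gender_shares),
                                        provenance="census")

    observed, _, _ = measure_from_tweets(corpus.tweets, genders_pred,
                                         census, min_sample, kinds=("PA",))
    truth_tweets = corpus.tweets.drop(columns=["label"]).rename(
        columns={"true_label": "label"})
    truth, _, _ = measure_from_tweets(truth_tweets, genders_true, census,
                                      min_sample, kinds=("PA",))
    true_pa = truth[("PA", "poststratified")].values
    raw = observed[("PA", "raw")].values
    ps = observed[("PA", "poststratified")].values
    shared = sorted(set(true_pa.index) & set(raw.index))
    return {
        "mae_raw": float((raw.loc[shared] - true_pa.loc[shared]).abs().mean()),
        "mae_poststratified": float(
            (ps.loc[shared] - true_pa.loc[shared]).abs().mean()),
    }


def run_demo(seed: int = 42, biassim_iterations: int = 1000
             ) -> dict[str, object]:
    """Default synthetic scenario end-to-end plus the bias simulation."""
    recovery = run_synthetic_recovery(default_scenario(seed))
    skew = skew_comparison(gender_skew_scenario(seed))
    sim = biassim.assess_indicator_bias(
        biassim.BiasSimConfig(iterations=biassim_iterations, seed=seed),
        synthgen.diagonal_confusion(0.85))
    return {"recovery": recovery, "skew": skew, "biassim": sim}
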