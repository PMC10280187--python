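"""Name-based gender inference and gender-distribution bookkeeping.

Russian full names usually carry grammatical gender — first names divide
cleanly into male and female, and surname endings (-ов/-ова, -ев/-ева,
-ин/-ина) mark gender — so a character-n-gram model over the full name
is both simple and highly accurate.  The featurization is TF-IDF over
character n-grams taken *inside word boundaries* (each word padded with
one boundary marker per side, so terminal n-grams — the informative
suffixes — are distinguishable), n-gram lengths 2–7, IDF on, L2
normalisation, and terms occurring in more than half the documents
ignored.  The classifier is L2-regularized logistic regression.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .indices import GenderDistribution

UNKNOWN = "unknown"


@dataclass(frozen=True)
class NameFeaturizerConfig:
    ngram_min: int = 2
    ngram_max: int = 7
    within_word_boundaries: bool = True
    use_idf: bool = True
    norm: str = "l2"
    max_document_frequency: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.ngram_min <= self.ngram_max:
            raise ValueError("need 1 <= ngram_min <= ngram_max")

    def build_vectorizer(self) -> TfidfVectorizer:
        return TfidfVectorizer(
            analyzer="char_wb" if self.within_word_boundaries else "char",
            ngram_range=(self.ngram_min, self.ngram_max),
            use_idf=self.use_idf,
            norm=self.norm,
            max_df=self.max_document_frequency,
            lowercase=True,
        )


def name_ngrams(name: str, cfg: NameFeaturizerConfig | None = None) -> list[str]:
    """The raw n-gram token stream for one (case-folded) name."""
    cfg = cfg or NameFeaturizerConfig()
    analyzer = cfg.build_vectorizer().build_analyzer()
    return analyzer(name.lower())


@dataclass
class GenderModel:
    """Fitted featurizer + linear classifier for binary gender."""

    config: NameFeaturizerConfig
    vectorizer: TfidfVectorizer
    classifier: LogisticRegression

    def featurize(self, names: Sequence[str]) -> sparse.csr_matrix:
        cleaned = [n.strip() for n in names]
        if any(not n for n in cleaned):
            raise ValueError("cannot featurize an empty name")
        return self.vectorizer.transform(cleaned)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "GenderModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("archive does not contain a GenderModel")
        return model


def train_gender_model(names: pd.DataFrame,
                       cfg: NameFeaturizerConfig | None = None,
                       reg_strength: float = 1.0,
                       seed: int = 0) -> GenderModel:
    """Fit the TF-IDF + logistic-regression gender classifier.

    Parameters
    ----------
    names : DataFrame with columns ``full_name`` and ``gender``
        (values "male"/"female"); both genders must be present and at
        least 50 examples supplied.
    reg_strength : L2 regularization knob, passed through as the
        classifier's C (default 1.0); grid-searchable by the caller.
    """
    cfg = cfg or NameFeaturizerConfig()
    if len(names) < 50:
        raise ValueError("need at least 50 training examples")
    classes = set(names["gender"])
    if classes != {"male", "female"}:
        raise ValueError(f"need both genders in training data, got {classes}")
    if reg_strength <= 0:
        raise ValueError("reg_strength must be positive")
    vec = cfg.build_vectorizer()
    X = vec.fit_transform(names["full_name"].str.strip())
    # L2 penalty (sklearn default), strength via C
    clf = LogisticRegression(C=reg_strength, max_iter=1000, random_state=seed)
    clf.fit(X, names["gender"])
    return GenderModel(config=cfg, vectorizer=vec, classifier=clf)


def train_and_evaluate(names: pd.DataFrame,
                       cfg: NameFeaturizerConfig | None = None,
                       reg_strength: float = 1.0,
                       test_size: float = 0.2,
                       seed: int = 0) -> tuple[GenderModel, dict[str, float]]:
    """80/20 split, fit on the training part only, metrics on the held-out
    part (both binary-positive-class and macro F1 are reported)."""
    train, test = train_test_split(names, test_size=test_size,
                                   random_state=seed,
                                   stratify=names["gender"])
    model = train_gender_model(train, cfg, reg_strength, seed)
    pred = predict_gender(model, test["full_name"].tolist())
    metrics = {
        "f1_binary_female": f1_score(test["gender"], pred,
                                     pos_label="female"),
        "f1_macro": f1_score(test["gender"], pred, average="macro"),
        "n_train": float(len(train)),
        "n_test": float(len(test)),
    }
    return model, metrics


def predict_gender(model: GenderModel, names: Sequence[str]) -> list[str]:
    """One label per name; empty/degenerate names get "unknown" and are
    excluded from stratified counts downstream."""
    cleaned = [str(n).strip() if n is not None else "" for n in names]
    out = [UNKNOWN] * len(cleaned)
    idx = [i for i, n in enumerate(cleaned) if n]
    if idx:
        preds = model.classifier.predict(
            model.vectorizer.transform([cleaned[i] for i in idx]))
        for i, p in zip(idx, preds):
            out[i] = str(p)
    return out


def estimate_sample_distribution(users: pd.DataFrame) -> tuple[GenderDistribution, int]:
    """Gender shares over known-gender users; unknown count alongside."""
    known = users[users["gender"].isin(("male", "female"))]
    n_unknown = len(users) - len(known)
    if len(known) == 0:
        raise ValueError("no users with known gender")
    shares = (known["gender"].value_counts(normalize=True)).to_dict()
    shares.setdefault("male", 0.0)
    shares.setdefault("female", 0.0)
    return GenderDistribution(shares, provenance="sample"), n_unknown
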