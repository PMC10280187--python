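"""User-month aggregation, post-stratification and the seven indicators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oswb import indices
from oswb.indices import (LABELS, GenderDistribution, SentimentCounts,
                          UserMonthLabel, aggregate_user_month,
                          check_min_sample, compute_indicator, compute_series,
                          count_by_stratum, majority_label,
                          poststratification_weights)

counts_strategy = st.builds(
    SentimentCounts,
    *[st.floats(min_value=0, max_value=1e6, allow_nan=False)
      for _ in range(5)])


def oracle_majority(labels):
    """Independent re-statement of the voting rule via explicit loops:
    count each class, collect the classes at the maximum, resolve ties
    toward Neutral (NEU tied, or a POS/NEG conflict), else walk the
    precedence list."""
    tally = {}
    for lab in labels:
        tally[lab] = tally.get(lab, 0) + 1
    top = max(tally.values())
    tied = sorted(lab for lab, n in tally.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    if "NEU" in tied:
        return "NEU"
    if "POS" in tied and "NEG" in tied:
        return "NEU"
    for lab in ("SKIP", "SA", "POS", "NEG"):
        if lab in tied:
            return lab


class TestMajorityVoting:
    def test_strict_majority(self):
        assert majority_label(["POS", "POS", "NEG"]) == "POS"

    def test_conflicting_affect_tie_collapses_to_neutral(self):
        assert majority_label(["POS", "NEG"]) == "NEU"

    def test_neutral_wins_ties_it_is_part_of(self):
        assert majority_label(["POS", "NEU"]) == "NEU"
        assert majority_label(["NEU", "NEG", "NEG", "NEU"]) == "NEU"

    def test_order_invariance(self):
        labs = ["POS", "NEG", "NEU", "POS", "SKIP"]
        results = {majority_label(list(p))
                   for p in itertools.permutations(labs)}
        assert len(results) == 1

    def test_exhaustive_against_oracle(self):
        """Every label sequence of length 1..5 (5 + 25 + ... + 3,125 cases)
        matches the independent enumeration oracle."""
        for n in range(1, 6):
            for seq in itertools.product(LABELS, repeat=n):
                assert majority_label(list(seq)) == oracle_majority(seq)

    def test_unlabelled_tweet_is_hard_error(self):
        with pytest.raises(ValueError):
            majority_label(["POS", "???"])
        frame = pd.DataFrame({"user_id": ["u"], "label": [None]})
        with pytest.raises(ValueError):
            aggregate_user_month(frame, "2020-01")

    def test_aggregate_user_month_one_record_per_user(self):
        frame = pd.DataFrame({
            "user_id": ["a", "a", "a", "b"],
            "label": ["POS", "POS", "NEG", "SA"]})
        recs = aggregate_user_month(frame, "2020-01")
        assert {(r.user_id, r.label, r.n_tweets) for r in recs} == {
            ("a", "POS", 3), ("b", "SA", 1)}


class TestIndicators:
    def test_uniform_counts(self):
        c = SentimentCounts(1, 1, 1, 1, 1)
        assert compute_indicator(c, "PA") == pytest.approx(0.2)
        assert compute_indicator(c, "Net") == pytest.approx(0.0)
        assert compute_indicator(c, "SA") == pytest.approx(0.2)

    def test_worked_arithmetic(self):
        c = SentimentCounts(POS=3, NEG=2, NEU=4, SA=1, SKIP=0)
        assert compute_indicator(c, "PA") == pytest.approx(0.3)
        assert compute_indicator(c, "PA_Neu") == pytest.approx(0.75)
        assert compute_indicator(c, "Net") == pytest.approx(0.1)

    def test_zero_positive_posts_hits_lower_bound(self):
        c = SentimentCounts(POS=0, NEG=2, NEU=4, SA=1, SKIP=1)
        assert compute_indicator(c, "PA") == 0.0
        assert compute_indicator(c, "PA_Neu") == 0.0

    def test_zero_denominators_are_named_errors(self):
        with pytest.raises(indices.UndefinedIndicatorError, match="PA"):
            compute_indicator(SentimentCounts(), "PA", month="2020-01")
        with pytest.raises(indices.UndefinedIndicatorError, match="NEU"):
            compute_indicator(SentimentCounts(POS=1), "PA_Neu")

    @given(counts_strategy)
    def test_net_identity_and_normalization(self, c):
        if c.total <= 0:
            return
        pa = compute_indicator(c, "PA")
        na = compute_indicator(c, "NA")
        sa = compute_indicator(c, "SA")
        assert compute_indicator(c, "Net") == pytest.approx(pa - na, abs=1e-12)
        assert pa + na + sa + c.NEU / c.total + c.SKIP / c.total == \
            pytest.approx(1.0, abs=1e-12)

    @given(counts_strategy)
    def test_neu_relative_identity(self, c):
        if c.NEU < 1e-6:
            return
        assert compute_indicator(c, "Net_Neu") == pytest.approx(
            compute_indicator(c, "PA_Neu") - compute_indicator(c, "NA_Neu"),
            rel=1e-12, abs=1e-12)

    def test_monotonicity_in_pos(self):
        c = SentimentCounts(POS=3, NEG=2, NEU=4, SA=1, SKIP=2)
        c2 = SentimentCounts(POS=4, NEG=2, NEU=4, SA=1, SKIP=1)
        assert compute_indicator(c2, "PA") > compute_indicator(c, "PA")
        assert compute_indicator(c2, "Net") > compute_indicator(c, "Net")


class TestMinSample:
    def _labels(self, n):
        return [UserMonthLabel(f"u{i}", "2020-01", "POS", 1) for i in range(n)]

    @pytest.mark.parametrize("n,ok", [(1600, True), (1599, False), (0, False)])
    def test_threshold(self, n, ok):
        passed, count = check_min_sample(self._labels(n))
        assert (passed, count) == (ok, n)


class TestCountByStratum:
    def test_counts_users_not_tweets(self):
        labels = [UserMonthLabel("a", "m", "POS", 5),
                  UserMonthLabel("b", "m", "POS", 1),
                  UserMonthLabel("c", "m", "NEG", 2)]
        genders = {"a": "male", "b": "male", "c": "female"}
        per, unknown = count_by_stratum(labels, genders)
        assert per["male"].POS == 2 and per["female"].NEG == 1
        assert unknown == 0

    def test_empty(self):
        per, unknown = count_by_stratum([], {})
        assert per == {} and unknown == 0

    def test_conservation_with_unknowns(self):
        labels = [UserMonthLabel(f"u{i}", "m", "NEU", 1) for i in range(10)]
        genders = {f"u{i}": ("male" if i < 4 else "unknown") for i in range(10)}
        per, unknown = count_by_stratum(labels, genders)
        assert sum(c.total for c in per.values()) + unknown == 10


class TestWeights:
    def test_sample_equals_census_gives_unit_weights(self):
        d = GenderDistribution({"male": 0.46, "female": 0.54})
        assert poststratification_weights(d, d) == {"male": 1.0, "female": 1.0}

    def test_direct_division(self):
        sample = GenderDistribution({"male": 0.75, "female": 0.25})
        census = GenderDistribution({"male": 0.46, "female": 0.54}, "census")
        w = poststratification_weights(sample, census)
        assert w["male"] == pytest.approx(0.46 / 0.75)
        assert w["female"] == pytest.approx(2.16)

    @given(st.floats(min_value=0.05, max_value=0.95),
           st.floats(min_value=0.05, max_value=0.95))
    def test_weighted_sample_mass_is_one(self, p_male, c_male):
        sample = GenderDistribution({"male": p_male, "female": 1 - p_male})
        census = GenderDistribution({"male": c_male, "female": 1 - c_male})
        w = poststratification_weights(sample, census)
        assert sum(w[g] * sample.shares[g] for g in w) == pytest.approx(
            1.0, abs=1e-9)

    def test_empty_stratum_is_degenerate(self):
        sample = GenderDistribution({"male": 1.0, "female": 0.0})
        census = GenderDistribution({"male": 0.46, "female": 0.54})
        with pytest.raises(ValueError):
            poststratification_weights(sample, census)


def brute_force_weighted_counts(labels, genders, census):
    """Per-user oracle: each user's unit vote scaled by census/sample."""
    known = [r for r in labels if genders.get(r.user_id, "unknown") != "unknown"]
    n = len(known)
    sample = {}
    for r in known:
        g = genders[r.user_id]
        sample[g] = sample.get(g, 0) + 1 / n
    out = dict.fromkeys(LABELS, 0.0)
    for r in known:
        g = genders[r.user_id]
        out[r.label] += census.shares[g] / sample[g]
    return out


class TestComputeSeries:
    CENSUS = GenderDistribution({"male": 0.46, "female": 0.54}, "census")

    def test_hand_computed_reweighting(self):
        """3 male users (2 POS, 1 NEU) + 1 female NEG: weighted counts
        POS=1.2267, NEU=0.6133, NEG=2.16, total 4 ⇒ PA=0.3067."""
        labels = [UserMonthLabel("m1", "2020-01", "POS", 1),
                  UserMonthLabel("m2", "2020-01", "POS", 1),
                  UserMonthLabel("m3", "2020-01", "NEU", 1),
                  UserMonthLabel("f1", "2020-01", "NEG", 1)]
        genders = {"m1": "male", "m2": "male", "m3": "male", "f1": "female"}
        series = compute_series({"2020-01": labels}, genders, self.CENSUS)
        pa = series[("PA", "poststratified")].values["2020-01"]
        assert pa == pytest.approx(1.2266667 / 4.0, abs=1e-6)
        oracle = brute_force_weighted_counts(labels, genders, self.CENSUS)
        assert pa == pytest.approx(
            oracle["POS"] / sum(oracle.values()), abs=1e-9)

    def test_weights_all_one_gives_raw_equals_poststratified(self):
        labels = [UserMonthLabel(f"u{i}", "2020-01",
                                 ["POS", "NEG", "NEU"][i % 3], 1)
                  for i in range(100)]
        genders = {f"u{i}": ("male" if i < 46 else "female")
                   for i in range(100)}
        series = compute_series({"2020-01": labels}, genders, self.CENSUS)
        for kind in indices.INDICATOR_KINDS:
            raw = series[(kind, "raw")].values
            ps = series[(kind, "poststratified")].values
            pd.testing.assert_series_equal(raw, ps)

    def test_oracle_equivalence_small_worlds(self):
        """compute_series on ≤ 20 users matches the exhaustive per-user
        reweighting oracle for every indicator."""
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = rng.integers(4, 21)
            labels = [UserMonthLabel(f"u{i}", "2020-01",
                                     LABELS[rng.integers(5)], 1)
                      for i in range(n)]
            genders = {f"u{i}": ("male" if rng.uniform() < 0.6 else "female")
                       for i in range(n)}
            if len({genders[f"u{i}"] for i in range(n)}) < 2:
                continue
            try:
                series = compute_series({"2020-01": labels}, genders,
                                        self.CENSUS)
            except indices.UndefinedIndicatorError:
                continue  # no NEU user drawn this trial
            oracle = brute_force_weighted_counts(labels, genders, self.CENSUS)
            c = SentimentCounts(**oracle)
            for kind in indices.INDICATOR_KINDS:
                try:
                    expected = compute_indicator(c, kind)
                except indices.UndefinedIndicatorError:
                    continue
                got = series[(kind, "poststratified")].values["2020-01"]
                assert got == pytest.approx(expected, abs=1e-9)

    def test_weighted_mass_equals_known_users(self):
        labels = [UserMonthLabel(f"u{i}", "2020-01",
                                 LABELS[i % 5], 1) for i in range(50)]
        genders = {f"u{i}": ("male" if i % 3 else "female")
                   for i in range(50)}
        per, _ = count_by_stratum(labels, genders)
        n_known = sum(c.total for c in per.values())
        sample = GenderDistribution(
            {g: c.total / n_known for g, c in per.items()})
        w = poststratification_weights(sample, self.CENSUS)
        assert sum(w[g] * per[g].total for g in per) == pytest.approx(n_known)
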