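"""Report categories, multilevel frequency estimates, temporal profiles."""

import numpy as np
import pandas as pd
import pytest

from emonet import (
    SyntheticConfig,
    categorize_report,
    categorize_reports,
    estimate_frequency,
    fluctuation_magnitude,
    frequency_table,
    generate_dataset,
    positive_negative_ratio,
    temporal_profile,
)
from emonet.frequency import TemporalProfile

from conftest import make_dataset


def vec(taxonomy, **endorsed):
    v = np.zeros(len(taxonomy), dtype=int)
    for name in endorsed:
        v[taxonomy.index(name)] = 1
    return v


class TestCategorize:
    def test_positive_only(self, taxonomy):
        assert categorize_report(vec(taxonomy, joy=1, love=1), taxonomy) == "positive_only"

    def test_mixed(self, taxonomy):
        assert categorize_report(vec(taxonomy, joy=1, anxiety=1), taxonomy) == "mixed"

    def test_negative_only(self, taxonomy):
        assert categorize_report(vec(taxonomy, fear=1), taxonomy) == "negative_only"

    def test_all_zero_is_none(self, taxonomy):
        assert categorize_report(np.zeros(18, dtype=int), taxonomy) == "none"

    def test_length_mismatch_fatal(self, taxonomy):
        with pytest.raises(ValueError, match="length"):
            categorize_report(np.zeros(17, dtype=int), taxonomy)

    def test_vectorized_matches_scalar(self, small_dataset):
        series = categorize_reports(small_dataset)
        for i, rep in enumerate(small_dataset.reports()):
            assert series.iloc[i] == categorize_report(
                rep.indicators, small_dataset.taxonomy
            )


class TestEstimateFrequency:
    def test_every_report_endorsing_gives_100(self, taxonomy):
        X = np.zeros((10, 18), dtype=int)
        X[:, 0] = 1
        ds = make_dataset(X, participant_ids=np.repeat(["a", "b"], 5))
        est = estimate_frequency(ds, "any")
        assert est.estimate == 100.0
        assert est.ci_high == 100.0

    def test_balanced_design_equals_grand_mean(self, taxonomy):
        # 2 participants x 2 reports, outcomes (1,1) and (1,0): the
        # compound-symmetry estimate is the grand mean, 75%
        X = np.zeros((4, 18), dtype=int)
        X[[0, 1, 2], 0] = 1
        ds = make_dataset(X, participant_ids=["a", "a", "b", "b"])
        est = estimate_frequency(ds, taxonomy.emotions[0])
        assert est.estimate == pytest.approx(75.0, abs=1e-6)

    def test_single_participant_falls_back_to_binomial_ci(self, taxonomy):
        X = np.zeros((20, 18), dtype=int)
        X[:7, 0] = 1
        ds = make_dataset(X, participant_ids=["solo"] * 20)
        with pytest.warns(UserWarning, match="single participant"):
            est = estimate_frequency(ds, taxonomy.emotions[0])
        assert est.ci_method == "binomial"
        assert est.ci_low < est.estimate < est.ci_high

    def test_recovers_target_prevalence(self):
        cfg = SyntheticConfig(
            n_participants=500, prompts_per_participant=20,
            prompts_dispersion=50, hour_amplitude={}, seed=77,
        )
        ds = generate_dataset(cfg)
        est = estimate_frequency(ds, "joy")
        assert 33 <= est.estimate <= 37
        assert est.ci_low < 35 < est.ci_high

    def test_logit_link_close_to_identity(self, small_dataset):
        a = estimate_frequency(small_dataset, "joy", link="identity")
        b = estimate_frequency(small_dataset, "joy", link="logit")
        assert abs(a.estimate - b.estimate) < 1.0
        assert b.ci_low < b.estimate < b.ci_high

    def test_unknown_target_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown target"):
            estimate_frequency(small_dataset, "nostalgia")


class TestFrequencyTable:
    def test_has_22_rows(self, small_dataset):
        table = frequency_table(small_dataset, method="pooled")
        assert len(table) == 22
        assert (table.kind == "emotion").sum() == 18
        assert (table.kind == "category").sum() == 3

    def test_all_zero_dataset(self):
        ds = make_dataset(np.zeros((6, 18), dtype=int),
                          participant_ids=np.repeat(["a", "b", "c"], 2))
        table = frequency_table(ds, method="pooled")
        assert (table.estimate_pct == 0).all()

    def test_emotions_sorted_descending(self, small_dataset):
        table = frequency_table(small_dataset, method="pooled")
        emo = table[table.kind == "emotion"]["estimate_pct"].to_numpy()
        assert (np.diff(emo) <= 1e-12).all()

    def test_any_matches_independence_closed_form(self):
        # independent emotions: any-emotion frequency = 1 - prod(1 - p_e)
        cfg = SyntheticConfig(
            n_participants=10_000, prompts_per_participant=10,
            prompts_dispersion=1e6, latent_corr=np.eye(18).tolist(),
            sigma_u=0.0, hour_amplitude={}, seed=21,
        )
        ds = generate_dataset(cfg)
        p = cfg.prevalence_vector()
        expected = 100 * (1 - np.prod(1 - p))
        got = estimate_frequency(ds, "any", method="pooled").estimate
        assert got == pytest.approx(expected, abs=0.6)


class TestRatio:
    def test_ratio_from_category_frequencies(self):
        # 41% positive-only vs 16% negative-only -> 2.5625, the "2.5 times"
        # headline asymmetry
        rng = np.random.default_rng(0)
        n = 10_000
        X = np.zeros((n, 18), dtype=int)
        cat = rng.choice(4, n, p=[0.41, 0.16, 0.33, 0.10])
        X[cat == 0, 5] = 1  # joy
        X[cat == 1, 10] = 1  # anxiety
        X[cat == 2, 5] = 1
        X[cat == 2, 10] = 1
        ds = make_dataset(X, participant_ids=rng.choice(50, n).astype(str))
        r = positive_negative_ratio(ds)
        exact = (cat == 0).mean() / (cat == 1).mean()
        assert r == pytest.approx(exact, rel=1e-9)
        assert r == pytest.approx(2.5625, rel=0.06)

    def test_equal_categories_give_one(self, taxonomy):
        X = np.zeros((4, 18), dtype=int)
        X[:2, 0] = 1  # positive only
        X[2:, 9] = 1  # negative only
        ds = make_dataset(X, participant_ids=["a", "b", "a", "b"])
        assert positive_negative_ratio(ds) == pytest.approx(1.0)

    def test_no_negative_endorsements_flagged(self, taxonomy):
        X = np.zeros((4, 18), dtype=int)
        X[:, 0] = 1
        ds = make_dataset(X, participant_ids=["a", "b", "a", "b"])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(positive_negative_ratio(ds))


class TestTemporalProfile:
    def test_single_hour_always_present(self, taxonomy):
        X = np.ones((5, 18), dtype=int)
        ts = pd.to_datetime(["2013-03-01 09:15:00"] * 5) + pd.to_timedelta(
            range(5), unit="D"
        )
        ds = make_dataset(X, timestamps=pd.Series(ts))
        prof = temporal_profile(ds, "joy", by="hour", min_reports=1)
        assert prof.values == {9: 1.0}

    def test_night_reports_filtered_by_default_range(self, taxonomy):
        X = np.ones((5, 18), dtype=int)
        ts = pd.to_datetime(["2013-03-01 03:00:00"] * 5)
        ds = make_dataset(X, timestamps=pd.Series(ts))
        with pytest.warns(UserWarning, match="no hour bins"):
            prof = temporal_profile(ds, "joy", by="hour", min_reports=1)
        assert prof.values == {}

    def test_min_reports_floor_excludes_sparse_bins(self, taxonomy):
        X = np.ones((11, 18), dtype=int)
        ts = pd.to_datetime(["2013-03-01 09:00:00"] * 10 + ["2013-03-01 10:00:00"])
        ds = make_dataset(X, timestamps=pd.Series(ts))
        prof = temporal_profile(ds, "joy", by="hour", min_reports=5)
        assert set(prof.bins) == {9}

    def test_weekday_is_iso(self, taxonomy):
        X = np.ones((2, 18), dtype=int)
        # 2013-03-04 is a Monday
        ts = pd.to_datetime(["2013-03-04 09:00:00", "2013-03-10 09:00:00"])
        ds = make_dataset(X, timestamps=pd.Series(ts))
        prof = temporal_profile(ds, "joy", by="weekday", min_reports=1)
        assert set(prof.bins) == {1, 7}

    def test_evening_peaked_emission_maximal_at_peak_bin(self):
        cfg = SyntheticConfig(
            n_participants=6000, prompts_per_participant=10, prompts_dispersion=1e6,
            hour_amplitude={"joy": 0.6}, peak_hour=20, seed=30,
        )
        ds = generate_dataset(cfg)
        prof = temporal_profile(ds, "joy", by="hour", min_reports=200)
        series = prof.as_series()
        # the argmax sits at (or next to) the emission peak, and the peak
        # hour clearly dominates the trough 12 hours away
        assert series.idxmax() in (19, 20, 21)
        assert series[20] > series[8]


class TestFluctuationMagnitude:
    def test_constant_profile_gives_zero(self):
        prof = TemporalProfile("joy", "hour", {6: 0.3, 7: 0.3, 8: 0.3}, {6: 9, 7: 9, 8: 9})
        assert fluctuation_magnitude({"joy": prof}, ["joy"]) == 0.0

    def test_hand_computed_sd(self):
        # values 0.1, 0.2, 0.3: sample SD = 0.1; mean over one emotion = 0.1
        prof = TemporalProfile("joy", "hour", {6: 0.1, 7: 0.2, 8: 0.3}, {6: 9, 7: 9, 8: 9})
        assert fluctuation_magnitude({"joy": prof}, ["joy"]) == pytest.approx(0.1)

    def test_fewer_than_two_bins_fatal(self):
        prof = TemporalProfile("joy", "hour", {9: 1.0}, {9: 5})
        with pytest.raises(ValueError, match="2 bins"):
            fluctuation_magnitude({"joy": prof}, ["joy"])

    def test_sinusoidal_positive_flat_negative_emissions(self):
        # positive emotions modulated by hour, negatives flat: the mean
        # hourly SD must come out larger for the positive set
        tax = SyntheticConfig().taxonomy()
        amp = {e: (0.4 if tax.valence[e] == "positive" else 0.0) for e in tax}
        cfg = SyntheticConfig(
            n_participants=8000, prompts_per_participant=8, prompts_dispersion=1e6,
            hour_amplitude=amp, seed=31,
        )
        ds = generate_dataset(cfg)
        profiles = {
            e: temporal_profile(ds, e, by="hour", min_reports=300) for e in tax
        }
        pos = fluctuation_magnitude(profiles, tax.positive)
        neg = fluctuation_magnitude(profiles, tax.negative)
        assert pos > 2 * neg


class TestCategoryArithmetic:
    def test_pooled_categories_sum_to_100(self, small_dataset):
        table = frequency_table(small_dataset, method="pooled").set_index("target")
        cats = table.loc[["positive_only", "negative_only", "mixed"], "pooled_pct"].sum()
        none_pct = 100.0 - table.loc["any", "pooled_pct"]
        assert cats + none_pct == pytest.approx(100.0, abs=1e-9)

    def test_every_emotion_below_any(self, small_dataset):
        table = frequency_table(small_dataset, method="pooled").set_index("target")
        any_pct = table.loc["any", "pooled_pct"]
        emo = table[table.kind == "emotion"]["pooled_pct"]
        assert (emo <= any_pct + 1e-12).all()
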