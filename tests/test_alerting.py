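"""Surprise-index computation, thresholding, phenotypes and imputation."""

import warnings

import numpy as np
import pandas as pd
import pytest

import rapidindex as rx
from rapidindex.alerting import (
    AlarmEvent,
    PhenotypeModel,
    RapidIndexSeries,
    calibrate_threshold,
    fit_phenotypes,
    generate_alerts,
    impute_missing,
)
from rapidindex.synthetic import DeteriorationSpec, SyntheticScenario, generate_cohort, generate_session

from conftest import CLEAN


def series_from_values(values, start=0, threshold=None):
    frame = pd.DataFrame(
        {"index": values, "flag": "direct"},
        index=pd.Index(range(start, start + len(values)), name="minute"),
    )
    return RapidIndexSeries(session_id="s", frame=frame, threshold=threshold)


class TestCalibrateThreshold:
    def test_nearest_rank_percentile(self):
        assert calibrate_threshold(np.arange(1.0, 101.0), 95) == 95.0

    def test_all_equal(self):
        assert calibrate_threshold(np.full(200, 3.3), 95) == 3.3

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="100"):
            calibrate_threshold(np.arange(50.0), 95)


class TestGenerateAlerts:
    def test_no_crossing_no_events(self):
        assert generate_alerts(series_from_values(np.zeros(30)), 1.0) == []

    def test_single_spike(self):
        v = np.zeros(30)
        v[10] = 5.0
        events = generate_alerts(series_from_values(v), 1.0)
        assert len(events) == 1
        assert (events[0].start_minute, events[0].end_minute) == (10, 10)
        assert events[0].peak_index == 5.0

    def test_square_wave_two_events(self):
        v = np.zeros(40)
        v[5:10] = 2.0
        v[20:30] = 3.0
        events = generate_alerts(series_from_values(v), 1.0)
        assert [(e.start_minute, e.end_minute) for e in events] == [(5, 9), (20, 29)]

    def test_alarm_conservation(self, rng):
        """Total event duration equals the count of super-threshold minutes."""
        v = rng.exponential(1.0, size=500)
        thr = 2.0
        events = generate_alerts(series_from_values(v), thr)
        assert sum(e.duration for e in events) == int((v >= thr).sum())

    def test_nan_breaks_runs(self):
        v = np.array([5.0, np.nan, 5.0])
        events = generate_alerts(series_from_values(v), 1.0)
        assert len(events) == 2

    def test_invalid_event_rejected(self):
        with pytest.raises(ValueError):
            AlarmEvent("s", 10, 5, 1.0)


class TestPhenotypes:
    def test_two_blobs_recovered(self, rng):
        blob_a = rng.normal([0, 0], 0.1, size=(40, 2))
        blob_b = rng.normal([5, 5], 0.1, size=(40, 2))
        P = np.vstack([blob_a, blob_b])
        ph = fit_phenotypes(P, seed=0)
        assert ph.k == 2
        got = np.sort(ph.centroids, axis=0)
        np.testing.assert_allclose(got, [[0, 0], [5, 5]], atol=0.2)

    def test_assignments_stable_under_relabeling(self, rng):
        P = np.vstack(
            [rng.normal([0, 0], 0.1, size=(30, 2)), rng.normal([4, 0], 0.1, size=(30, 2))]
        )
        ph = fit_phenotypes(P, seed=0)
        # same-blob points share a label regardless of which id it is
        assert len(set(ph.assignments[:30])) == 1
        assert len(set(ph.assignments[30:])) == 1
        assert ph.assignments[0] != ph.assignments[-1]

    def test_degenerate_points_single_cluster(self):
        P = np.zeros((20, 2))
        with pytest.warns(UserWarning, match="single phenotype"):
            ph = fit_phenotypes(P, seed=0)
        assert ph.k == 1

    def test_chosen_k_beats_neighbours(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        P = np.vstack([rng.normal(c, 0.3, size=(30, 2)) for c in ([0, 0], [4, 0], [0, 4])])
        ph = fit_phenotypes(P, seed=0)
        score_at = {}
        for k in (ph.k - 1, ph.k, ph.k + 1):
            if k < 2:
                continue
            lab = KMeans(n_clusters=k, random_state=0, n_init=10).fit_predict(P)
            score_at[k] = silhouette_score(P, lab)
        assert score_at[ph.k] == max(score_at.values())


def make_phenotype(mean=100.0, sd=5.0, phi=0.9):
    return PhenotypeModel(
        centroids=np.zeros((1, 2)),
        channels=("hr", "rr", "spo2"),
        means=np.full((1, 3), mean),
        sds=np.full((1, 3), sd),
        phis=np.full((1, 3), phi),
        assignments=np.zeros(1, dtype=int),
        k=1,
    )


class TestImputation:
    def frame_with_gap(self, gap, n=40):
        f = pd.DataFrame(
            {"hr": 100.0, "rr": 100.0, "spo2": 100.0}, index=pd.RangeIndex(n)
        )
        f.iloc[10 : 10 + gap] = np.nan
        return f

    def test_long_gap_refused(self):
        f = self.frame_with_gap(16)
        out, mask = impute_missing(f, make_phenotype(), 0, max_gap=15)
        assert out["hr"].isna().sum() == 16
        assert not mask.any().any()

    def test_short_gap_within_phenotype_spread(self):
        f = self.frame_with_gap(1)
        ph = make_phenotype(mean=95.0, sd=5.0)
        out, mask = impute_missing(f, ph, 0)
        v = out.loc[10, "hr"]
        assert mask.loc[10, "hr"]
        assert abs(v - 95.0) <= 4 * 5.0
        # without noise, the conditional mean pulls from the last observed
        # value toward the phenotype mean
        out2, _ = impute_missing(f, ph, 0, noise=False)
        assert 95.0 <= out2.loc[10, "hr"] <= 100.0

    def test_imputation_deterministic(self):
        f = self.frame_with_gap(5)
        ph = make_phenotype(mean=95.0, sd=5.0)
        a, _ = impute_missing(f, ph, 0)
        b, _ = impute_missing(f, ph, 0)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_phenotype_fills_mean(self):
        f = self.frame_with_gap(3)
        out, _ = impute_missing(f, make_phenotype(mean=97.0, sd=0.0), 0)
        assert (out.loc[10:12, "hr"] == 97.0).all()

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ValueError):
            impute_missing(self.frame_with_gap(1), make_phenotype(), 3)


class TestComputeIndex:
    def test_first_value_at_warmup_minute(self, trained_model, stable_session):
        series = rx.compute_rapid_index(stable_session, trained_model)
        assert series.frame.index[0] == 5
        assert series.frame.index[-1] == stable_session.intended_end - 1
        assert (series.frame["index"].dropna() >= 0).all()

    def test_training_sessions_score_low(self, trained_model):
        """Replaying training data keeps the median index at the training scale."""
        sessions, _ = generate_cohort(2, 0, seed=2, duration_minutes=720)
        med_train = float(np.median(trained_model.training_index_values))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = rx.compute_rapid_index(sessions[0], trained_model)
        assert series.frame["index"].median() <= max(2 * med_train, med_train + 3)

    def test_deterioration_raises_index(self, trained_model):
        det = DeteriorationSpec(onset_minute=200, event_minute=690)
        gen = generate_session(
            SyntheticScenario(duration_minutes=720, deterioration=det, seed=21, **CLEAN),
            "case",
        )
        series = rx.compute_rapid_index(gen.session, trained_model)
        f = series.frame
        assert f.loc[f.index >= 200, "index"].mean() > f.loc[f.index < 200, "index"].mean()

    def test_constant_vitals_near_constant_index(self, trained_model):
        frame = pd.DataFrame(
            {"hr": 120.0, "rr": 30.0, "spo2": 97.0, "pr": 120.0},
            index=pd.RangeIndex(200),
        )
        session = rx.MonitoringSession("const", 24, 0, 200, frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = rx.compute_rapid_index(session, trained_model)
        steady = series.frame.loc[20:, "index"]
        assert steady.std() < 1e-6

    def test_determinism(self, trained_model, stable_session):
        a = rx.compute_rapid_index(stable_session, trained_model)
        b = rx.compute_rapid_index(stable_session, trained_model)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_single_sensor_outage_keeps_index_available(self, trained_model):
        """A <=15-min pulse-ox outage is imputed, not dropped."""
        sessions, _ = generate_cohort(1, 0, seed=31, duration_minutes=300, **CLEAN)
        s = sessions[0]
        s.frame.loc[100:112, ["spo2", "pr"]] = np.nan  # 13-min sensor outage
        series = rx.compute_rapid_index(s, trained_model)
        affected = series.frame.loc[100:112 + 15]
        assert (affected["flag"] != "unavailable").all()
        assert affected["index"].notna().all()
        assert (series.frame.loc[100:112, "flag"] == "imputed").any()


def test_training_is_deterministic():
    sessions, _ = generate_cohort(4, 0, seed=13, duration_minutes=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = rx.train_rapid(sessions, seed=13)
        m2 = rx.train_rapid(sessions, seed=13)
    np.testing.assert_array_equal(m1.nsmap.weights, m2.nsmap.weights)
    assert m1.threshold == m2.threshold
    np.testing.assert_array_equal(m1.training_index_values, m2.training_index_values)
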