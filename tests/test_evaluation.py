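"""Tests for ROC/AUC discrimination, intensity classification and MET association."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import actimetrics as am
from actimetrics.core_metrics import Metric
from actimetrics.evaluation import (
    DEFAULT_ACTIVITY_PAIRS,
    IntensityClass,
    _median_table,
    rocs_to_frame,
)


def brute_force_auc(pos, neg) -> float:
    """Oracle: fraction of (positive, negative) pairs won, ties counting 1/2."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestMetConversion:
    @pytest.mark.parametrize("vo2,met", [(3.5, 1.0), (10.5, 3.0), (0.0, 0.0)])
    def test_vo2_to_met(self, vo2, met):
        assert am.met_from_vo2(vo2) == pytest.approx(met, abs=1e-15)

    def test_negative_vo2_rejected(self):
        with pytest.raises(ValueError):
            am.met_from_vo2(-1.0)

    @pytest.mark.parametrize(
        "met,label",
        [
            (0.0, "sedentary"),
            (1.4, "sedentary"),
            (1.5, "light"),  # left-closed boundary
            (2.9, "light"),
            (3.0, "mvpa"),  # left-closed boundary
            (8.0, "mvpa"),
        ],
    )
    def test_intensity_classification(self, met, label):
        assert am.classify_intensity(met).value == label

    def test_negative_met_rejected(self):
        with pytest.raises(ValueError):
            am.classify_intensity(-0.1)

    def test_intervals_partition_nonnegative_mets(self):
        lo_hi = [c.met_interval for c in IntensityClass]
        assert lo_hi[0][0] == 0.0
        for (_, hi), (lo, _) in zip(lo_hi, lo_hi[1:]):
            assert hi == lo
        assert lo_hi[-1][1] == float("inf")


class TestRocAuc:
    def test_perfect_separation(self):
        assert am.roc_auc([2, 3], [0, 1]).auc == 1.0

    def test_all_ties_give_half(self):
        assert am.roc_auc([1, 1, 1], [1, 1, 1]).auc == 0.5

    def test_mixed_example(self):
        # brute force over the 4 pairs: 3 wins, 0 ties -> 0.75
        assert am.roc_auc([1, 3], [2, 0]).auc == 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            am.roc_auc([], [1.0])

    def test_curve_shape(self):
        r = am.roc_auc([0.2, 0.9, 0.9], [0.1, 0.2])
        assert tuple(r.curve[0]) == (0.0, 0.0)
        assert tuple(r.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)
        assert r.n_pos == 3 and r.n_neg == 2

    @given(
        pos=st.lists(st.integers(0, 6), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 6), min_size=1, max_size=12),
    )
    def test_matches_brute_force_with_ties(self, pos, neg):
        """Midrank AUC equals explicit pairwise win/tie counting."""
        assert am.roc_auc(pos, neg).auc == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @given(
        pos=st.lists(st.floats(-5, 5), min_size=1, max_size=10),
        neg=st.lists(st.floats(-5, 5), min_size=1, max_size=10),
    )
    def test_label_swap_antisymmetry(self, pos, neg):
        assert am.roc_auc(pos, neg).auc == pytest.approx(
            1.0 - am.roc_auc(neg, pos).auc, abs=1e-12
        )

    @given(
        pos=st.lists(st.integers(-300, 300), min_size=1, max_size=10),
        neg=st.lists(st.integers(-300, 300), min_size=1, max_size=10),
    )
    def test_monotone_transform_invariance(self, pos, neg):
        # a 0.01-spaced score grid keeps exp() injective in double precision
        pos, neg = np.asarray(pos) / 100.0, np.asarray(neg) / 100.0
        transformed = am.roc_auc(np.exp(pos), np.exp(neg)).auc
        assert am.roc_auc(pos, neg).auc == pytest.approx(transformed, abs=1e-12)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(20):
            pos = rng.normal(0.5, 1, rng.integers(2, 30))
            neg = rng.normal(0.0, 1, rng.integers(2, 30))
            labels = np.r_[np.ones(pos.size), np.zeros(neg.size)]
            scores = np.r_[pos, neg]
            assert am.roc_auc(pos, neg).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


def two_alias_cohort(amp_a, amp_b, met_a, met_b, n=6, noise=0.01, seed=0):
    """Small cohort with two activities for discrimination tests."""
    bouts = (
        am.ActivityBoutSpec("A", 30.0, amp_a, 1.0, met_mean=met_a, met_sd=0.05),
        am.ActivityBoutSpec("B", 30.0, amp_b, 1.3, met_mean=met_b, met_sd=0.05),
    )
    base = am.SessionSpec(bouts=bouts, noise_sd_per_axis=noise)
    return am.simulate_cohort(n, base, seed=seed)


def metrics_for(sessions, sigma_sq=3e-4):
    noise = am.NoiseProfile((sigma_sq / 3,) * 3)
    return [am.session_metrics(s, noise) for s in sessions]


class TestActivityPairRocs:
    def test_identical_distributions_near_half(self):
        sessions = two_alias_cohort(0.05, 0.05, 2.0, 2.0, n=8, seed=1)
        results = am.activity_pair_rocs(
            sessions, metrics_for(sessions), pairs=[("A", "B")]
        )
        for r in results:
            assert abs(r.auc - 0.5) < 0.1

    def test_separation_limit(self):
        sessions = two_alias_cohort(0.4, 0.005, 3.5, 1.0, n=4, noise=0.0, seed=2)
        results = am.activity_pair_rocs(
            sessions, metrics_for(sessions), pairs=[("B", "A")]
        )
        ai = next(r for r in results if r.label.endswith("AI_REL"))
        assert ai.auc == 1.0

    def test_higher_met_alias_is_positive_regardless_of_pair_order(self):
        sessions = two_alias_cohort(0.3, 0.01, 3.5, 1.0, n=4, noise=0.0, seed=3)
        mm = metrics_for(sessions)
        fwd = am.activity_pair_rocs(sessions, mm, pairs=[("A", "B")])
        rev = am.activity_pair_rocs(sessions, mm, pairs=[("B", "A")])
        assert fwd[0].auc == rev[0].auc >= 0.5

    def test_absent_alias_rejected(self):
        sessions = two_alias_cohort(0.05, 0.05, 2.0, 2.0, n=2, seed=4)
        with pytest.raises(ValueError, match="absent"):
            am.activity_pair_rocs(
                sessions, metrics_for(sessions), pairs=[("A", "MISSING")]
            )

    def test_participant_median_pooling(self):
        sessions = two_alias_cohort(0.15, 0.01, 3.0, 1.0, n=6, seed=5)
        results = am.activity_pair_rocs(
            sessions, metrics_for(sessions), pairs=[("A", "B")],
            pooling="participant_median",
        )
        assert results[0].n_pos == results[0].n_neg == 6

    def test_default_pairs_are_the_four_contrasts(self):
        assert DEFAULT_ACTIVITY_PAIRS == (
            ("DVD", "DISH"), ("DVD", "LAUN"), ("DVD", "PUZZ"), ("WALK", "MOP"),
        )


class TestIntensityRocs:
    def cohort(self, seed=6, n=8):
        sessions = am.simulate_cohort(
            n, am.default_opach_protocol(bout_seconds=20.0), seed=seed
        )
        return sessions, metrics_for(sessions)

    def test_monotone_metric_gives_perfect_auc(self):
        """If per-activity metric medians increase strictly with MET class,
        every intensity task reaches AUC 1."""
        sessions, mm = self.cohort()
        table = _median_table(sessions, mm)
        # use the MET itself as a strictly monotone score
        mets = table["met"].to_numpy()
        classes = table["met"].map(lambda x: am.classify_intensity(x).value)
        pos = mets[classes == "mvpa"]
        neg = mets[classes != "mvpa"]
        assert am.roc_auc(pos, neg).auc == 1.0

    def test_three_tasks_per_metric(self):
        sessions, mm = self.cohort()
        frame = rocs_to_frame(am.intensity_rocs(sessions, mm))
        assert set(frame["task"]) == {
            "sedentary_vs_light", "light_vs_mvpa", "mvpa_vs_rest",
        }
        assert set(frame["metric"]) == {"AI_REL", "ENMO"}

    def test_shuffled_labels_near_half(self):
        """Permuting MET values across (participant, activity) destroys the
        association, driving every AUC into the null band around 0.5."""
        sessions, mm = self.cohort(seed=7, n=10)
        rng = np.random.default_rng(23)
        shuffled = []
        all_mets = [m for s in sessions for m in s.met_values.values()]
        perm = rng.permutation(all_mets)
        k = 0
        for s in sessions:
            new_mets = {}
            for alias in s.aliases:
                new_mets[alias] = float(perm[k])
                k += 1
            shuffled.append(dataclasses.replace(s, met_values=new_mets))
        for r in am.intensity_rocs(shuffled, mm):
            assert abs(r.auc - 0.5) < 0.2

    def test_empty_class_names_the_class(self):
        # sedentary and light activities only: the light-vs-mvpa task has an
        # empty positive class and the error must say which one
        sessions = two_alias_cohort(0.05, 0.1, 1.0, 2.0, n=3, seed=8)
        with pytest.raises(ValueError, match="mvpa"):
            am.intensity_rocs(sessions, metrics_for(sessions))


class TestMetAssociation:
    def test_collinear_points_give_r_one(self):
        """Three hand-computed collinear points: r = 1 exactly."""
        from scipy import stats

        r = stats.pearsonr([1, 2, 3], [1, 3, 5]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_linear_metric_gives_r2_one(self):
        sessions, mm = TestIntensityRocs().cohort(seed=9, n=4)
        # overwrite metric values so the median equals the MET exactly
        fake = []
        for s in sessions:
            vals = {}
            n_sec = int(s.recording.duration_seconds)
            for name in (Metric.AI_REL, Metric.ENMO):
                arr = np.zeros(n_sec)
                for alias, start, end in s.bout_intervals:
                    sr = s.recording.sample_rate
                    arr[start // sr : end // sr] = s.met_values[alias]
                vals[name] = am.MetricSeries(name, 1, arr)
            fake.append(vals)
        table = am.met_association(sessions, fake)
        assert table["r_squared"].to_numpy() == pytest.approx(1.0, abs=1e-12)

    def test_independent_metric_near_zero(self):
        sessions, mm = TestIntensityRocs().cohort(seed=10, n=10)
        rng = np.random.default_rng(31)
        fake = []
        for s in sessions:
            n_sec = int(s.recording.duration_seconds)
            fake.append(
                {
                    Metric.AI_REL: am.MetricSeries(
                        Metric.AI_REL, 1, rng.uniform(0, 1, n_sec)
                    )
                }
            )
        table = am.met_association(sessions, fake)
        assert table["r_squared"].iloc[0] < 0.08

    def test_too_few_points_rejected(self):
        sessions = two_alias_cohort(0.05, 0.1, 2.0, 2.5, n=1, seed=11)
        with pytest.raises(ValueError, match="at least 3"):
            am.met_association(sessions[:1], metrics_for(sessions[:1]))

    def test_zero_variance_rejected(self):
        sessions, _ = TestIntensityRocs().cohort(seed=12, n=2)
        const = [
            {
                Metric.AI_REL: am.MetricSeries(
                    Metric.AI_REL, 1, np.ones(int(s.recording.duration_seconds))
                )
            }
            for s in sessions
        ]
        with pytest.raises(ValueError, match="zero variance"):
            am.met_association(sessions, const)
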