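"""Cross-validation structure, ablation, majority voting, grouping rules and
correlation statistics."""

import itertools
import math

import numpy as np
import pytest

from mmgesture.core import MOVEMENT_LABELS, ValidationError
from mmgesture.evaluate import (
    CONFUSABLE_PAIRS,
    DEFAULT_GROUPS,
    ConfusionMatrix,
    GroupingScheme,
    RealtimeProtocol,
    ablate_sensors,
    featurize_trials,
    loto_cv,
    majority_vote,
    pearson_corr,
    score_grouping,
    simulate_realtime,
    validate_grouping,
)
from mmgesture.pipeline import FeatureMatrix
from mmgesture.synth import ImpairmentProfile, SynthConfig, generate_trial


def _noise_fm(rng, n_trials=3, n_per_trial=40, p=68):
    """Label-free noise features: chance-level classification material."""
    n = n_trials * n_per_trial
    labels = rng.choice(["MF", "ME", "HG"], size=n)
    return FeatureMatrix(
        X=rng.standard_normal((n, p)),
        t=np.arange(n, dtype=float),
        labels=labels.astype(object),
        valid=np.ones(n, dtype=bool),
        degenerate=np.zeros(n, dtype=bool),
        trial_ids=np.repeat(np.arange(n_trials), n_per_trial),
    )


@pytest.fixture(scope="module")
def subject_fm(five_trials):
    return featurize_trials(five_trials)


class TestLotoCV:
    def test_five_trials_five_folds(self, subject_fm):
        cm, folds = loto_cv(subject_fm, model="LDA")
        assert len(folds) == 5
        assert cm.total == len(subject_fm)

    def test_accuracy_conservation(self, subject_fm):
        # aggregate-matrix accuracy equals the frame-weighted fold mean
        cm, folds = loto_cv(subject_fm, model="LDA")
        weights = [np.sum(subject_fm.trial_ids == t) for t in folds]
        weighted = np.average([folds[t] for t in folds], weights=weights)
        assert math.isclose(cm.accuracy, weighted, rel_tol=1e-12)

    def test_confusion_matrix_invariants(self, subject_fm):
        cm, _ = loto_cv(subject_fm, model="LDA")
        assert np.all(cm.counts >= 0)
        row_sums = cm.counts.sum(axis=1)
        for lab, total in zip(cm.labels, row_sums):
            assert total == np.sum(subject_fm.labels.astype(str) == lab)
        assert math.isclose(cm.accuracy, np.trace(cm.counts) / cm.total)

    def test_no_leakage_vs_deliberate_leak(self, rng):
        """Negative control: on pure-noise features a leaky evaluation
        (train set containing the test points) scores near 100% with 3-NN
        while honest leave-one-trial-out stays near chance."""
        fm = _noise_fm(rng)
        leaky = np.mean(
            __import__("sklearn.neighbors", fromlist=["KNeighborsClassifier"])
            .KNeighborsClassifier(n_neighbors=3)
            .fit(fm.X, fm.labels.astype(str))
            .predict(fm.X) == fm.labels.astype(str)
        )
        cm, _ = loto_cv(fm, model="KNN")
        assert leaky > 0.5          # self-inclusion inflates accuracy
        assert cm.accuracy < 0.45   # honest CV stays near 1/3 chance
        assert leaky > cm.accuracy + 0.1

    def test_missing_label_in_training_fold(self, rng):
        fm = _noise_fm(rng, n_trials=2)
        fm.labels[fm.trial_ids == 0] = "MF"  # trial 1 keeps other labels
        with pytest.raises(ValidationError, match="absent from training"):
            loto_cv(fm, model="LDA")

    def test_invalid_frames_excluded(self, five_trials):
        fm = featurize_trials(five_trials)
        fm.valid[:100] = False
        cm, _ = loto_cv(fm, model="LDA")
        assert cm.total == len(fm) - 100

    def test_deterministic_lda_path(self, subject_fm):
        a, _ = loto_cv(subject_fm, model="LDA")
        b, _ = loto_cv(subject_fm, model="LDA")
        assert np.array_equal(a.counts, b.counts)


class TestAblation:
    def test_seven_rows_and_masks(self, subject_fm):
        table = ablate_sensors(subject_fm, model="LDA")
        assert len(table) == 7
        assert sorted(table["n_features"]) == [8, 12, 20, 48, 56, 60, 68]
        assert set(table["n_sensors"]) == {1, 2, 3}

    def test_fused_at_least_single_modalities(self, subject_fm):
        table = ablate_sensors(subject_fm, model="LDA").set_index("sensors")
        fused = table.loc["EMG+FMG+IMU", "accuracy"]
        for single in ("EMG", "FMG", "IMU"):
            assert fused >= table.loc[single, "accuracy"]

    def test_single_modality_confusions_resolved_by_fusion(self, subject_fm):
        """EMG alone cannot split CG/SG and FMG alone cannot split MF/HG
        (identical signatures in that modality); fusion resolves both."""
        from mmgesture.core import sensor_mask

        labels = None
        confusions = {}
        for modality in ("EMG", "FMG"):
            cm, _ = loto_cv(subject_fm, model="LDA", mask=sensor_mask({modality}))
            labels = cm.labels
            idx = {l: i for i, l in enumerate(labels)}
            confusions[modality] = cm
        cg, sg = idx["CG"], idx["SG"]
        mf, hg = idx["MF"], idx["HG"]
        emg_cm, fmg_cm = confusions["EMG"].counts, confusions["FMG"].counts
        # above chance-adjusted confusion on the designed pairs
        assert emg_cm[cg, sg] + emg_cm[sg, cg] > 0.3 * (emg_cm[cg].sum())
        assert fmg_cm[mf, hg] + fmg_cm[hg, mf] > 0.3 * (fmg_cm[mf].sum())
        fused_cm, _ = loto_cv(subject_fm, model="LDA")
        recall = dict(zip(fused_cm.labels, fused_cm.per_class_recall))
        assert min(recall["CG"], recall["SG"], recall["MF"], recall["HG"]) > 0.9


class TestMajorityVote:
    def test_plain_majority(self):
        assert majority_vote(["A"] * 7 + ["B"] * 3) == "A"

    def test_tie_broken_by_summed_score(self):
        preds = ["A"] * 5 + ["B"] * 5
        scores = np.zeros((10, 2))
        scores[:, 0] = 1.0  # sum delta_A > sum delta_B
        assert majority_vote(preds, scores, classes=["A", "B"]) == "A"
        scores[:, 1] = 2.0
        assert majority_vote(preds, scores, classes=["A", "B"]) == "B"

    def test_tie_without_scores_uses_class_order(self):
        assert majority_vote(["SG", "CG"], classes=["CG", "SG"]) == "CG"

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            majority_vote([])


class TestGrouping:
    def test_default_grouping_satisfies_constraints(self):
        report = validate_grouping(GroupingScheme())
        assert report.ok
        assert report.violations == ()

    def test_confusable_pair_flagged(self):
        bad = (("CG", "SG", "MF"), ("ME", "O", "FP"), ("HG", "TA", "WF"),
               ("WE", "FS", "NM"))
        report = validate_grouping(bad)
        assert not report.ok
        assert ("CG", "SG") in report.violations

    def test_overlap_and_missing_raise(self):
        with pytest.raises(ValidationError, match="more than one group"):
            validate_grouping((("MF", "MF", "ME"),) + DEFAULT_GROUPS[1:])
        with pytest.raises(ValidationError, match="partition"):
            validate_grouping((("MF", "ME"),), labels=("MF", "ME", "HG"))

    def test_regrouping_reduces_within_group_confusion(self):
        """Brute force over all partitions of 6 labels into two triples: the
        best grouping by confusion mass must beat one that pairs CG with SG
        and ME with HG."""
        labels = ("MF", "ME", "CG", "SG", "WF", "NM")
        counts = np.full((6, 6), 1.0)
        np.fill_diagonal(counts, 50.0)
        idx = {l: i for i, l in enumerate(labels)}
        for a, b in (("CG", "SG"), ("MF", "ME")):
            counts[idx[a], idx[b]] = counts[idx[b], idx[a]] = 20.0
        cm = ConfusionMatrix(labels, counts)

        def partitions():
            rest = labels[1:]
            for pair in itertools.combinations(rest, 2):
                g1 = (labels[0],) + pair
                g2 = tuple(l for l in labels if l not in g1)
                yield (g1, g2)

        valid = {p: score_grouping(p, cm) for p in partitions()
                 if validate_grouping(p, labels=labels).ok}
        assert valid  # constraint-satisfying partitions exist
        best_p = min(valid, key=valid.get)
        bad = score_grouping((("MF", "ME", "NM"), ("CG", "SG", "WF")), cm)
        assert valid[best_p] < bad
        # the optimum keeps both heavy pairs apart
        for a, b in (("CG", "SG"), ("MF", "ME")):
            assert not any(a in g and b in g for g in best_p)


class TestRealtimeSimulation:
    def test_one_vote_per_movement_per_fold(self, five_trials):
        result = simulate_realtime(five_trials)
        assert result["n_votes"] == 12 * 5  # 12 movements x 5 leave-outs
        assert all(v["n_frames"] == 10 for v in result["votes"])
        per_movement = {}
        for v in result["votes"]:
            per_movement.setdefault((v["fold"], v["movement"]), 0)
            per_movement[(v["fold"], v["movement"])] += 1
        assert set(per_movement.values()) == {1}

    def test_heavy_impairment_stays_above_group_chance(self):
        cfg = SynthConfig(seed=77)
        prof = ImpairmentProfile(gamma=0.2)
        recs = [generate_trial(cfg, prof, trial_id=t) for t in range(5)]
        result = simulate_realtime(recs)
        assert result["overall"] > 1.0 / 3.0  # 3-label groups

    def test_small_group_rejected(self, five_trials):
        with pytest.raises(ValidationError, match="fewer than 2"):
            simulate_realtime(five_trials,
                              GroupingScheme(groups=(("MF",),) + DEFAULT_GROUPS[1:]))

    def test_protocol_validation(self):
        with pytest.raises(ValidationError):
            RealtimeProtocol(n_test_frames=0)
        with pytest.raises(ValidationError):
            RealtimeProtocol(train_start_s=5.5, train_end_s=2.0)


class TestPearson:
    def test_perfect_linear(self):
        a = np.arange(10.0)
        r, p = pearson_corr(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson_corr(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        b = np.array([2.0, 3.0, 3.0, 6.0, 8.0])
        # direct formula computed independently
        am, bm = a - a.mean(), b - b.mean()
        r_hand = float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))
        r, p = pearson_corr(a, b)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert 0 < p < 1

    def test_constant_vector_errors(self):
        with pytest.raises(ValidationError, match="non-constant"):
            pearson_corr(np.ones(5), np.arange(5.0))
        with pytest.raises(ValidationError, match="3 observations"):
            pearson_corr(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
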