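"""Evaluation protocols: leave-one-trial-out CV, sensor ablation, grouped
simulated real-time classification with majority voting, and correlations.

Cross-validation is always at the *trial* level: overlapping windows within
a trial are heavily correlated, so frames are never the CV unit and no test
frame's trial ever contributes to its fold's training set (asserted
structurally on every run).

The simulated real-time protocol mirrors live use: models are trained on
the [2 s, 5.5 s] cutout of each movement in four trials, then for each
movement of the held-out trial the first 10 frames starting 1 s after onset
are classified and fused into a single majority-vote decision. Movements
are partitioned into small groups so that gestures known to be mutually
confusable never compete within one decision round.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .core import (
    EMG_RATE,
    MOVEMENT_LABELS,
    MultimodalRecording,
    ValidationError,
    sensor_mask,
    ALL_SENSOR_SUBSETS,
)
from .models import ShrinkageLDA, make_comparator
from .pipeline import (
    FeatureConfig,
    FeatureMatrix,
    TrimRule,
    WindowingConfig,
    extract_features,
    featurize_recording,
    segment_by_triggers,
    zscore_by_trial,
)

__all__ = [
    "ConfusionMatrix",
    "GroupingScheme",
    "DEFAULT_GROUPS",
    "CONFUSABLE_PAIRS",
    "RealtimeProtocol",
    "featurize_trials",
    "loto_cv",
    "ablate_sensors",
    "majority_vote",
    "simulate_realtime",
    "pearson_corr",
    "validate_grouping",
    "score_grouping",
]

logger = logging.getLogger(__name__)

#: Gesture pairs that must not share a decision group (mutually confusable).
CONFUSABLE_PAIRS: frozenset = frozenset({
    frozenset({"CG", "SG"}),
    frozenset({"TA", "O"}),
    frozenset({"ME", "HG"}),
    frozenset({"HG", "MF"}),
    frozenset({"HG", "NM"}),
    frozenset({"TA", "NM"}),
    frozenset({"WE", "FP"}),
})

#: Default four-groups-of-three partition satisfying every confusable-pair
#: constraint (the exact groups are a protocol configuration, not a given).
DEFAULT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("MF", "TA", "WE"),
    ("ME", "O", "FP"),
    ("HG", "CG", "WF"),
    ("SG", "FS", "NM"),
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row = true label, column = predicted label."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels: Sequence[str]) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=list(labels))
        return cls(labels=tuple(labels), counts=counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValidationError("cannot add confusion matrices over different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")

    @property
    def per_class_recall(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, np.diag(self.counts) / np.maximum(row, 1), np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of the movement labels into decision groups."""

    groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS
    labels: tuple[str, ...] = MOVEMENT_LABELS

    def __iter__(self):
        return iter(self.groups)


@dataclass(frozen=True)
class GroupingReport:
    ok: bool
    violations: tuple[tuple[str, str], ...]
    within_group_confusion: float | None = None


def validate_grouping(
    grouping: GroupingScheme | Sequence[Sequence[str]],
    labels: Sequence[str] = MOVEMENT_LABELS,
    confusion: "ConfusionMatrix | None" = None,
) -> GroupingReport:
    """Check a grouping is a partition of ``labels`` with no confusable pair
    inside one group; optionally score it against a confusion matrix.

    Overlapping or missing labels raise; constraint violations are reported.
    """
    groups = grouping.groups if isinstance(grouping, GroupingScheme) else tuple(
        tuple(g) for g in grouping
    )
    flat = [lab for g in groups for lab in g]
    dupes = [lab for lab, c in Counter(flat).items() if c > 1]
    if dupes:
        raise ValidationError(f"labels appear in more than one group: {sorted(dupes)}")
    missing = set(labels) - set(flat)
    extra = set(flat) - set(labels)
    if missing or extra:
        raise ValidationError(
            f"grouping is not a partition: missing {sorted(missing)}, unknown {sorted(extra)}"
        )
    violations = []
    for g in groups:
        for i, a in enumerate(g):
            for b in g[i + 1:]:
                if frozenset({a, b}) in CONFUSABLE_PAIRS:
                    violations.append((a, b))
    score = score_grouping(groups, confusion) if confusion is not None else None
    return GroupingReport(ok=not violations, violations=tuple(violations),
                          within_group_confusion=score)


def score_grouping(
    grouping: GroupingScheme | Sequence[Sequence[str]],
    confusion: ConfusionMatrix,
) -> float:
    """Within-group off-diagonal confusion mass (lower is a better grouping)."""
    groups = grouping.groups if isinstance(grouping, GroupingScheme) else grouping
    idx = {lab: i for i, lab in enumerate(confusion.labels)}
    mass = 0.0
    for g in groups:
        for a in g:
            for b in g:
                if a != b and a in idx and b in idx:
                    mass += float(confusion.counts[idx[a], idx[b]])
    return mass


@dataclass(frozen=True)
class RealtimeProtocol:
    """Timing of the simulated real-time test.

    Training frames come from ``[train_start_s, train_end_s]`` of each
    movement in the training trials; the test consumes the first
    ``n_test_frames`` frames starting ``test_start_s`` into each held-out
    movement, fused by one majority vote.
    """

    train_start_s: float = 2.0
    train_end_s: float = 5.5
    test_start_s: float = 1.0
    n_test_frames: int = 10

    def __post_init__(self) -> None:
        if self.n_test_frames < 1:
            raise ValidationError("vote window must contain at least one frame")
        if not self.train_start_s < self.train_end_s:
            raise ValidationError("train interval is empty")


# ---------------------------------------------------------------------------
# Feature assembly and cross-validation
# ---------------------------------------------------------------------------

def featurize_trials(
    recordings: Sequence[MultimodalRecording],
    movement_duration_s: float = 6.0,
    trim: TrimRule | None = TrimRule(),
    wcfg: WindowingConfig = WindowingConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
    normalize: bool = True,
) -> FeatureMatrix:
    """Featurize each trial independently and stack them."""
    trial_ids = [r.trial_id for r in recordings]
    if len(set(trial_ids)) != len(trial_ids):
        raise ValidationError("recordings must carry distinct trial ids")
    parts = [
        featurize_recording(r, movement_duration_s, trim, wcfg, fcfg, normalize)
        for r in recordings
    ]
    return FeatureMatrix.concatenate(parts)


def _new_model(model: str, random_state: int | None):
    return make_comparator(model, random_state)


def loto_cv(
    fm: FeatureMatrix,
    model: str = "LDA",
    mask: np.ndarray | None = None,
    random_state: int | None = 0,
) -> tuple[ConfusionMatrix, dict[int, float]]:
    """Leave-one-trial-out cross-validation over the trials in ``fm``.

    Only ``valid`` frames participate. Returns the confusion matrix
    aggregated over folds and the per-fold (per-trial) accuracies.
    """
    keep = fm.valid
    X = fm.X[keep]
    y = fm.labels[keep].astype(str)
    trials = fm.trial_ids[keep]
    if mask is not None:
        X = X[:, mask]

    unique_trials = np.unique(trials)
    if unique_trials.shape[0] < 2:
        raise ValidationError("leave-one-trial-out needs at least 2 trials")
    label_set = tuple(sorted(set(y), key=MOVEMENT_LABELS.index))

    agg = ConfusionMatrix(label_set, np.zeros((len(label_set), len(label_set)), dtype=int))
    fold_acc: dict[int, float] = {}
    for held in unique_trials:
        test = trials == held
        train = ~test
        assert not np.any(test & train)  # structural leakage guard
        missing = set(y[test]) - set(y[train])
        if missing:
            raise ValidationError(
                f"labels {sorted(missing)} absent from training folds for trial {held}"
            )
        clf = _new_model(model, random_state).fit(X[train], y[train])
        pred = clf.predict(X[test])
        cm = ConfusionMatrix.from_predictions(y[test], pred, label_set)
        agg = agg + cm
        fold_acc[int(held)] = cm.accuracy
    return agg, fold_acc


def ablate_sensors(
    fm: FeatureMatrix,
    model: str = "LDA",
    random_state: int | None = 0,
) -> pd.DataFrame:
    """LOTO accuracy for each of the 7 non-empty sensor subsets.

    Subsets are evaluated by masking columns of the already-extracted
    68-dim features; nothing is re-extracted.
    """
    rows = []
    for subset in ALL_SENSOR_SUBSETS:
        cols = sensor_mask(subset)
        cm, folds = loto_cv(fm, model=model, mask=cols, random_state=random_state)
        name = "+".join(s for s in ("EMG", "FMG", "IMU") if s in subset)
        rows.append({
            "sensors": name,
            "n_sensors": len(subset),
            "n_features": len(cols),
            "accuracy": cm.accuracy,
            "fold_accuracies": tuple(folds.values()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Majority voting and the simulated real-time protocol
# ---------------------------------------------------------------------------

def majority_vote(
    predictions: Sequence[str],
    scores: np.ndarray | None = None,
    classes: Sequence[str] | None = None,
) -> str:
    """Most frequent label; ties broken by the highest summed discriminant
    score over the tied labels (or by class order when no scores given)."""
    predictions = list(predictions)
    if not predictions:
        raise ValidationError("majority_vote needs at least one prediction")
    counts = Counter(predictions)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    if scores is not None and classes is not None:
        classes = list(classes)
        sums = {lab: float(np.sum(scores[:, classes.index(lab)])) for lab in tied}
        winner = max(sums, key=lambda lab: sums[lab])
        logger.info("vote tie among %s resolved by score to %s", tied, winner)
        return winner
    order = classes if classes is not None else MOVEMENT_LABELS
    winner = min(tied, key=lambda lab: order.index(lab) if lab in order else len(order))
    logger.info("vote tie among %s resolved by class order to %s", tied, winner)
    return winner


def _frozen_stats(norm_stats: dict[int, tuple[np.ndarray, np.ndarray]]
                  ) -> tuple[np.ndarray, np.ndarray]:
    means = np.stack([m for m, _ in norm_stats.values()])
    sds = np.stack([s for _, s in norm_stats.values()])
    return means.mean(axis=0), sds.mean(axis=0)


def simulate_realtime(
    recordings: Sequence[MultimodalRecording],
    grouping: GroupingScheme | None = None,
    protocol: RealtimeProtocol = RealtimeProtocol(),
    model: str = "LDA",
    movement_duration_s: float = 6.0,
    wcfg: WindowingConfig = WindowingConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
    random_state: int | None = 0,
) -> dict:
    """Cross-validated simulated real-time classification after grouping.

    For every leave-one-trial-out fold and every group: a group-restricted
    model is trained on the training trials' [train_start, train_end]
    frames; each of the held-out trial's movements in the group contributes
    exactly one majority-vote decision over its first ``n_test_frames``
    frames from ``test_start_s`` after onset. Test frames are normalized
    with statistics frozen from the training trials (per-trial stats are
    unavailable mid-stream).
    """
    if grouping is None:
        grouping = GroupingScheme()
    flat = tuple(lab for g in grouping for lab in g)
    validate_grouping(grouping, labels=flat)  # partition checks; violations allowed here
    for g in grouping:
        if len(g) < 2:
            raise ValidationError(f"group {g} has fewer than 2 labels")
    if len(recordings) < 2:
        raise ValidationError("need at least 2 trials")
    if len({r.trial_id for r in recordings}) != len(recordings):
        raise ValidationError("recordings must carry distinct trial ids")

    trim = TrimRule(head_s=protocol.train_start_s,
                    tail_s=movement_duration_s - protocol.train_end_s)

    # Per-trial normalization is trial-local, so each trial's trimmed
    # (training) and untrimmed (test) features can be computed once and
    # reused across folds.
    trimmed = [
        featurize_recording(r, movement_duration_s, trim, wcfg, fcfg, normalize=True)
        for r in recordings
    ]
    untrimmed = [
        extract_features(r, segment_by_triggers(r, movement_duration_s), wcfg, fcfg)
        for r in recordings
    ]

    per_group_hits: dict[tuple[str, ...], list[int]] = {tuple(g): [] for g in grouping}
    votes = []
    for fold_idx, held_rec in enumerate(recordings):
        train_fm = FeatureMatrix.concatenate(
            [trimmed[i] for i in range(len(recordings)) if i != fold_idx])
        mu, sd = _frozen_stats(train_fm.norm_stats)
        constant = sd < 1e-12

        test_fm = untrimmed[fold_idx]
        safe_sd = np.where(constant, 1.0, sd)
        Xt = (test_fm.X - mu) / safe_sd
        Xt[:, constant] = 0.0
        start_t = test_fm.t - wcfg.emg_win / EMG_RATE
        onsets = dict((lab, onset) for lab, onset in held_rec.triggers)

        for g in grouping:
            g = tuple(g)
            rows = train_fm.valid & np.isin(train_fm.labels.astype(str), g)
            y_train = train_fm.labels[rows].astype(str)
            if set(g) - set(y_train):
                raise ValidationError(f"group labels {set(g) - set(y_train)} missing from training")
            clf = _new_model(model, random_state).fit(train_fm.X[rows], y_train)
            classes = list(clf.classes_)
            for lab in g:
                if lab not in onsets:
                    continue
                onset = onsets[lab]
                sel = (
                    (test_fm.labels.astype(str) == lab)
                    & (start_t >= onset + protocol.test_start_s - 1e-9)
                )
                idx = np.flatnonzero(sel)[: protocol.n_test_frames]
                idx = idx[test_fm.valid[idx]]
                if idx.size == 0:
                    raise ValidationError("no valid frames for vote")
                preds = clf.predict(Xt[idx])
                scores = (clf.decision_function(Xt[idx])
                          if hasattr(clf, "decision_function") else None)
                decision = majority_vote(list(preds), scores, classes)
                hit = int(decision == lab)
                per_group_hits[g].append(hit)
                votes.append({"fold": fold_idx, "group": "+".join(g), "movement": lab,
                              "decision": decision, "correct": bool(hit),
                              "n_frames": int(idx.size)})

    per_group = {"+".join(g): float(np.mean(h)) for g, h in per_group_hits.items()}
    return {
        "per_group": per_group,
        "overall": float(np.mean([v for h in per_group_hits.values() for v in h])),
        "mean_of_groups": float(np.mean(list(per_group.values()))),
        "n_votes": len(votes),
        "votes": votes,
        "grouping": [list(g) for g in grouping],
    }


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_corr(a, b) -> tuple[float, float]:
    """Pearson r with its two-sided p-value (t-transform)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("inputs must be non-constant")
    res = sstats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
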