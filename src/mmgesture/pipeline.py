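"""Raw recording → feature matrix.

Stages, in order:

1. ``segment_by_triggers`` — cut each movement out of the trial using the
   trigger track, at both sampling rates.
2. ``trim_segment`` — drop the first 2 s and last 0.5 s of every movement
   (transition bursts and slow reactions).
3. ``drop_invalid_fmg`` — mark low-rate samples where any FMG channel left
   its valid measuring range; frames touching them are flagged invalid.
4. ``make_frames`` — overlapped 222 ms / 55.6 ms EMG windows paired with the
   latest disjoint 2-sample (55.6 ms) FMG/IMU window ending by the EMG
   window's end. At 1926 Hz / 36 Hz the frozen counts are 428 / 107 / 2
   samples (round-half-up).
5. ``extract_features`` — per EMG channel and window the 8-tuple
   [MAV, WL, ZC, SSC, AR1..AR4]; per FMG and IMU channel the MAV; 68
   features per frame in a frozen column order.
6. ``zscore_by_trial`` — zero-mean/unit-variance scaling per feature column
   within each trial (the offline rule; streaming uses frozen stats).

MAV is (1/N)Σ|xᵢ|; WL is Σ|x_{i+1}−xᵢ|; ZC counts sign changes whose step
clears an amplitude threshold ε; SSC counts local extrema whose larger
adjacent step clears ε; AR1..AR4 are Burg-estimated coefficients of
x_t = Σₚ aₚ x_{t−p} + e_t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core import (
    EMG_RATE,
    FEATURE_NAMES,
    LOW_RATE,
    N_EMG,
    N_FEATURES,
    N_FMG,
    N_IMU,
    MultimodalRecording,
    Segment,
    ValidationError,
)

__all__ = [
    "WindowingConfig",
    "FeatureConfig",
    "TrimRule",
    "FeatureFrame",
    "FeatureMatrix",
    "segment_by_triggers",
    "trim_segment",
    "drop_invalid_fmg",
    "make_frames",
    "frame_count",
    "mav",
    "wl",
    "zc",
    "ssc",
    "burg_ar",
    "ar_coeffs",
    "extract_features",
    "zscore_by_trial",
    "featurize_recording",
]

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowingConfig:
    """Window/step durations and their frozen integer sample counts."""

    emg_window_s: float = 0.222
    emg_step_s: float = 0.0556
    low_window_s: float = 0.0556

    @property
    def emg_win(self) -> int:
        return _round_half_up(self.emg_window_s * EMG_RATE)  # 428

    @property
    def emg_step(self) -> int:
        return _round_half_up(self.emg_step_s * EMG_RATE)  # 107

    @property
    def low_win(self) -> int:
        return _round_half_up(self.low_window_s * LOW_RATE)  # 2

    def __post_init__(self) -> None:
        if self.emg_step > self.emg_win:
            raise ValidationError("emg step must not exceed emg window")
        if self.low_win < 1:
            raise ValidationError("low-rate window must span at least one sample")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters (threshold in the EMG stream's units)."""

    zc_ssc_threshold: float = 4e-6
    ar_order: int = 4

    def __post_init__(self) -> None:
        if self.zc_ssc_threshold < 0:
            raise ValidationError("threshold must be >= 0")
        if self.ar_order < 1:
            raise ValidationError("ar_order must be >= 1")


@dataclass(frozen=True)
class TrimRule:
    """Seconds removed from each movement's head and tail."""

    head_s: float = 2.0
    tail_s: float = 0.5

    def __post_init__(self) -> None:
        if self.head_s < 0 or self.tail_s < 0:
            raise ValidationError("trim durations must be >= 0")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_by_triggers(rec: MultimodalRecording, movement_duration_s: float) -> list[Segment]:
    """One segment per trigger, truncated at the recording end.

    Triggers at or beyond the recording end are dropped with a warning.
    """
    if movement_duration_s <= 0:
        raise ValidationError("movement_duration_s must be > 0")
    segments = []
    for label, onset in rec.triggers:
        e0 = _round_half_up(onset * EMG_RATE)
        e1 = min(_round_half_up((onset + movement_duration_s) * EMG_RATE), rec.n_emg)
        l0 = _round_half_up(onset * LOW_RATE)
        l1 = min(_round_half_up((onset + movement_duration_s) * LOW_RATE), rec.n_low)
        if e0 >= e1 or l0 >= l1:
            logger.warning("dropping trigger (%s, %.3fs) beyond recording end", label, onset)
            continue
        segments.append(Segment(label=label, emg_range=(e0, e1), low_range=(l0, l1),
                                trial_id=rec.trial_id))
    return segments


def trim_segment(seg: Segment, rule: TrimRule) -> Segment:
    """Shift the segment in by ``head_s`` and ``tail_s``, per stream."""
    e0 = seg.emg_range[0] + _round_half_up(rule.head_s * EMG_RATE)
    e1 = seg.emg_range[1] - _round_half_up(rule.tail_s * EMG_RATE)
    l0 = seg.low_range[0] + _round_half_up(rule.head_s * LOW_RATE)
    l1 = seg.low_range[1] - _round_half_up(rule.tail_s * LOW_RATE)
    if e0 >= e1 or l0 >= l1:
        raise ValidationError(
            f"segment of {seg.emg_len / EMG_RATE:.2f}s too short for trim "
            f"({rule.head_s}+{rule.tail_s}s)"
        )
    return Segment(label=seg.label, emg_range=(e0, e1), low_range=(l0, l1),
                   trial_id=seg.trial_id)


def drop_invalid_fmg(rec: MultimodalRecording) -> np.ndarray:
    """Low-rate sample indices where any FMG channel is out of range.

    The samples are not removed from the stream; frames whose low-rate
    window intersects one are flagged ``valid=False`` downstream, which is
    how the deletion rule propagates through the multirate pipeline.
    """
    lo, hi = rec.fmg_valid_range
    bad = np.any((rec.fmg < lo) | (rec.fmg > hi), axis=1)
    return np.flatnonzero(bad)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def frame_count(n_samples: int, win: int, step: int) -> int:
    """Number of overlapped windows: floor((L − win)/step) + 1, 0 if L < win."""
    if n_samples < win:
        return 0
    return (n_samples - win) // step + 1


def make_frames(seg: Segment, wcfg: WindowingConfig = WindowingConfig()
                ) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Absolute (emg_interval, low_interval) index pairs for each frame.

    Frame *i* spans EMG samples ``[s + i·step, s + i·step + win)``. Its
    low-rate partner is the latest disjoint ``low_win``-sample window (laid
    out from the segment's low-rate start) ending at or before the EMG
    window's end time. A segment shorter than one EMG window yields no
    frames (logged).
    """
    n = frame_count(seg.emg_len, wcfg.emg_win, wcfg.emg_step)
    if n == 0:
        logger.warning("segment %s shorter than one EMG window; no frames", seg.label)
        return []
    e_start, l_start = seg.emg_range[0], seg.low_range[0]
    n_low_windows = seg.low_len // wcfg.low_win
    frames = []
    for i in range(n):
        e0 = e_start + i * wcfg.emg_step
        e1 = e0 + wcfg.emg_win
        t_end = e1 / EMG_RATE
        # largest j with (l_start + (j+1)*low_win)/LOW_RATE <= t_end
        j = int(np.floor((t_end * LOW_RATE + 1e-9 - l_start) / wcfg.low_win)) - 1
        j = max(0, min(j, n_low_windows - 1))
        l0 = l_start + j * wcfg.low_win
        frames.append(((e0, e1), (l0, l0 + wcfg.low_win)))
    return frames


# ---------------------------------------------------------------------------
# Feature primitives (vectorized along the last axis)
# ---------------------------------------------------------------------------

def mav(w: np.ndarray) -> np.ndarray:
    """Mean absolute value along the last axis."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] < 1:
        raise ValidationError("MAV needs at least one sample")
    return np.mean(np.abs(w), axis=-1)


def wl(w: np.ndarray) -> np.ndarray:
    """Waveform length: cumulative absolute first difference."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] < 2:
        raise ValidationError("WL needs at least two samples")
    return np.sum(np.abs(np.diff(w, axis=-1)), axis=-1)


def zc(w: np.ndarray, threshold: float = 4e-6) -> np.ndarray:
    """Zero crossings: sign changes whose step amplitude clears ``threshold``."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] < 2:
        raise ValidationError("ZC needs at least two samples")
    a, b = w[..., :-1], w[..., 1:]
    return np.sum((a * b < 0) & (np.abs(a - b) >= threshold), axis=-1)


def ssc(w: np.ndarray, threshold: float = 4e-6) -> np.ndarray:
    """Slope-sign changes: local extrema whose larger adjacent step clears ``threshold``."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] < 3:
        raise ValidationError("SSC needs at least three samples")
    prev, cur, nxt = w[..., :-2], w[..., 1:-1], w[..., 2:]
    d1, d2 = cur - prev, cur - nxt
    return np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= threshold), axis=-1)


def burg_ar(w: np.ndarray, order: int = 4, demean: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Burg-recursion AR coefficient estimates, batched over leading axes.

    Returns ``(coeffs, degenerate)`` where ``coeffs[..., p-1]`` is aₚ in the
    convention ``x_t = Σₚ aₚ x_{t−p} + e_t`` and ``degenerate`` flags
    (near-)zero-variance windows, whose coefficients are set to zero.
    """
    x = np.asarray(w, dtype=float)
    n = x.shape[-1]
    if n <= 2 * order:
        raise ValidationError(f"need more than {2 * order} samples for AR({order})")
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)

    degenerate = x.var(axis=-1) < _SD_FLOOR
    batch = x.shape[:-1]
    a = np.zeros(batch + (order,))
    f = x[..., 1:].copy()
    b = x[..., :-1].copy()
    for m in range(order):
        num = -2.0 * np.sum(f * b, axis=-1)
        den = np.sum(f * f, axis=-1) + np.sum(b * b, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        prev = a.copy()
        a[..., m] = k
        if m > 0:
            a[..., :m] = prev[..., :m] + k[..., None] * prev[..., m - 1::-1]
        f, b = f + k[..., None] * b, b + k[..., None] * f
        f = f[..., 1:]
        b = b[..., :-1]
    coeffs = -a  # monic error-filter polynomial → regression convention
    coeffs[degenerate] = 0.0
    return coeffs, degenerate


def ar_coeffs(w: np.ndarray, order: int = 4) -> np.ndarray:
    """AR coefficients only (zero-variance windows yield zeros)."""
    return burg_ar(w, order=order)[0]


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureFrame:
    """One fused 68-dim feature vector with its frame-end time and flags."""

    t: float
    x: np.ndarray
    label: str
    valid: bool = True
    degenerate: bool = False
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.x.shape != (N_FEATURES,):
            raise ValidationError(f"feature vector must have length {N_FEATURES}")


@dataclass
class FeatureMatrix:
    """Stacked feature frames for one or more trials.

    ``X`` is (n_frames, 68) in the frozen column order of
    :data:`mmgesture.core.FEATURE_NAMES`; ``valid`` is False for frames whose
    low-rate window touched an out-of-range FMG sample; ``degenerate`` marks
    frames where a zero-variance EMG channel forced zero AR coefficients.
    ``norm_stats`` records the per-trial (mean, sd) actually applied, or is
    empty when the matrix is unnormalized.
    """

    X: np.ndarray
    t: np.ndarray
    labels: np.ndarray
    valid: np.ndarray
    degenerate: np.ndarray
    trial_ids: np.ndarray
    norm_stats: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValidationError(f"X must be (n, {N_FEATURES})")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def frames(self) -> Iterator[FeatureFrame]:
        for i in range(len(self)):
            yield FeatureFrame(
                t=float(self.t[i]), x=self.X[i], label=str(self.labels[i]),
                valid=bool(self.valid[i]), degenerate=bool(self.degenerate[i]),
                trial_id=int(self.trial_ids[i]),
            )

    @staticmethod
    def concatenate(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        stats: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for p in parts:
            stats.update(p.norm_stats)
        return FeatureMatrix(
            X=np.concatenate([p.X for p in parts]),
            t=np.concatenate([p.t for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            valid=np.concatenate([p.valid for p in parts]),
            degenerate=np.concatenate([p.degenerate for p in parts]),
            trial_ids=np.concatenate([p.trial_ids for p in parts]),
            norm_stats=stats,
        )


def extract_features(
    rec: MultimodalRecording,
    segments: Sequence[Segment],
    wcfg: WindowingConfig = WindowingConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
    dropped_low: np.ndarray | None = None,
) -> FeatureMatrix:
    """Extract the fused 68-dim feature vector for every frame of ``segments``.

    Column layout per frame: for each EMG channel the 8-tuple
    [MAV, WL, ZC, SSC, AR1..AR4] (48 columns), then FMG MAV per channel (8),
    then IMU MAV per channel (12). Frames whose low-rate window intersects
    ``dropped_low`` carry ``valid=False``.
    """
    if dropped_low is None:
        dropped_low = drop_invalid_fmg(rec)
    dropped = set(int(i) for i in dropped_low)

    xs, ts, labels, valids, degs = [], [], [], [], []
    for seg in segments:
        pairs = make_frames(seg, wcfg)
        if not pairs:
            continue
        n = len(pairs)
        e_starts = np.array([p[0][0] for p in pairs])
        l_starts = np.array([p[1][0] for p in pairs])

        idx = e_starts[:, None] + np.arange(wcfg.emg_win)[None, :]
        # (n, 6, win): every EMG window of every channel, batched
        win = rec.emg[idx].transpose(0, 2, 1)

        emg_feats = np.empty((n, N_EMG, 8))
        emg_feats[..., 0] = mav(win)
        emg_feats[..., 1] = wl(win)
        emg_feats[..., 2] = zc(win, fcfg.zc_ssc_threshold)
        emg_feats[..., 3] = ssc(win, fcfg.zc_ssc_threshold)
        coeffs, degenerate = burg_ar(win, order=fcfg.ar_order)
        emg_feats[..., 4:4 + fcfg.ar_order] = coeffs

        lidx = l_starts[:, None] + np.arange(wcfg.low_win)[None, :]
        fmg_feats = mav(rec.fmg[lidx].transpose(0, 2, 1))  # (n, 8)
        imu_feats = mav(rec.imu[lidx].transpose(0, 2, 1))  # (n, 12)

        xs.append(np.concatenate(
            [emg_feats.reshape(n, N_EMG * 8), fmg_feats, imu_feats], axis=1))
        ts.append((e_starts + wcfg.emg_win) / EMG_RATE)
        labels.append(np.full(n, seg.label, dtype=object))
        valids.append(np.array([
            not dropped.intersection(range(p[1][0], p[1][1])) for p in pairs
        ]))
        degs.append(degenerate.any(axis=1))

    if not xs:
        return FeatureMatrix(
            X=np.empty((0, N_FEATURES)), t=np.empty(0), labels=np.empty(0, dtype=object),
            valid=np.empty(0, dtype=bool), degenerate=np.empty(0, dtype=bool),
            trial_ids=np.empty(0, dtype=int),
        )
    n_total = sum(x.shape[0] for x in xs)
    return FeatureMatrix(
        X=np.concatenate(xs),
        t=np.concatenate(ts),
        labels=np.concatenate(labels),
        valid=np.concatenate(valids),
        degenerate=np.concatenate(degs),
        trial_ids=np.full(n_total, rec.trial_id, dtype=int),
    )


def zscore_by_trial(fm: FeatureMatrix) -> FeatureMatrix:
    """Zero-mean/unit-sd scale each feature column within each trial.

    Columns whose within-trial sd falls below 1e−12 are set to zero (and
    logged) rather than divided by ~0. The applied stats are stored in
    ``norm_stats`` keyed by trial id, so normalization is invertible.
    """
    X = fm.X.copy()
    stats: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for trial in np.unique(fm.trial_ids):
        rows = fm.trial_ids == trial
        if rows.sum() < 2:
            raise ValidationError(f"trial {trial} has fewer than 2 frames; cannot normalize")
        mean = X[rows].mean(axis=0)
        sd = X[rows].std(axis=0, ddof=0)
        constant = sd < _SD_FLOOR
        if constant.any():
            logger.warning("trial %s: %d constant feature column(s) zeroed", trial,
                           int(constant.sum()))
        safe_sd = np.where(constant, 1.0, sd)
        Z = (X[rows] - mean) / safe_sd
        Z[:, constant] = 0.0
        X[rows] = Z
        stats[int(trial)] = (mean, sd)
    return FeatureMatrix(
        X=X, t=fm.t.copy(), labels=fm.labels.copy(), valid=fm.valid.copy(),
        degenerate=fm.degenerate.copy(), trial_ids=fm.trial_ids.copy(), norm_stats=stats,
    )


def featurize_recording(
    rec: MultimodalRecording,
    movement_duration_s: float = 6.0,
    trim: TrimRule | None = TrimRule(),
    wcfg: WindowingConfig = WindowingConfig(),
    fcfg: FeatureConfig = FeatureConfig(),
    normalize: bool = True,
) -> FeatureMatrix:
    """Convenience: segment → (trim) → extract → (per-trial zscore)."""
    segments = segment_by_triggers(rec, movement_duration_s)
    if trim is not None:
        segments = [trim_segment(s, trim) for s in segments]
    fm = extract_features(rec, segments, wcfg, fcfg)
    if normalize and len(fm) > 0:
        fm = zscore_by_trial(fm)
    return fm
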