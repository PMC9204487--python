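"""Synthetic multimodal recording generator.

Emulates the structure of a guided training trial: the 12 movements are
performed in a fixed order, each held for 6 s with a 4 s rest between, and a
trigger marks each onset. Per class the generator applies a fixed *signature*
— an EMG activation level per channel, an FMG pressure offset per channel and
an IMU offset per channel — on top of sensor noise:

* EMG: amplitude-modulated band-limited (20–450 Hz) Gaussian noise, a
  standard surrogate for surface EMG, with a 0.25 s raised-cosine ramp at
  block edges to mimic the transition bursts that head/tail trimming removes.
* FMG: baseline + class offset + slow sinusoidal drift + white noise.
* IMU: class offset + white noise.

The default signature table is built so the modalities complement each other
the way a wrist-worn multimodal device's do: the two grasps CG and SG share
an EMG/IMU signature and differ only in FMG, while MF and HG share FMG/IMU
and differ only in EMG — so no single modality can resolve both pairs but
the fused feature vector can. An :class:`ImpairmentProfile` attenuates all
signatures (weaker, less distinct muscle activity) and can blend a
movement's signature toward a designated confusable partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import (
    EMG_RATE,
    LOW_RATE,
    MOVEMENT_LABELS,
    N_EMG,
    N_FMG,
    N_IMU,
    MultimodalRecording,
    ValidationError,
    write_session,
)

__all__ = [
    "SynthConfig",
    "ImpairmentProfile",
    "default_signatures",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

#: Movement pairs an impaired realization may blend toward.
CONFUSABLE_PARTNERS = {"CG": "SG", "SG": "CG", "TA": "O", "O": "TA"}


def default_signatures() -> dict[str, np.ndarray]:
    """Per-class EMG activations (12×6, in [0,1]), FMG offsets (12×8) and
    IMU offsets (12×12), rows in ``MOVEMENT_LABELS`` order.

    Deliberate structure: CG and SG rows are identical in EMG and IMU and
    differ only in FMG; MF and HG rows are identical in FMG and IMU and
    differ only in EMG; the rest class NM is all zeros. Wrist/forearm
    movements (WF, WE, FP, FS) carry the largest IMU offsets; finger
    movements carry little IMU information. WE channel 1 is exactly zero so
    an inactive channel is indistinguishable from rest.
    """
    emg = np.array([
        #  ch1  ch2  ch3  ch4  ch5  ch6
        [0.90, 0.70, 0.20, 0.10, 0.50, 0.30],  # MF
        [0.20, 0.30, 0.80, 0.90, 0.30, 0.60],  # ME
        [0.60, 0.90, 0.50, 0.30, 0.20, 0.60],  # HG  (≠ MF in EMG only)
        [0.30, 0.20, 0.30, 0.50, 0.80, 0.20],  # TA
        [0.50, 0.40, 0.20, 0.60, 0.60, 0.40],  # O
        [0.80, 0.50, 0.40, 0.20, 0.30, 0.70],  # CG
        [0.80, 0.50, 0.40, 0.20, 0.30, 0.70],  # SG  (== CG in EMG)
        [0.70, 0.30, 0.10, 0.20, 0.90, 0.50],  # WF
        [0.00, 0.40, 0.90, 0.60, 0.20, 0.30],  # WE  (ch1 silent)
        [0.40, 0.60, 0.30, 0.80, 0.40, 0.20],  # FP
        [0.30, 0.50, 0.60, 0.40, 0.70, 0.80],  # FS
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00],  # NM
    ])
    fmg = np.array([
        [8, 6, 2, 1, 4, 3, 2, 5],  # MF
        [2, 3, 7, 8, 3, 5, 6, 2],  # ME
        [8, 6, 2, 1, 4, 3, 2, 5],  # HG  (== MF in FMG)
        [3, 2, 3, 5, 7, 2, 4, 6],  # TA
        [5, 4, 2, 6, 6, 4, 3, 2],  # O
        [7, 5, 4, 2, 3, 6, 8, 4],  # CG
        [3, 8, 6, 5, 2, 4, 3, 7],  # SG  (≠ CG in FMG only)
        [6, 3, 1, 2, 8, 5, 4, 3],  # WF
        [1, 4, 8, 6, 2, 3, 5, 7],  # WE
        [4, 6, 3, 7, 4, 2, 6, 5],  # FP
        [2, 5, 6, 4, 7, 8, 3, 2],  # FS
        [0, 0, 0, 0, 0, 0, 0, 0],  # NM
    ], dtype=float)
    imu = np.zeros((12, N_IMU))
    # columns: ax ay az gx gy gz mx my mz roll pitch yaw
    imu[0] = [0.3, 0.1, 0.0, 0, 0, 0, 0.2, 0.1, 0.0, 1.0, 0.5, 0.2]  # MF
    imu[1] = [0.1, 0.3, 0.1, 0, 0, 0, 0.1, 0.2, 0.1, 0.8, 0.9, 0.3]  # ME
    imu[2] = imu[0].copy()                                            # HG == MF
    imu[3] = [0.2, 0.0, 0.2, 0, 0, 0, 0.0, 0.1, 0.2, 0.5, 0.4, 0.6]  # TA
    imu[4] = [0.0, 0.2, 0.3, 0, 0, 0, 0.1, 0.0, 0.1, 0.6, 0.7, 0.1]  # O
    imu[5] = [0.2, 0.2, 0.1, 0, 0, 0, 0.2, 0.2, 0.0, 0.9, 0.3, 0.4]  # CG
    imu[6] = imu[5].copy()                                            # SG == CG
    imu[7] = [1.5, 0.8, 0.4, 2.0, 0.5, 0.3, 1.0, 0.4, 0.2, 12.0, 4.0, 1.5]  # WF
    imu[8] = [0.6, 1.4, 0.5, 0.4, 2.2, 0.4, 0.3, 1.1, 0.3, -10.0, 5.0, 2.0]  # WE
    imu[9] = [0.8, 0.5, 1.6, 0.3, 0.6, 2.4, 0.5, 0.2, 1.2, 3.0, -11.0, 6.0]  # FP
    imu[10] = [0.5, 0.9, 1.2, 0.5, 0.4, 2.0, 0.2, 0.6, 0.9, -4.0, 9.0, -7.0]  # FS
    return {"emg": emg, "fmg": fmg, "imu": imu}


@dataclass(frozen=True)
class ImpairmentProfile:
    """Subject-level attenuation and confusability of movement signatures.

    ``gamma`` in (0, 1] scales every class signature (1 = unimpaired).
    With probability ``confusion_prob`` a movement's realized signature in a
    trial is a convex blend with its designated confusable partner
    (CG↔SG, TA↔O) at weight ``blend_weight`` in [0, 0.5].
    """

    gamma: float = 1.0
    confusion_prob: float = 0.0
    blend_weight: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValidationError(f"gamma must be in (0, 1], got {self.gamma}")
        if not 0.0 <= self.confusion_prob <= 1.0:
            raise ValidationError("confusion_prob must be in [0, 1]")
        if not 0.0 <= self.blend_weight <= 0.5:
            raise ValidationError("blend_weight must be in [0, 0.5]")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the guided training protocol: 12 movements per trial,
    5 trials, 6 s per movement with 4 s rests. Noise scales and amplitudes
    are in the streams' native units (EMG mV, FMG calibrated pressure units,
    IMU mixed units).
    """

    n_classes: int = 12
    n_trials: int = 5
    movement_duration_s: float = 6.0
    inter_movement_gap_s: float = 4.0
    emg_amplitude: float = 0.5        # mV scale of fully-activated EMG
    sigma_emg: float = 0.01           # EMG sensor-noise floor, mV
    fmg_baseline: float = 50.0
    sigma_fmg: float = 1.0
    drift_amplitude: float = 0.25     # ~5% of the mean FMG signature scale
    drift_period_s: float = 40.0
    sigma_imu: float = 0.5
    ramp_s: float = 0.25              # raised-cosine edge ramp
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    clip_fraction: float = 0.0        # fraction of low-rate samples pushed out of range
    fmg_valid_range: tuple[float, float] = (0.0, 115.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= len(MOVEMENT_LABELS):
            raise ValidationError(f"n_classes must be in [1, {len(MOVEMENT_LABELS)}]")
        if self.movement_duration_s <= 0 or self.inter_movement_gap_s < 0:
            raise ValidationError("durations must be positive")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if not 0.0 <= self.clip_fraction < 1.0:
            raise ValidationError("clip_fraction must be in [0, 1)")

    @property
    def labels(self) -> tuple[str, ...]:
        return MOVEMENT_LABELS[: self.n_classes]

    @property
    def duration_s(self) -> float:
        n = self.n_classes
        return n * self.movement_duration_s + (n - 1) * self.inter_movement_gap_s


def _raised_cosine_envelope(n: int, ramp: int) -> np.ndarray:
    """Unit plateau with half-cosine ramps of ``ramp`` samples at each edge."""
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = up
        env[n - r:] = up[::-1]
    return env


def _bandlimited_noise(rng: np.random.Generator, n: int, n_ch: int,
                       band: tuple[float, float], rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise shaped to ``band`` (Hz), per channel."""
    white = rng.standard_normal((n, n_ch))
    nyq = rate / 2.0
    sos = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    shaped = sps.sosfiltfilt(sos, white, axis=0)
    shaped /= shaped.std(axis=0, keepdims=True)
    return shaped


def _realized_signatures(cfg: SynthConfig, impairment: ImpairmentProfile,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    sig = default_signatures()
    emg = sig["emg"][: cfg.n_classes].copy()
    fmg = sig["fmg"][: cfg.n_classes].copy()
    imu = sig["imu"][: cfg.n_classes].copy()
    labels = cfg.labels
    for i, lab in enumerate(labels):
        partner = CONFUSABLE_PARTNERS.get(lab)
        if (
            partner is not None
            and partner in labels
            and impairment.confusion_prob > 0
            and rng.random() < impairment.confusion_prob
        ):
            j = labels.index(partner)
            w = impairment.blend_weight
            emg[i] = (1 - w) * sig["emg"][i] + w * sig["emg"][j]
            fmg[i] = (1 - w) * sig["fmg"][i] + w * sig["fmg"][j]
            imu[i] = (1 - w) * sig["imu"][i] + w * sig["imu"][j]
    g = impairment.gamma
    return {"emg": g * emg, "fmg": g * fmg, "imu": g * imu}


def generate_trial(
    cfg: SynthConfig,
    impairment: ImpairmentProfile | None = None,
    trial_id: int = 0,
    subject_id: str = "S00",
    subject_index: int = 0,
) -> MultimodalRecording:
    """Generate one trial: ``n_classes`` movement blocks in label order.

    The stream is fully determined by ``(cfg.seed, subject_index, trial_id)``.
    """
    impairment = impairment or ImpairmentProfile()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index, trial_id]))

    duration = cfg.duration_s
    n_emg = int(round(duration * EMG_RATE))
    n_low = int(round(duration * LOW_RATE))
    sig = _realized_signatures(cfg, impairment, rng)

    # Per-sample class index (-1 = rest gap) at both rates.
    cls_emg = np.full(n_emg, -1, dtype=int)
    cls_low = np.full(n_low, -1, dtype=int)
    env_emg = np.zeros(n_emg)
    env_low = np.zeros(n_low)
    triggers: list[tuple[str, float]] = []
    period = cfg.movement_duration_s + cfg.inter_movement_gap_s
    for c, label in enumerate(cfg.labels):
        onset = c * period
        triggers.append((label, onset))
        e0, e1 = int(round(onset * EMG_RATE)), int(round((onset + cfg.movement_duration_s) * EMG_RATE))
        l0, l1 = int(round(onset * LOW_RATE)), int(round((onset + cfg.movement_duration_s) * LOW_RATE))
        e1, l1 = min(e1, n_emg), min(l1, n_low)
        cls_emg[e0:e1] = c
        cls_low[l0:l1] = c
        env_emg[e0:e1] = _raised_cosine_envelope(e1 - e0, int(round(cfg.ramp_s * EMG_RATE)))
        env_low[l0:l1] = _raised_cosine_envelope(l1 - l0, int(round(cfg.ramp_s * LOW_RATE)))

    # EMG: activation-modulated band-limited noise + sensor noise.
    carrier = _bandlimited_noise(rng, n_emg, N_EMG, cfg.emg_band_hz, EMG_RATE)
    act = np.zeros((n_emg, N_EMG))
    active = cls_emg >= 0
    act[active] = sig["emg"][cls_emg[active]]
    emg = cfg.emg_amplitude * act * env_emg[:, None] * carrier
    emg += cfg.sigma_emg * rng.standard_normal((n_emg, N_EMG))

    # FMG: baseline + class offset + slow drift + noise.
    t_low = np.arange(n_low) / LOW_RATE
    offset = np.zeros((n_low, N_FMG))
    active_low = cls_low >= 0
    offset[active_low] = sig["fmg"][cls_low[active_low]]
    phases = rng.uniform(0, 2 * np.pi, N_FMG)
    drift = cfg.drift_amplitude * np.sin(
        2 * np.pi * t_low[:, None] / cfg.drift_period_s + phases[None, :]
    )
    fmg = cfg.fmg_baseline + offset * env_low[:, None] + drift
    fmg += cfg.sigma_fmg * rng.standard_normal((n_low, N_FMG))

    # IMU: class offset + noise.
    imu_offset = np.zeros((n_low, N_IMU))
    imu_offset[active_low] = sig["imu"][cls_low[active_low]]
    imu = imu_offset * env_low[:, None] + cfg.sigma_imu * rng.standard_normal((n_low, N_IMU))

    if cfg.clip_fraction > 0:
        n_clip = int(round(cfg.clip_fraction * n_low))
        idx = rng.choice(n_low, size=n_clip, replace=False)
        ch = rng.integers(0, N_FMG, size=n_clip)
        fmg[idx, ch] = cfg.fmg_valid_range[1] + 1.0 + rng.random(n_clip)

    return MultimodalRecording(
        emg=emg,
        fmg=fmg,
        imu=imu,
        triggers=triggers,
        subject_id=subject_id,
        trial_id=trial_id,
        fmg_valid_range=cfg.fmg_valid_range,
    )


def generate_cohort(
    cfg: SynthConfig,
    profiles: list[ImpairmentProfile],
) -> list[list[MultimodalRecording]]:
    """One subject per impairment profile, ``cfg.n_trials`` trials each.

    Trial streams are seeded from ``(cfg.seed, subject_index, trial_id)`` so
    distinct subjects/trials never share a stream and regeneration with the
    same master seed is bit-identical.
    """
    if not profiles:
        raise ValidationError("need at least one impairment profile")
    cohort = []
    for s, profile in enumerate(profiles):
        subject_id = f"S{s:02d}"
        trials = [
            generate_trial(cfg, profile, trial_id=t, subject_id=subject_id, subject_index=s)
            for t in range(cfg.n_trials)
        ]
        cohort.append(trials)
    return cohort


def write_cohort(cohort: list[list[MultimodalRecording]], out_dir: str | Path) -> list[Path]:
    """Write every trial as ``<out>/<subject>/trial<k>`` session directories."""
    out_dir = Path(out_dir)
    paths = []
    for trials in cohort:
        for rec in trials:
            p = out_dir / rec.subject_id / f"trial{rec.trial_id}"
            write_session(rec, p)
            paths.append(p)
    return paths
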