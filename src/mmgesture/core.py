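"""Domain types and session-directory I/O for multimodal gesture recordings.

A *session* is one trial of one subject: six forearm EMG channels sampled at
1926 Hz, eight wrist barometric-pressure (FMG) channels and twelve IMU
channels (accelerometer, gyroscope, magnetometer, Euler angles) sampled at
36 Hz, plus a trigger track marking the onset of each instructed movement.

On disk a session is a directory of plain-text files::

    meta.json      subject/trial ids, rates, channel counts, FMG valid range
    emg.csv        t,ch1..ch6
    fmg.csv        t,ch1..ch8
    imu.csv        t,ax,ay,az,gx,gy,gz,mx,my,mz,roll,pitch,yaw
    triggers.csv   onset_s,label

Floats are written with 9 significant digits so that rewriting the same
recording is byte-identical and a read/write round trip is lossless to the
declared precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EMG_RATE",
    "LOW_RATE",
    "N_EMG",
    "N_FMG",
    "N_IMU",
    "N_FEATURES",
    "MOVEMENT_LABELS",
    "REST_LABEL",
    "IMU_CHANNELS",
    "EMG_FEATURE_NAMES",
    "FEATURE_NAMES",
    "FEATURE_MODALITY",
    "FormatError",
    "ValidationError",
    "MultimodalRecording",
    "Segment",
    "SensorConfig",
    "ALL_SENSOR_SUBSETS",
    "sensor_mask",
    "read_session",
    "write_session",
]

EMG_RATE = 1926.0
LOW_RATE = 36.0
N_EMG = 6
N_FMG = 8
N_IMU = 12
N_FEATURES = 68

#: The 11 Fugl-Meyer-derived hand/wrist/forearm movements plus rest (NM).
MOVEMENT_LABELS: tuple[str, ...] = (
    "MF", "ME", "HG", "TA", "O", "CG", "SG", "WF", "WE", "FP", "FS", "NM",
)
REST_LABEL = "NM"

IMU_CHANNELS: tuple[str, ...] = (
    "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz", "roll", "pitch", "yaw",
)

#: Per-EMG-channel feature block, in frozen order.
EMG_FEATURE_NAMES: tuple[str, ...] = (
    "MAV", "WL", "ZC", "SSC", "AR1", "AR2", "AR3", "AR4",
)

#: Frozen 68-column feature ordering: per EMG channel 1..6 the 8-tuple
#: [MAV, WL, ZC, SSC, AR1..AR4], then FMG-MAV ch 1..8, then IMU-MAV ch 1..12.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"emg{ch + 1}_{feat}" for ch in range(N_EMG) for feat in EMG_FEATURE_NAMES
) + tuple(f"fmg{ch + 1}_MAV" for ch in range(N_FMG)) + tuple(
    f"imu_{name}_MAV" for name in IMU_CHANNELS
)

FEATURE_MODALITY: tuple[str, ...] = (
    ("EMG",) * (8 * N_EMG) + ("FMG",) * N_FMG + ("IMU",) * N_IMU
)

_FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """A session directory is missing files or malformed."""


class ValidationError(ValueError):
    """A recording or configuration violates a structural invariant."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class MultimodalRecording:
    """Synchronized raw streams plus trigger events for one trial.

    ``emg`` is (n_emg, 6) in millivolts at 1926 Hz; ``fmg`` is (n_low, 8)
    calibrated pressure units and ``imu`` (n_low, 12), both at 36 Hz.
    ``triggers`` is an ordered list of ``(label, onset_seconds)``.
    """

    emg: np.ndarray
    fmg: np.ndarray
    imu: np.ndarray
    triggers: list[tuple[str, float]]
    subject_id: str = "S00"
    trial_id: int = 0
    fmg_valid_range: tuple[float, float] = (0.0, 115.0)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.fmg = np.asarray(self.fmg, dtype=float)
        self.imu = np.asarray(self.imu, dtype=float)
        self.validate()

    @property
    def n_emg(self) -> int:
        return self.emg.shape[0]

    @property
    def n_low(self) -> int:
        return self.fmg.shape[0]

    @property
    def duration(self) -> float:
        """Wall-clock duration in seconds, from the low-rate streams."""
        return self.n_low / LOW_RATE

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[1] != N_EMG:
            raise ValidationError(
                f"emg stream must have {N_EMG} channels, got shape {self.emg.shape}"
            )
        if self.fmg.ndim != 2 or self.fmg.shape[1] != N_FMG:
            raise ValidationError(
                f"fmg stream must have {N_FMG} channels, got shape {self.fmg.shape}"
            )
        if self.imu.ndim != 2 or self.imu.shape[1] != N_IMU:
            raise ValidationError(
                f"imu stream must have {N_IMU} channels, got shape {self.imu.shape}"
            )
        if self.fmg.shape[0] != self.imu.shape[0]:
            raise ValidationError(
                "fmg and imu streams must share one low-rate length "
                f"({self.fmg.shape[0]} != {self.imu.shape[0]})"
            )
        # Both streams must describe the same wall clock, to within one
        # low-rate sample period.
        if abs(self.n_emg / EMG_RATE - self.n_low / LOW_RATE) > 1.0 / LOW_RATE:
            raise ValidationError(
                "emg and low-rate stream durations disagree: "
                f"{self.n_emg / EMG_RATE:.4f}s vs {self.n_low / LOW_RATE:.4f}s"
            )
        lo, hi = self.fmg_valid_range
        if not lo < hi:
            raise ValidationError(f"fmg_valid_range must satisfy low < high, got {lo!r} >= {hi!r}")
        last = -np.inf
        for label, onset in self.triggers:
            if label not in MOVEMENT_LABELS:
                raise ValidationError(f"unknown movement label {label!r}")
            if not onset > last:
                raise ValidationError("trigger onsets must be strictly increasing")
            if onset < 0 or onset > self.duration:
                raise ValidationError(
                    f"trigger onset {onset}s outside recording [0, {self.duration:.3f}]s"
                )
            last = onset

    def equals(self, other: "MultimodalRecording", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-by-field equality (exact by default)."""
        return (
            self.subject_id == other.subject_id
            and self.trial_id == other.trial_id
            and self.fmg_valid_range == tuple(other.fmg_valid_range)
            and len(self.triggers) == len(other.triggers)
            and all(
                a[0] == b[0] and np.isclose(a[1], b[1], rtol=rtol, atol=max(atol, 0.0))
                for a, b in zip(self.triggers, other.triggers)
            )
            and np.allclose(self.emg, other.emg, rtol=rtol, atol=atol)
            and np.allclose(self.fmg, other.fmg, rtol=rtol, atol=atol)
            and np.allclose(self.imu, other.imu, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class Segment:
    """One movement's extent, as half-open sample intervals per stream."""

    label: str
    emg_range: tuple[int, int]
    low_range: tuple[int, int]
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.label not in MOVEMENT_LABELS:
            raise ValidationError(f"unknown movement label {self.label!r}")
        e0, e1 = self.emg_range
        l0, l1 = self.low_range
        if not (e0 < e1 and l0 < l1):
            raise ValidationError(f"segment ranges must be non-empty: {self.emg_range}, {self.low_range}")
        if abs((e1 - e0) / EMG_RATE - (l1 - l0) / LOW_RATE) > 1.0 / LOW_RATE:
            raise ValidationError("emg and low-rate segment durations disagree")

    @property
    def emg_len(self) -> int:
        return self.emg_range[1] - self.emg_range[0]

    @property
    def low_len(self) -> int:
        return self.low_range[1] - self.low_range[0]


_MODALITY_SLICES = {
    "EMG": slice(0, 48),
    "FMG": slice(48, 56),
    "IMU": slice(56, 68),
}

#: All 7 non-empty sensor subsets, singles → doubles → triple.
ALL_SENSOR_SUBSETS: tuple[frozenset, ...] = (
    frozenset({"EMG"}),
    frozenset({"FMG"}),
    frozenset({"IMU"}),
    frozenset({"EMG", "FMG"}),
    frozenset({"EMG", "IMU"}),
    frozenset({"FMG", "IMU"}),
    frozenset({"EMG", "FMG", "IMU"}),
)


def sensor_mask(sensors: Iterable[str]) -> np.ndarray:
    """Column indices into the 68-dim feature vector for a sensor subset."""
    sensors = set(sensors)
    if not sensors:
        raise ValidationError("sensor subset must be non-empty")
    unknown = sensors - set(_MODALITY_SLICES)
    if unknown:
        raise ValidationError(f"unknown sensors {sorted(unknown)}")
    cols: list[int] = []
    for name in ("EMG", "FMG", "IMU"):  # frozen column-block order
        if name in sensors:
            cols.extend(range(_MODALITY_SLICES[name].start, _MODALITY_SLICES[name].stop))
    return np.asarray(cols, dtype=int)


@dataclass(frozen=True)
class SensorConfig:
    """A subset of {EMG, FMG, IMU}, determining a feature-column mask."""

    sensors: frozenset = frozenset({"EMG", "FMG", "IMU"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensors", frozenset(self.sensors))
        sensor_mask(self.sensors)  # validates

    @property
    def mask(self) -> np.ndarray:
        return sensor_mask(self.sensors)

    @property
    def name(self) -> str:
        return "+".join(s for s in ("EMG", "FMG", "IMU") if s in self.sensors)


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

def _format_csv(t: np.ndarray, data: np.ndarray, header: Sequence[str]) -> str:
    cols = np.column_stack([t, data])
    lines = [",".join(header)]
    for row in cols:
        lines.append(",".join(_FLOAT_FMT % v for v in row))
    return "\n".join(lines) + "\n"


def write_session(rec: MultimodalRecording, path: str | Path) -> Path:
    """Write a recording as a session directory; returns the directory path.

    Two writes of the same recording produce byte-identical files.
    """
    rec.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "rates": {"emg": int(EMG_RATE), "low": int(LOW_RATE)},
        "channels": {"emg": N_EMG, "fmg": N_FMG, "imu": N_IMU},
        "fmg_valid_range": [rec.fmg_valid_range[0], rec.fmg_valid_range[1]],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    t_emg = np.arange(rec.n_emg) / EMG_RATE
    t_low = np.arange(rec.n_low) / LOW_RATE
    (path / "emg.csv").write_text(
        _format_csv(t_emg, rec.emg, ["t"] + [f"ch{i + 1}" for i in range(N_EMG)])
    )
    (path / "fmg.csv").write_text(
        _format_csv(t_low, rec.fmg, ["t"] + [f"ch{i + 1}" for i in range(N_FMG)])
    )
    (path / "imu.csv").write_text(_format_csv(t_low, rec.imu, ["t"] + list(IMU_CHANNELS)))

    lines = ["onset_s,label"]
    for label, onset in rec.triggers:
        lines.append(f"{_FLOAT_FMT % onset},{label}")
    (path / "triggers.csv").write_text("\n".join(lines) + "\n")
    return path


def _read_stream(path: Path, n_channels: int, names: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path)
    expected = ["t"] + list(names)
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path.name}: expected columns {expected}, got {list(df.columns)}"
        )
    data = df[list(names)].to_numpy(dtype=float)
    if data.shape[1] != n_channels:
        raise ValidationError(f"{path.name}: expected {n_channels} channels")
    return data


def read_session(path: str | Path) -> MultimodalRecording:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("meta.json", "emg.csv", "fmg.csv", "imu.csv", "triggers.csv"):
        if not (path / fname).exists():
            raise FormatError(f"session {path} is missing {fname}")

    meta = json.loads((path / "meta.json").read_text())
    rates = meta.get("rates", {})
    channels = meta.get("channels", {})
    if rates.get("emg") != int(EMG_RATE) or rates.get("low") != int(LOW_RATE):
        raise ValidationError(f"meta.json declares unsupported rates {rates}")
    if (channels.get("emg"), channels.get("fmg"), channels.get("imu")) != (N_EMG, N_FMG, N_IMU):
        raise ValidationError(f"meta.json declares unsupported channel counts {channels}")

    emg = _read_stream(path / "emg.csv", N_EMG, [f"ch{i + 1}" for i in range(N_EMG)])
    fmg = _read_stream(path / "fmg.csv", N_FMG, [f"ch{i + 1}" for i in range(N_FMG)])
    imu = _read_stream(path / "imu.csv", N_IMU, IMU_CHANNELS)

    trig_df = pd.read_csv(path / "triggers.csv")
    if list(trig_df.columns) != ["onset_s", "label"]:
        raise ValidationError("triggers.csv: expected columns ['onset_s', 'label']")
    triggers = [(str(row.label), float(row.onset_s)) for row in trig_df.itertuples()]

    return MultimodalRecording(
        emg=emg,
        fmg=fmg,
        imu=imu,
        triggers=triggers,
        subject_id=str(meta["subject_id"]),
        trial_id=int(meta["trial_id"]),
        fmg_valid_range=tuple(meta["fmg_valid_range"]),
    )
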