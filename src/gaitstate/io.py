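"""Data model for insole GRF recordings and state labels, plus CSV persistence.

An insole recording is a matrix of per-sensor vertical forces sampled at a
fixed rate (typically 100 Hz), one column per force-sensing resistor (FSR).
Sensor positions live in a :class:`SensorLayout`; ground-truth standing/walking
labels live in a :class:`StateSeries` whose rate may differ from the force
stream (motion-capture reference systems commonly run at 30 Hz), hence the
trigger-based :func:`synchronize`.

Coordinate convention: ``x`` is medio-lateral (negative = wearer's left),
``y`` is anterior-posterior (increasing toward the toes), both in metres and
shared between the two feet so that inter-foot geometry is meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

STANDING = 0
WALKING = 1

__all__ = [
    "STANDING",
    "WALKING",
    "Sensor",
    "SensorLayout",
    "Subject",
    "GrfRecording",
    "StateSeries",
    "SynchronizationError",
    "synchronize",
    "read_recording",
    "write_recording",
    "read_states",
    "write_states",
]


class SynchronizationError(ValueError):
    """Raised when trigger marks are missing or span no time."""


@dataclass(frozen=True)
class Sensor:
    """One FSR: an identifier and its planar position in metres."""

    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"sensor {self.id!r} has non-finite coordinates")


@dataclass(frozen=True)
class SensorLayout:
    """Per-foot FSR identifiers and coordinates.

    The default layout places four sensors per foot at the load-bearing
    landmarks of the sole: heel, fifth metatarsal head, first metatarsal
    head, and hallux, with the feet ~0.18 m apart mediolaterally. Any layout
    with at least two sensors per foot is accepted; real devices differ in
    sensor count and placement, so this is fully configurable.
    """

    left: tuple[Sensor, ...]
    right: tuple[Sensor, ...]

    def __post_init__(self) -> None:
        for foot, sensors in (("left", self.left), ("right", self.right)):
            if len(sensors) < 2:
                raise ValueError(f"{foot} foot needs >=2 sensors")
            ids = [s.id for s in sensors]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate sensor ids on {foot} foot: {ids}")

    @classmethod
    def default(cls) -> "SensorLayout":
        half = 0.09  # half inter-foot distance, m
        spots = [
            ("heel", 0.00, 0.03),
            ("met5", 0.04, 0.15),  # lateral forefoot
            ("met1", -0.03, 0.16),  # medial forefoot
            ("hallux", -0.01, 0.22),
        ]
        left = tuple(Sensor(n, -half + dx * -1, y) for n, dx, y in spots)
        right = tuple(Sensor(n, half + dx, y) for n, dx, y in spots)
        return cls(left=left, right=right)

    @property
    def n_sensors(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def column_names(self) -> list[str]:
        return [f"L:{s.id}" for s in self.left] + [f"R:{s.id}" for s in self.right]

    def coords(self, foot: str) -> np.ndarray:
        """(n, 2) array of sensor x/y for ``foot`` in {'left','right','both'}."""
        if foot == "left":
            sensors: Sequence[Sensor] = self.left
        elif foot == "right":
            sensors = self.right
        elif foot == "both":
            sensors = tuple(self.left) + tuple(self.right)
        else:
            raise ValueError(f"unknown foot selector {foot!r}")
        return np.array([[s.x, s.y] for s in sensors], dtype=float)

    def to_dict(self) -> dict:
        return {
            foot: [{"id": s.id, "x": s.x, "y": s.y} for s in getattr(self, foot)]
            for foot in ("left", "right")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        return cls(
            left=tuple(Sensor(e["id"], float(e["x"]), float(e["y"])) for e in d["left"]),
            right=tuple(Sensor(e["id"], float(e["x"]), float(e["y"])) for e in d["right"]),
        )


@dataclass(frozen=True)
class Subject:
    """Anthropometrics needed by the feature pipeline."""

    height: float  # m
    weight: float  # kg
    group: str = "healthy"  # 'healthy' | 'patient'

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if self.group not in ("healthy", "patient"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class StateSeries:
    """A binary standing(0)/walking(1) label stream at a fixed rate."""

    sampling_rate: float
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-D")
        if not np.isin(self.states, (STANDING, WALKING)).all():
            raise ValueError("states must contain only 0 (standing) and 1 (walking)")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.states)) / self.sampling_rate


@dataclass
class GrfRecording:
    """Synchronized per-sensor force matrix with subject metadata.

    ``forces`` is (n_samples, n_sensors) in newtons; column order follows
    ``layout.column_names`` (left sensors first). ``trigger_marks`` are the
    sample indices of the experiment start/end trigger signals, half-open:
    samples ``start <= i < end`` are inside the experiment.
    """

    sampling_rate: float
    forces: np.ndarray
    layout: SensorLayout
    subject: Subject
    trigger_marks: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != self.layout.n_sensors:
            raise ValueError(
                f"forces must be (n_samples, {self.layout.n_sensors}); "
                f"got {self.forces.shape}"
            )
        if (self.forces < 0).any():
            raise ValueError("forces must be non-negative")
        if self.trigger_marks is not None:
            s, e = self.trigger_marks
            if not (0 <= s < e <= len(self.forces)):
                raise ValueError(f"bad trigger marks {self.trigger_marks}")
            self.trigger_marks = (int(s), int(e))

    @property
    def n_samples(self) -> int:
        return len(self.forces)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def foot_forces(self, foot: str) -> np.ndarray:
        nl = len(self.layout.left)
        if foot == "left":
            return self.forces[:, :nl]
        if foot == "right":
            return self.forces[:, nl:]
        if foot == "both":
            return self.forces
        raise ValueError(f"unknown foot selector {foot!r}")

    def foot_sum(self, foot: str) -> np.ndarray:
        """Per-sample sum of GRF over the selected foot's sensors (N)."""
        return self.foot_forces(foot).sum(axis=1)


def synchronize(
    grf: GrfRecording,
    labels: StateSeries,
    label_trigger_marks: tuple[int, int],
) -> StateSeries:
    """Resample a label stream onto the force-sample grid between triggers.

    Both streams carry trigger marks at experiment start and end. Each force
    sample inside the GRF trigger span is mapped to normalized time within
    the span and assigned the nearest-in-time source label (labels are
    categorical, so nearest-neighbour rather than linear interpolation).
    Samples outside the span are truncated.
    """
    if grf.trigger_marks is None:
        raise SynchronizationError("recording has no trigger marks")
    if label_trigger_marks is None:
        raise SynchronizationError("label stream has no trigger marks")
    gs, ge = grf.trigger_marks
    ls, le = int(label_trigger_marks[0]), int(label_trigger_marks[1])
    if ge <= gs or le <= ls:
        raise SynchronizationError("zero-length trigger span")
    if not (0 <= ls < le <= len(labels)):
        raise SynchronizationError(f"label trigger marks {label_trigger_marks} out of range")
    idx = np.arange(gs, ge)
    t_norm = (idx - gs) / (ge - gs)
    src = np.rint(ls + t_norm * (le - ls)).astype(int)
    src = np.clip(src, 0, len(labels) - 1)
    return StateSeries(sampling_rate=grf.sampling_rate, states=labels.states[src])


# ---------------------------------------------------------------------------
# CSV persistence: one CSV of forces per recording + a YAML metadata sidecar.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_recording(recording: GrfRecording, path: str | Path) -> None:
    """Write forces to ``path`` (CSV) and metadata to ``<path>.meta.yaml``."""
    path = Path(path)
    df = pd.DataFrame(recording.forces, columns=recording.layout.column_names)
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless float64
    meta = {
        "sampling_rate": float(recording.sampling_rate),
        "subject": {
            "height": float(recording.subject.height),
            "weight": float(recording.subject.weight),
            "group": recording.subject.group,
        },
        "trigger_marks": list(recording.trigger_marks)
        if recording.trigger_marks is not None
        else None,
        "layout": recording.layout.to_dict(),
        "meta": recording.meta,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_recording(path: str | Path) -> GrfRecording:
    """Read a recording written by :func:`write_recording` (lossless round-trip)."""
    path = Path(path)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    layout = SensorLayout.from_dict(meta["layout"])
    df = pd.read_csv(path, float_precision="round_trip")
    expected = layout.column_names
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing force columns {missing}")
    trig = meta.get("trigger_marks")
    return GrfRecording(
        sampling_rate=float(meta["sampling_rate"]),
        forces=df[expected].to_numpy(dtype=float),
        layout=layout,
        subject=Subject(**meta["subject"]),
        trigger_marks=tuple(trig) if trig is not None else None,
        meta=meta.get("meta", {}),
    )


def write_states(states: StateSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": states.times, "state": states.states})
    df.to_csv(path, index=False)


def read_states(path: str | Path, sampling_rate: float | None = None) -> StateSeries:
    df = pd.read_csv(path)
    if sampling_rate is None:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from <2 samples")
        sampling_rate = 1.0 / float(np.mean(np.diff(t)))
    return StateSeries(sampling_rate=sampling_rate, states=df["state"].to_numpy())


def relabel(series: StateSeries, states: np.ndarray) -> StateSeries:
    """A copy of ``series`` with replaced state values (same rate)."""
    return replace(series, states=np.asarray(states))
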