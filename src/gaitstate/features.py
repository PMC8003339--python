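"""Center-of-pressure geometry and the waveform-length factor.

From a per-sensor force matrix this module derives, per sample:

* the combined and per-foot COP coordinates (force-weighted mean of sensor
  positions),
* the COP gradient ``theta = arctan((COP_RY - COP_LY) / L)`` — the angle, in
  the sagittal sense, between the frontal plane and the segment joining the
  two feet's COPs, with ``L`` the inter-foot (hip-width) distance,
* its time derivative ``cop_dot`` in deg/s, and
* ``cop_w``, the waveform length of ``cop_dot``: the trailing-window sum of
  its magnitudes. During alternating gait theta swings between large positive
  and negative values, so cop_w is large while walking and near zero during
  quiet standing — the property the threshold and neural classifiers exploit.

When a foot is fully unloaded (swing) its COP is undefined; the pipeline
holds the last valid value so that theta stays finite through the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import GrfRecording, SensorLayout

#: The ten per-sample features consumed by the neural classifier, in order.
FEATURE_NAMES = [
    "grf",
    "cop_x",
    "cop_y",
    "cop_lx",
    "cop_rx",
    "cop_ly",
    "cop_ry",
    "cop_gradient",
    "cop_dot",
    "cop_w",
]

#: Hip width as a fraction of body height (standard anthropometric ratio).
DEFAULT_HIP_RATIO = 0.191

#: Trailing-window length for the waveform length, in seconds.
DEFAULT_WINDOW_S = 0.25

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_HIP_RATIO",
    "DEFAULT_WINDOW_S",
    "CopFeatureSeries",
    "compute_cop",
    "compute_cop_gradient",
    "hip_width_from_height",
    "compute_cop_dot",
    "compute_waveform_length",
    "featurize",
]


def compute_cop(
    forces: np.ndarray,
    layout: SensorLayout,
    foot: str = "both",
    min_force: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Force-weighted mean sensor position for one foot or both.

    ``forces`` is (n_samples, n_sensors) over the *full* sensor set in layout
    column order (a single sample may be passed as a 1-D array). Samples whose
    selected force sum does not exceed ``min_force`` (default: zero) have an
    undefined COP and are returned as NaN; callers decide the hold policy.
    A few newtons of floor is advisable on real or noisy data — the COP of a
    nominally unloaded foot is sensor noise, not posture.

    Returns ``(x, y)`` arrays in metres (scalars for 1-D input).
    """
    forces = np.asarray(forces, dtype=float)
    scalar = forces.ndim == 1
    f = np.atleast_2d(forces)
    if f.shape[1] != layout.n_sensors:
        raise ValueError(f"expected {layout.n_sensors} force columns, got {f.shape[1]}")
    nl = len(layout.left)
    if foot == "left":
        f = f[:, :nl]
    elif foot == "right":
        f = f[:, nl:]
    elif foot != "both":
        raise ValueError(f"unknown foot selector {foot!r}")
    coords = layout.coords(foot)
    total = f.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (f @ coords[:, 0]) / total
        y = (f @ coords[:, 1]) / total
    undefined = total <= min_force if min_force > 0 else total == 0
    x[undefined] = np.nan
    y[undefined] = np.nan
    if scalar:
        return float(x[0]), float(y[0])
    return x, y


def compute_cop_gradient(
    cop_ly: np.ndarray | float, cop_ry: np.ndarray | float, L: float
) -> np.ndarray | float:
    """COP gradient theta = arctan((cop_ry - cop_ly) / L), in radians.

    ``L`` is the inter-foot distance (> 0). The arctan image (-pi/2, pi/2)
    respects the required range by construction.
    """
    if L <= 0:
        raise ValueError("inter-foot distance L must be positive")
    return np.arctan((np.asarray(cop_ry) - np.asarray(cop_ly)) / L)[()]


def hip_width_from_height(height: float, ratio: float = DEFAULT_HIP_RATIO) -> float:
    """Inter-foot distance L approximated as hip width = ratio * height."""
    if height <= 0:
        raise ValueError("height must be positive")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio * height


def compute_cop_dot(theta: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Time derivative of theta in deg/s (backward difference x rate).

    The first sample has no predecessor and is set to 0.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or len(theta) < 2:
        raise ValueError("theta must be 1-D with >=2 samples")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    d = np.diff(theta, prepend=theta[0])
    return np.degrees(d) * sampling_rate


def compute_waveform_length(
    cop_dot: np.ndarray, window_size: int, signed: bool = False
) -> np.ndarray:
    """Waveform length: trailing-window sum of |cop_dot| (deg/s).

    ``cop_w[k]`` sums the window of ``window_size`` samples ending at ``k``
    (causal — only past data enter the current classification); windows
    shorter than ``window_size`` at the start of the series use all samples
    available so far.

    The magnitudes are summed, following the waveform-length feature of the
    EMG literature; a signed sum would cancel to ~0 over a symmetric stride
    and carry no state information. ``signed=True`` computes the raw signed
    sum for comparison.
    """
    x = np.asarray(cop_dot, dtype=float)
    if x.ndim != 1:
        raise ValueError("cop_dot must be 1-D")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not signed:
        x = np.abs(x)
    n = len(x)
    out = np.empty(n, dtype=float)
    head = min(window_size - 1, n)
    for k in range(head):
        out[k] = x[: k + 1].sum()
    if n >= window_size:
        out[window_size - 1 :] = sliding_window_view(x, window_size).sum(axis=1)
    return out


def _hold_last(x: np.ndarray, initial: float) -> np.ndarray:
    """Forward-fill NaNs; leading NaNs become ``initial``."""
    x = x.copy()
    mask = np.isnan(x)
    if not mask.any():
        return x
    idx = np.where(~mask, np.arange(len(x)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, x[np.maximum(idx, 0)], initial)
    return filled


@dataclass
class CopFeatureSeries:
    """Per-sample feature table (columns = :data:`FEATURE_NAMES`).

    ``inter_foot_distance`` is the L used for theta; ``window_size`` the
    waveform-length window in samples.
    """

    sampling_rate: float
    data: pd.DataFrame
    window_size: int
    inter_foot_distance: float

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """(n_samples, 10) matrix in canonical feature order."""
        return self.data[FEATURE_NAMES].to_numpy(dtype=float)

    @property
    def cop_w(self) -> np.ndarray:
        return self.data["cop_w"].to_numpy(dtype=float)


def featurize(
    recording: GrfRecording,
    window_size: int | None = None,
    hip_ratio: float = DEFAULT_HIP_RATIO,
    signed_waveform: bool = False,
    cop_min_force: float = 5.0,
) -> CopFeatureSeries:
    """Full feature extraction for one recording.

    Per-foot COPs undefined during swing are held at their last valid value
    (samples before any valid value take the foot's sensor centroid, the
    natural neutral position). A foot loaded below ``cop_min_force`` newtons
    counts as unloaded — without this floor, sensor noise on an airborne
    foot would masquerade as violent COP motion. ``window_size`` defaults to
    0.25 s at the recording's rate.
    """
    layout = recording.layout
    fs = recording.sampling_rate
    if window_size is None:
        window_size = max(1, int(round(DEFAULT_WINDOW_S * fs)))
    L = hip_width_from_height(recording.subject.height, hip_ratio)

    cx, cy = compute_cop(recording.forces, layout, "both", min_force=cop_min_force)
    lx, ly = compute_cop(recording.forces, layout, "left", min_force=cop_min_force)
    rx, ry = compute_cop(recording.forces, layout, "right", min_force=cop_min_force)

    lcent = layout.coords("left").mean(axis=0)
    rcent = layout.coords("right").mean(axis=0)
    bcent = layout.coords("both").mean(axis=0)
    lx = _hold_last(lx, lcent[0])
    ly = _hold_last(ly, lcent[1])
    rx = _hold_last(rx, rcent[0])
    ry = _hold_last(ry, rcent[1])
    cx = _hold_last(cx, bcent[0])
    cy = _hold_last(cy, bcent[1])

    theta = compute_cop_gradient(ly, ry, L)
    cop_dot = compute_cop_dot(theta, fs)
    cop_w = compute_waveform_length(cop_dot, window_size, signed=signed_waveform)

    data = pd.DataFrame(
        {
            "grf": recording.foot_sum("both"),
            "cop_x": cx,
            "cop_y": cy,
            "cop_lx": lx,
            "cop_rx": rx,
            "cop_ly": ly,
            "cop_ry": ry,
            "cop_gradient": theta,
            "cop_dot": cop_dot,
            "cop_w": cop_w,
        }
    )
    return CopFeatureSeries(
        sampling_rate=fs,
        data=data,
        window_size=window_size,
        inter_foot_distance=L,
    )
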