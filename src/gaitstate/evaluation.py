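"""Scoring of state classifiers against ground truth.

Per-state accuracy (standing and walking scored separately, then averaged),
histogram mode / pooled-percentile summaries of the classifying factor, and
signed start/stop detection delays with a persistence (debounce) rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import STANDING, WALKING, StateSeries

__all__ = [
    "StateAccuracy",
    "DelayStats",
    "accuracy_by_state",
    "detection_delay",
    "mode_and_percentile",
    "summarize_delays",
]


@dataclass(frozen=True)
class StateAccuracy:
    """Per-state and mean classification accuracy in percent."""

    standing: float
    walking: float

    @property
    def mean(self) -> float:
        return 0.5 * (self.standing + self.walking)


def accuracy_by_state(pred: StateSeries, truth: StateSeries) -> StateAccuracy:
    """Percent of correctly classified samples within each true state.

    Standing accuracy = correct among truth-standing samples; walking
    likewise. A state absent from the truth yields NaN for that state.
    """
    p = np.asarray(pred.states)
    y = np.asarray(truth.states)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: pred {p.shape} vs truth {y.shape}")
    out = []
    for state in (STANDING, WALKING):
        mask = y == state
        out.append(100.0 * float(np.mean(p[mask] == state)) if mask.any() else float("nan"))
    return StateAccuracy(standing=out[0], walking=out[1])


def _first_persistent(
    states: np.ndarray, target: int, start: int, min_run: int
) -> int | None:
    """First index >= start where ``states`` equals ``target`` for >= min_run samples."""
    x = states[start:] == target
    if not x.any():
        return None
    # run-length scan over change points
    idx = np.flatnonzero(np.diff(np.concatenate(([0], x.view(np.int8), [0]))))
    for run_start, run_end in zip(idx[::2], idx[1::2]):
        if run_end - run_start >= min_run:
            return start + int(run_start)
    return None


def detection_delay(
    pred: StateSeries,
    truth: StateSeries,
    events: dict,
    debounce_ms: float = 50.0,
) -> tuple[float | None, float | None]:
    """Signed start/stop classification delays in milliseconds.

    The predicted walking start is the first sample (anywhere in the trial)
    where the prediction enters walking and persists for at least
    ``debounce_ms``; the predicted stop is the first persistent standing
    entry after the midpoint of the true walking interval. Delays are
    predicted minus true event time, so negative means early detection.
    A transition that never qualifies is reported as ``None``.
    """
    fs = pred.sampling_rate
    if truth.sampling_rate != fs:
        raise ValueError("pred and truth must share a sampling rate")
    min_run = max(1, int(round(debounce_ms / 1000.0 * fs)))
    start_t, stop_t = float(events["start_s"]), float(events["stop_s"])

    i_start = _first_persistent(pred.states, WALKING, 0, min_run)
    start_delay = None if i_start is None else (i_start / fs - start_t) * 1000.0

    mid = int(round(0.5 * (start_t + stop_t) * fs))
    mid = min(max(mid, 0), len(pred.states) - 1)
    i_stop = _first_persistent(pred.states, STANDING, mid, min_run)
    stop_delay = None if i_stop is None else (i_stop / fs - stop_t) * 1000.0
    return start_delay, stop_delay


@dataclass(frozen=True)
class DelayStats:
    """Mean +/- SD of a set of signed delays (ms), with missing count."""

    mean: float
    sd: float
    n: int
    n_missing: int


def summarize_delays(delays: list[float | None]) -> DelayStats:
    vals = np.array([d for d in delays if d is not None], dtype=float)
    n_missing = len(delays) - len(vals)
    if len(vals) == 0:
        return DelayStats(mean=float("nan"), sd=float("nan"), n=0, n_missing=n_missing)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return DelayStats(mean=float(np.mean(vals)), sd=sd, n=len(vals), n_missing=n_missing)


def mode_and_percentile(
    values_state_a: np.ndarray,
    values_state_b: np.ndarray,
    bin_width: float | None = None,
) -> tuple[float, float]:
    """Histogram mode of state A and its percentile within the pooled sample.

    The mode is the centre of the highest-count histogram bin of the state-A
    values (Freedman-Diaconis binning unless ``bin_width`` is given). The
    percentile is the fraction (x100) of the pooled A+B values <= mode,
    ascending.
    """
    a = np.asarray(values_state_a, dtype=float)
    b = np.asarray(values_state_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_width is None:
        edges = np.histogram_bin_edges(a, bins="fd")
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lo, hi = float(a.min()), float(a.max())
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    mode = float(0.5 * (edges[:-1] + edges[1:])[int(np.argmax(counts))])
    pooled = np.concatenate([a, b])
    percentile = 100.0 * float(np.mean(pooled <= mode))
    return mode, percentile
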