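"""Standing/walking state classifiers and variable-importance analysis.

Three classifiers share the 0 = standing / 1 = walking label convention:

* **TAM** (Timing Analysis Module): the classical GRF threshold. The
  threshold sits 10% of the way from the minimum to the maximum per-foot
  GRF sum observed on the fitting data; a sample is *standing* only when
  both feet exceed it (a foot below threshold is off the ground, i.e. the
  wearer is mid-step). Shuffling gait defeats this rule: residual swing-foot
  contact pushes the swing foot above threshold.

* **COPw threshold**: walking iff the waveform length ``cop_w`` meets a
  threshold chosen from the overlap region of the standing/walking ``cop_w``
  histograms (the most probable value inside the overlap).

* **ANN**: a single-hidden-layer network (10 inputs, 20 sigmoid hidden
  units, 1 sigmoid output) trained by full-batch gradient descent on
  max-normalized features. One hidden layer keeps Garson's weight-based
  importance decomposition applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .features import FEATURE_NAMES, CopFeatureSeries
from .io import STANDING, WALKING, GrfRecording, StateSeries

__all__ = [
    "TamModel",
    "CopwModel",
    "AnnModel",
    "ImportanceReport",
    "tam_fit",
    "tam_classify",
    "copw_select_threshold",
    "copw_classify",
    "ann_fit",
    "ann_predict",
    "ann_forward",
    "garson_importance",
    "split_trials",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Threshold classifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TamModel:
    """GRF threshold in newtons."""

    grf_threshold: float


@dataclass(frozen=True)
class CopwModel:
    """Waveform-length threshold in deg/s."""

    copw_threshold: float


def tam_fit(grf_sums: np.ndarray | Sequence[np.ndarray]) -> TamModel:
    """Threshold = GRF_min + (GRF_max - GRF_min) * 10/100.

    ``grf_sums`` is one array or a sequence of arrays of per-foot GRF sums
    from the fitting data (fit once per subject group — the force range
    differs between groups).
    """
    if not isinstance(grf_sums, np.ndarray):
        grf_sums = np.concatenate([np.asarray(a, dtype=float) for a in grf_sums])
    if grf_sums.size == 0:
        raise ValueError("empty fitting data")
    lo = float(grf_sums.min())
    hi = float(grf_sums.max())
    if lo == hi:
        warnings.warn("degenerate GRF range (min == max); threshold = min")
    return TamModel(grf_threshold=lo + (hi - lo) * 10.0 / 100.0)


def tam_classify(
    recording: GrfRecording, model: TamModel, rule: str = "per_foot"
) -> StateSeries:
    """Standing iff the foot GRF criterion exceeds the threshold.

    ``rule='per_foot'`` (default): standing requires *both* feet above
    threshold — during a step the swing foot drops below it. ``rule='total'``
    applies the threshold to the two-foot total instead; the total rarely
    drops below 10% of its range during gait (one foot always bears load),
    so this strict reading is kept only for comparison.
    """
    th = model.grf_threshold
    if rule == "per_foot":
        standing = (recording.foot_sum("left") > th) & (recording.foot_sum("right") > th)
    elif rule == "total":
        standing = recording.foot_sum("both") > th
    else:
        raise ValueError(f"unknown rule {rule!r}")
    states = np.where(standing, STANDING, WALKING)
    return StateSeries(sampling_rate=recording.sampling_rate, states=states)


def copw_select_threshold(
    copw_standing: np.ndarray,
    copw_walking: np.ndarray,
    bin_width: float | None = None,
) -> CopwModel:
    """Pick the COPw threshold from the class-histogram overlap region.

    Aligned histograms of the standing and walking ``cop_w`` samples are
    built over their common range (Freedman-Diaconis bin width on the pooled
    sample unless ``bin_width`` is given). The overlap region is the set of
    bins where both class probabilities are positive; its density is
    ``min(p_standing, p_walking)`` per bin, and the threshold is the centre
    of the bin where that overlap density is highest (for unimodal classes
    this is where the class histograms cross). If the class histograms are
    disjoint, any threshold between them is perfect on the fitting data and
    the midpoint of the gap is returned.
    """
    s = np.asarray(copw_standing, dtype=float)
    w = np.asarray(copw_walking, dtype=float)
    if s.size == 0 or w.size == 0:
        raise ValueError("both standing and walking samples are required")
    s_max, w_min = float(s.max()), float(w.min())
    if s_max < w_min:
        return CopwModel(copw_threshold=0.5 * (s_max + w_min))
    if float(w.max()) < float(s.min()):
        warnings.warn("walking cop_w entirely below standing cop_w; check inputs")
        return CopwModel(copw_threshold=0.5 * (float(w.max()) + float(s.min())))

    pooled = np.concatenate([s, w])
    if bin_width is None:
        edges = np.histogram_bin_edges(pooled, bins="fd")
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lo, hi = float(pooled.min()), float(pooled.max())
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
    p_s = np.histogram(s, bins=edges)[0] / s.size
    p_w = np.histogram(w, bins=edges)[0] / w.size
    overlap = (p_s > 0) & (p_w > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not overlap.any():
        # ranges interleave but no bin holds both classes; split at the
        # probability-weighted boundary between the class bulks
        return CopwModel(copw_threshold=0.5 * (s_max + w_min))
    if np.array_equal(np.sort(s), np.sort(w)):
        warnings.warn("identical class distributions; threshold is their mode")
    score = np.where(overlap, np.minimum(p_s, p_w), -np.inf)
    return CopwModel(copw_threshold=float(centers[int(np.argmax(score))]))


def copw_classify(
    cop_w: np.ndarray | CopFeatureSeries,
    model: CopwModel,
    sampling_rate: float | None = None,
) -> StateSeries:
    """Walking iff cop_w >= threshold (ties classify as walking)."""
    if isinstance(cop_w, CopFeatureSeries):
        sampling_rate = cop_w.sampling_rate
        cop_w = cop_w.cop_w
    if sampling_rate is None:
        raise ValueError("sampling_rate required when passing a bare array")
    states = np.where(np.asarray(cop_w) >= model.copw_threshold, WALKING, STANDING)
    return StateSeries(sampling_rate=sampling_rate, states=states)


# ---------------------------------------------------------------------------
# Single-hidden-layer neural classifier
# ---------------------------------------------------------------------------


@dataclass
class AnnModel:
    """Weights and normalization of the 10-20-1 state classifier.

    ``norm_maxima`` are the per-feature maxima of |x| on the training data;
    inputs are divided by them before the forward pass (features spanning
    both signs are scaled by magnitude so the divisor is never ~0 for a
    sign-symmetric feature).
    """

    input_names: list[str]
    norm_maxima: np.ndarray  # (n_in,)
    w_in: np.ndarray  # (n_in, n_hidden)
    b_in: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (n_hidden,)
    b_out: float
    seed: int
    epochs: int
    learning_rate: float
    loss_curve: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_in, n_hidden = self.w_in.shape
        if len(self.input_names) != n_in or self.norm_maxima.shape != (n_in,):
            raise ValueError("input_names/norm_maxima inconsistent with w_in")
        if self.b_in.shape != (n_hidden,) or self.w_out.shape != (n_hidden,):
            raise ValueError("hidden-layer shapes inconsistent")

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _stack_features(
    features: CopFeatureSeries | Sequence[CopFeatureSeries],
) -> np.ndarray:
    if isinstance(features, CopFeatureSeries):
        return features.values
    return np.vstack([f.values for f in features])


def _stack_labels(labels: StateSeries | Sequence[StateSeries]) -> np.ndarray:
    if isinstance(labels, StateSeries):
        return labels.states.astype(float)
    return np.concatenate([s.states for s in labels]).astype(float)


def ann_fit(
    features: CopFeatureSeries | Sequence[CopFeatureSeries],
    labels: StateSeries | Sequence[StateSeries],
    seed: int = 0,
    n_hidden: int = 20,
    epochs: int = 600,
    learning_rate: float = 0.5,
    momentum: float = 0.9,
    sample_stride: int = 1,
) -> AnnModel:
    """Train the single-hidden-layer classifier (deterministic given seed).

    Full-batch gradient descent with momentum on mean binary cross-entropy;
    sigmoid activations throughout. ``sample_stride`` trains on every k-th
    sample (the decision surface is smooth in time, so a modest stride cuts
    cost without changing the fit materially). Raises if the training labels
    contain a single class.
    """
    X = _stack_features(features)[::sample_stride]
    y = _stack_labels(labels)[::sample_stride]
    if len(X) != len(y):
        raise ValueError(f"feature/label length mismatch: {len(X)} vs {len(y)}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    maxima = np.abs(X).max(axis=0)
    maxima = np.where(maxima == 0, 1.0, maxima)
    Xn = X / maxima

    rng = np.random.default_rng(seed)
    n_in = X.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
    b2 = 0.0
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0

    n = len(Xn)
    losses: list[float] = []
    eps = 1e-12
    for epoch in range(epochs):
        h = _sigmoid(Xn @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        if epoch % 25 == 0 or epoch == epochs - 1:
            loss = -float(
                np.mean(y * np.log(o + eps) + (1.0 - y) * np.log(1.0 - o + eps))
            )
            losses.append(loss)
        # BCE + sigmoid output: dL/dz_out = (o - y) / n
        dz2 = (o - y) / n
        g_w2 = h.T @ dz2
        g_b2 = float(dz2.sum())
        dh = np.outer(dz2, w2) * h * (1.0 - h)
        g_w1 = Xn.T @ dh
        g_b1 = dh.sum(axis=0)
        v_w1 = momentum * v_w1 - learning_rate * g_w1
        v_b1 = momentum * v_b1 - learning_rate * g_b1
        v_w2 = momentum * v_w2 - learning_rate * g_w2
        v_b2 = momentum * v_b2 - learning_rate * g_b2
        w1 += v_w1
        b1 += v_b1
        w2 += v_w2
        b2 += v_b2

    names = list(FEATURE_NAMES) if n_in == len(FEATURE_NAMES) else [
        f"x{i}" for i in range(n_in)
    ]
    return AnnModel(
        input_names=names,
        norm_maxima=maxima,
        w_in=w1,
        b_in=b1,
        w_out=w2,
        b_out=b2,
        seed=seed,
        epochs=epochs,
        learning_rate=learning_rate,
        loss_curve=losses,
    )


def ann_forward(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Normalized forward pass returning the output probability per row."""
    Xn = np.atleast_2d(np.asarray(X, dtype=float)) / model.norm_maxima
    h = _sigmoid(Xn @ model.w_in + model.b_in)
    return _sigmoid(h @ model.w_out + model.b_out)


def ann_predict(
    features: CopFeatureSeries | np.ndarray,
    model: AnnModel,
    sampling_rate: float | None = None,
) -> StateSeries:
    """Walking iff network output >= 0.5."""
    if isinstance(features, CopFeatureSeries):
        sampling_rate = features.sampling_rate
        X = features.values
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a bare matrix")
        X = features
    o = ann_forward(model, X)
    states = np.where(o >= 0.5, WALKING, STANDING)
    return StateSeries(sampling_rate=sampling_rate, states=states)


# ---------------------------------------------------------------------------
# Garson importance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImportanceReport:
    """Per-input relative importance in percent (non-negative, sums to 100)."""

    input_names: list[str]
    importance: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.input_names, map(float, self.importance)))


def garson_importance(model: AnnModel) -> ImportanceReport:
    """Garson's weight-decomposition importance for a one-hidden-layer net.

    For input i: ``Q_i = sum_j (|w_in[i,j]| / sum_k |w_in[k,j]|) * |w_out[j]|``
    and the report scales Q to percentages summing to 100. Hidden units whose
    incoming weights are all zero contribute nothing.
    """
    a = np.abs(model.w_in)  # (n_in, n_hidden)
    col = a.sum(axis=0)
    share = np.divide(a, col, out=np.zeros_like(a), where=col > 0)
    q = share @ np.abs(model.w_out)
    total = q.sum()
    if total == 0:
        raise ValueError("all weights are zero; importance undefined")
    return ImportanceReport(
        input_names=list(model.input_names), importance=100.0 * q / total
    )


# ---------------------------------------------------------------------------
# Trial-level split and model persistence
# ---------------------------------------------------------------------------


def split_trials(trials: Sequence, n_train: int, seed: int) -> tuple[list, list]:
    """Seeded random split at the trial level (never within a trial)."""
    if not 0 < n_train < len(trials):
        raise ValueError(f"n_train must be in (0, {len(trials)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [trials[i] for i in train_idx], [trials[i] for i in test_idx]


def save_model(model: TamModel | CopwModel | AnnModel, path: str | Path) -> None:
    """Serialize any classifier to a YAML text file."""
    if isinstance(model, TamModel):
        doc = {"kind": "tam", "grf_threshold": float(model.grf_threshold)}
    elif isinstance(model, CopwModel):
        doc = {"kind": "copw", "copw_threshold": float(model.copw_threshold)}
    elif isinstance(model, AnnModel):
        doc = {
            "kind": "ann",
            "input_names": model.input_names,
            "norm_maxima": model.norm_maxima.tolist(),
            "w_in": model.w_in.tolist(),
            "b_in": model.b_in.tolist(),
            "w_out": model.w_out.tolist(),
            "b_out": float(model.b_out),
            "seed": int(model.seed),
            "epochs": int(model.epochs),
            "learning_rate": float(model.learning_rate),
            "loss_curve": [float(v) for v in model.loss_curve],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> TamModel | CopwModel | AnnModel:
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "tam":
        return TamModel(grf_threshold=float(doc["grf_threshold"]))
    if kind == "copw":
        return CopwModel(copw_threshold=float(doc["copw_threshold"]))
    if kind == "ann":
        return AnnModel(
            input_names=list(doc["input_names"]),
            norm_maxima=np.asarray(doc["norm_maxima"], dtype=float),
            w_in=np.asarray(doc["w_in"], dtype=float),
            b_in=np.asarray(doc["b_in"], dtype=float),
            w_out=np.asarray(doc["w_out"], dtype=float),
            b_out=float(doc["b_out"]),
            seed=int(doc["seed"]),
            epochs=int(doc["epochs"]),
            learning_rate=float(doc["learning_rate"]),
            loss_curve=list(doc.get("loss_curve", [])),
        )
    raise ValueError(f"unknown model kind {kind!r} in {path}")
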