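"""End-to-end cohort experiment: simulate, split, fit, classify, score.

This is the driver shared by the command-line ``demo`` and by reproduction
scripts: per subject group it simulates a cohort, splits it at the trial
level into training and held-out sets, fits the three classifiers on the
training split (thresholds per group, as their dynamic range differs between
groups), and scores the held-out trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers as clf
from .evaluation import (
    DelayStats,
    StateAccuracy,
    accuracy_by_state,
    detection_delay,
    summarize_delays,
)
from .features import CopFeatureSeries, featurize
from .io import STANDING, WALKING, StateSeries
from .simulate import SimTrial, simulate_cohort

#: Cohort shape of the emulated study protocol: (n_subjects,
#: n_trials_per_subject, n_training_trials) per group.
COHORT_SHAPES = {
    "healthy": (28, 10, 200),
    "patient": (4, 10, 30),
}

#: Reduced shape for smoke runs.
QUICK_SHAPES = {
    "healthy": (4, 3, 8),
    "patient": (2, 3, 4),
}

__all__ = [
    "COHORT_SHAPES",
    "QUICK_SHAPES",
    "AnnConfig",
    "GroupResult",
    "run_group_experiment",
    "run_full_experiment",
    "accuracy_table",
    "delay_table",
]


@dataclass(frozen=True)
class AnnConfig:
    """Training hyperparameters of the neural classifier."""

    n_hidden: int = 20
    epochs: int = 600
    learning_rate: float = 0.5
    momentum: float = 0.9
    sample_stride: int = 3
    seed: int | None = None  # None: derive from the experiment seed


@dataclass
class GroupResult:
    """Held-out performance of the three classifiers for one group."""

    group: str
    n_train: int
    n_test: int
    tam_model: clf.TamModel
    copw_model: clf.CopwModel
    ann_model: clf.AnnModel
    accuracy: dict[str, StateAccuracy]  # method -> accuracies
    delays: dict[str, dict[str, DelayStats]] = field(default_factory=dict)
    importance: dict[str, float] = field(default_factory=dict)


def _pooled_accuracy(preds: list[StateSeries], truths: list[StateSeries]) -> StateAccuracy:
    p = np.concatenate([s.states for s in preds])
    y = np.concatenate([s.states for s in truths])
    fs = preds[0].sampling_rate
    return accuracy_by_state(StateSeries(fs, p), StateSeries(fs, y))


def run_group_experiment(
    group: str,
    seed: int,
    shape: tuple[int, int, int] | None = None,
    window_size: int | None = None,
    ann: AnnConfig | None = None,
    debounce_ms: float = 50.0,
    stand_range_s: tuple[float, float] = (3.0, 5.0),
) -> GroupResult:
    """Simulate one group's cohort and score all three classifiers on held-out trials.

    ``seed`` drives the simulation, the trial split, and the network
    initialization (each through an independent derived stream).
    """
    n_subjects, n_trials, n_train = shape or COHORT_SHAPES[group]
    ann = ann or AnnConfig()
    ss = np.random.SeedSequence([seed, 0 if group == "healthy" else 1])
    sim_seed, split_seed, ann_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    trials = simulate_cohort(
        n_subjects, n_trials, group, seed=sim_seed, stand_range_s=stand_range_s
    )
    train, test = clf.split_trials(trials, n_train=n_train, seed=split_seed)

    feats = {id(tr): featurize(tr.recording, window_size=window_size) for tr in trials}

    # --- TAM: per-foot GRF sums of the training split ---------------------
    tam_model = clf.tam_fit(
        [tr.recording.foot_sum(f) for tr in train for f in ("left", "right")]
    )

    # --- COPw threshold from the training split's labelled cop_w ----------
    copw_stand = np.concatenate(
        [feats[id(tr)].cop_w[tr.truth.states == STANDING] for tr in train]
    )
    copw_walk = np.concatenate(
        [feats[id(tr)].cop_w[tr.truth.states == WALKING] for tr in train]
    )
    copw_model = clf.copw_select_threshold(copw_stand, copw_walk)

    # --- ANN --------------------------------------------------------------
    ann_model = clf.ann_fit(
        [feats[id(tr)] for tr in train],
        [tr.truth for tr in train],
        seed=ann_seed if ann.seed is None else ann.seed,
        n_hidden=ann.n_hidden,
        epochs=ann.epochs,
        learning_rate=ann.learning_rate,
        momentum=ann.momentum,
        sample_stride=ann.sample_stride,
    )

    # --- score held-out trials -------------------------------------------
    methods = {
        "tam": lambda tr: clf.tam_classify(tr.recording, tam_model),
        "copw": lambda tr: clf.copw_classify(feats[id(tr)], copw_model),
        "ann": lambda tr: clf.ann_predict(feats[id(tr)], ann_model),
    }
    accuracy: dict[str, StateAccuracy] = {}
    delays: dict[str, dict[str, DelayStats]] = {}
    for name, predict in methods.items():
        preds = [predict(tr) for tr in test]
        accuracy[name] = _pooled_accuracy(preds, [tr.truth for tr in test])
        starts, stops = [], []
        for pr, tr in zip(preds, test):
            d0, d1 = detection_delay(pr, tr.truth, tr.events, debounce_ms=debounce_ms)
            starts.append(d0)
            stops.append(d1)
        delays[name] = {
            "start": summarize_delays(starts),
            "stop": summarize_delays(stops),
        }

    importance = clf.garson_importance(ann_model).as_dict()
    return GroupResult(
        group=group,
        n_train=len(train),
        n_test=len(test),
        tam_model=tam_model,
        copw_model=copw_model,
        ann_model=ann_model,
        accuracy=accuracy,
        delays=delays,
        importance=importance,
    )


def run_full_experiment(
    seed: int,
    scale: str = "full",
    window_size: int | None = None,
    ann: AnnConfig | None = None,
) -> dict[str, GroupResult]:
    """Both groups at the protocol cohort shape (``scale='quick'`` for smoke runs)."""
    shapes = COHORT_SHAPES if scale == "full" else QUICK_SHAPES
    if ann is None and scale == "quick":
        ann = AnnConfig(epochs=150)
    return {
        group: run_group_experiment(
            group, seed=seed, shape=shapes[group], window_size=window_size, ann=ann
        )
        for group in ("healthy", "patient")
    }


def accuracy_table(results: dict[str, GroupResult]) -> pd.DataFrame:
    """Accuracy summary: one row per group x method."""
    rows = []
    for group, res in results.items():
        for method, acc in res.accuracy.items():
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "standing_acc_pct": round(acc.standing, 2),
                    "walking_acc_pct": round(acc.walking, 2),
                    "mean_acc_pct": round(acc.mean, 2),
                }
            )
    return pd.DataFrame(rows)


def delay_table(results: dict[str, GroupResult]) -> pd.DataFrame:
    """Start/stop detection delays (ms, mean +/- SD) per group x method."""
    rows = []
    for group, res in results.items():
        for method, d in res.delays.items():
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "start_delay_ms": round(d["start"].mean, 1),
                    "start_delay_sd": round(d["start"].sd, 1),
                    "stop_delay_ms": round(d["stop"].mean, 1),
                    "stop_delay_sd": round(d["stop"].sd, 1),
                    "n_missing": d["start"].n_missing + d["stop"].n_missing,
                }
            )
    return pd.DataFrame(rows)
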