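"""Seeded synthetic insole-gait simulator.

Produces per-sensor GRF recordings plus ground-truth standing/walking labels
for two gait styles:

* **healthy** — quiet standing with postural sway, an anticipatory postural
  adjustment (APA) toward the swing-foot heel just before gait onset, then
  alternating steps whose stance-phase force follows a smooth double-bump
  (M-shaped) profile with the plantar load migrating heel-to-toe, and a
  fully unloaded swing foot;
* **patient** (hemiplegic, shuffling) — slower cadence, prolonged stance,
  exaggerated weight shift to the unaffected foot, and a residual
  "shuffling" force on the swing foot large enough to cross a GRF threshold
  fitted on the same data, which is precisely the failure mode of
  GRF-threshold state detection that COP-based features avoid.

The simulator is a statistical stand-in for clinical recordings, not a
forward-dynamics model: it reproduces the features the classifiers consume
(force thresholds crossed, COP geometry, timing), not joint kinetics.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GrfRecording, SensorLayout, StateSeries, Subject

G = 9.81  # m/s^2

__all__ = ["GaitProfile", "SimTrial", "simulate_trial", "simulate_cohort"]


@dataclass
class GaitProfile:
    """Subject- and group-level gait parameters.

    Defaults follow typical values for slow healthy walking and severely
    slowed hemiplegic walking: speeds 0.83 / 0.29 m/s, with the patient
    profile adding a swing-foot shuffle residual (as a fraction of body
    weight), a longer stance fraction, and an exaggerated weight shift to
    the unaffected side.
    """

    group: str = "healthy"  # 'healthy' | 'patient'
    walking_speed: float = 0.83  # m/s
    cadence: float = 1.6  # steps/s
    stance_fraction: float = 0.58  # stance duration / stride duration
    shuffle_residual: float = 0.0  # swing-foot force as fraction of bodyweight
    weight_shift_gain: float = 0.0  # exaggeration of load transfer (patient)
    apa_amplitude: float = 0.02  # m of pre-onset COP excursion
    sway_amplitude: float = 0.004  # m of standing AP sway
    noise_sd: float = 0.5  # N per sensor
    height: float = 1.70  # m
    weight: float = 62.0  # kg

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.walking_speed <= 0 or self.cadence <= 0:
            raise ValueError("walking_speed and cadence must be positive")
        if not 0.5 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0.5, 1) for bipedal gait")
        if not 0.0 <= self.shuffle_residual < 0.5:
            raise ValueError("shuffle_residual must lie in [0, 0.5)")
        if self.noise_sd < 0 or self.sway_amplitude < 0 or self.apa_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")

    @classmethod
    def healthy(cls, **overrides) -> "GaitProfile":
        return cls(group="healthy", **overrides)

    @classmethod
    def patient(cls, **overrides) -> "GaitProfile":
        defaults = dict(
            group="patient",
            walking_speed=0.29,
            cadence=0.9,
            stance_fraction=0.68,
            shuffle_residual=0.20,
            weight_shift_gain=0.35,
            apa_amplitude=0.012,
            sway_amplitude=0.006,
            height=1.67,
            weight=68.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimTrial:
    """One simulated trial: the recording, truth labels, and event times.

    ``events`` holds the ground-truth walking start/stop in seconds (the
    commanded gait onset and the final foot-down); ``schedule`` exposes the
    step timing used by the generator so tests can replay its equations.
    """

    recording: GrfRecording
    truth: StateSeries
    events: dict
    profile: GaitProfile
    subject_id: str = "s00"
    trial_id: int = 0
    schedule: dict = field(default_factory=dict)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def stance_force_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized M-shaped stance GRF vs stance phase tau in [0, 1].

    Two raised bumps (loading response and push-off) over a smooth rise/fall
    envelope; zero exactly at tau = 0 and 1. Peak value ~1.11.
    """
    tau = np.asarray(tau, dtype=float)
    e = _smoothstep(tau / 0.28) * _smoothstep((1.0 - tau) / 0.28)
    m = (
        1.0
        - 0.25 * np.exp(-(((tau - 0.5) / 0.12) ** 2))
        + 0.12 * (np.exp(-(((tau - 0.28) / 0.1) ** 2)) + np.exp(-(((tau - 0.72) / 0.1) ** 2)))
    )
    return e * m


def shuffle_force_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized swing-phase shuffle bump: 0.5 * (1 - cos(2 pi tau))."""
    tau = np.asarray(tau, dtype=float)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def _interval_mask(t: np.ndarray, start: float, dur: float) -> np.ndarray:
    return (t >= start) & (t < start + dur)


def cop_progression(tau: np.ndarray, dwell: float = 0.14) -> np.ndarray:
    """Normalized heel->toe COP advance vs stance phase tau in [0, 1].

    Piecewise: a heel dwell during loading (the first ``dwell`` fraction of
    stance), a steady mid-stance advance, and a push-off roll over the last
    ``dwell`` fraction. When ``dwell`` equals the double-support fraction of
    stance, the leading foot dwells exactly while the trailing foot rolls
    off, and the roll span ``q = dwell / (1 - dwell)`` makes the advance
    rate of the COP-gradient uniform over the whole gait cycle — walking COP
    motion never pauses, which is what separates it from quiet standing.
    """
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    d = float(np.clip(dwell, 0.02, 0.45))
    q = d / (1.0 - d)
    mid = (tau - d) / (1.0 - 2.0 * d) * (1.0 - q)
    roll = (1.0 - q) + (tau - (1.0 - d)) / d * q
    f = np.where(tau < d, 0.0, np.where(tau < 1.0 - d, mid, roll))
    return np.clip(f, 0.0, 1.0)


def simulate_trial(
    profile: GaitProfile,
    stand_pre_s: float = 4.0,
    stand_post_s: float = 4.0,
    seed: int = 0,
    sampling_rate: float = 100.0,
    distance_m: float = 5.0,
    layout: SensorLayout | None = None,
    subject_id: str = "s00",
    trial_id: int = 0,
) -> SimTrial:
    """Simulate one stand -> walk 5 m -> stand trial.

    The left foot takes the first step. Steps repeat every ``1/cadence`` s;
    each stance lasts ``stance_fraction`` of the stride, so consecutive
    stances overlap in double support. Truth labels are walking from the
    commanded gait onset (end of the pre-standing segment) until the final
    foot-down.
    """
    if stand_pre_s <= 0 or stand_post_s <= 0:
        raise ValueError("standing durations must be positive")
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    layout = layout or SensorLayout.default()
    fs = sampling_rate
    rng = np.random.default_rng(seed)
    W = profile.weight * G

    t_step = 1.0 / profile.cadence
    stride = 2.0 * t_step
    stance_dur = profile.stance_fraction * stride
    swing_dur = stride - stance_dur
    step_len = profile.walking_speed * t_step
    n_steps = max(2, int(round(distance_m / step_len)))

    onset = stand_pre_s
    swing_starts = onset + t_step * np.arange(n_steps)
    strikes = swing_starts + swing_dur
    stop = float(strikes[-1])
    duration = stop + stand_post_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    feet = ["left", "right"]
    swing_foot = [feet[k % 2] for k in range(n_steps)]
    first_toeoff = {"left": onset, "right": onset + t_step}

    ph = rng.uniform(0.0, 2.0 * np.pi, size=12)
    is_patient = profile.group == "patient"

    # ---- per-foot force totals -------------------------------------------
    sway_load = 0.04 * W * np.sin(2.0 * np.pi * 0.25 * t + ph[0])
    base = {"left": W / 2.0 + sway_load, "right": W / 2.0 - sway_load}

    # APA: load transfer toward the first-swing (left) foot just before onset
    apa = np.sin(np.pi * np.clip((t - (onset - 0.4)) / 0.4, 0.0, 1.0)) ** 2
    apa[t >= onset] = 0.0
    base["left"] = base["left"] + 0.08 * W * apa
    base["right"] = base["right"] - 0.08 * W * apa

    # patient: exaggerated pre-onset weight shift to the unaffected (right) foot
    if profile.weight_shift_gain > 0:
        shift = (
            profile.weight_shift_gain
            * 0.25
            * W
            * _smoothstep((t - (onset - 0.6)) / 0.6)
        )
        shift[t >= onset] = 0.0
        base["right"] = base["right"] + shift
        base["left"] = np.maximum(base["left"] - shift, 0.0)

    # compensation: sole-support load on the right foot during the first step
    base["right"] = base["right"] + 0.5 * W * _smoothstep((t - onset) / 0.25)

    gate = {}
    for foot in feet:
        toe = first_toeoff[foot]
        g = np.clip(1.0 - _smoothstep((t - (toe - 0.12)) / 0.12), 0.0, 1.0)
        g = np.maximum(g, _smoothstep((t - stop) / 0.4))
        gate[foot] = g

    force = {}
    stances: dict[str, list[float]] = {"left": [], "right": []}
    swings: dict[str, list[float]] = {"left": [], "right": []}
    for k in range(n_steps):
        stances[swing_foot[k]].append(float(strikes[k]))
        swings[swing_foot[k]].append(float(swing_starts[k]))
    for foot in feet:
        walk = np.zeros(n)
        amp = 1.05 * W
        if is_patient and foot == "right":
            # unaffected side carries the exaggerated load
            amp *= 1.0 + 0.3 * profile.weight_shift_gain
        for s0 in stances[foot]:
            mask = _interval_mask(t, s0, stance_dur)
            walk[mask] += amp * stance_force_profile((t[mask] - s0) / stance_dur)
        f = np.maximum(gate[foot] * base[foot], walk)
        if profile.shuffle_residual > 0:
            for s0 in swings[foot]:
                mask = _interval_mask(t, s0, swing_dur)
                f[mask] += (
                    profile.shuffle_residual
                    * W
                    * shuffle_force_profile((t[mask] - s0) / swing_dur)
                )
        force[foot] = f

    # ---- per-foot load centres (drive the COP) ---------------------------
    heel_y = {f: float(layout.coords(f)[:, 1].min()) + 0.01 for f in feet}
    toe_y = {f: float(layout.coords(f)[:, 1].max()) - 0.01 for f in feet}
    cent = {f: layout.coords(f).mean(axis=0) for f in feet}

    y_stand = {}
    for i, foot in enumerate(feet):
        y = (
            cent[foot][1]
            + profile.sway_amplitude * np.sin(2.0 * np.pi * 0.3 * t + ph[1 + 2 * i])
            + 0.5 * profile.sway_amplitude * np.sin(2.0 * np.pi * 0.55 * t + ph[2 + 2 * i])
        )
        # post-stop settling wobble: the body keeps moving briefly after the
        # final foot-down, which sustains COP motion past the truth stop
        post = t >= stop
        y[post] += (
            0.006
            * np.exp(-(t[post] - stop) / 0.3)
            * np.sin(2.0 * np.pi * 1.8 * (t[post] - stop) + ph[5 + i])
        )
        y_stand[foot] = y
    # APA: swing-foot COP excursion toward the heel before onset
    y_stand["left"] = y_stand["left"] - profile.apa_amplitude * apa
    if is_patient:
        # loading-response COP advance on the unaffected foot during the shift
        pre = _smoothstep((t - (onset - 0.6)) / 0.6)
        pre[t >= onset] = 1.0
        y_stand["right"] = y_stand["right"] + (
            profile.apa_amplitude + 0.03 * profile.weight_shift_gain
        ) * pre * (t < stop)

    y_c = {f: y_stand[f].copy() for f in feet}
    # push-off roll of the stepping (left) foot: the heel rises and the COP
    # sweeps to the forefoot in the last ~150 ms before toe-off
    a0 = onset - 0.15
    mask = (t >= a0) & (t < onset)
    frac = (t[mask] - a0) / 0.15
    y_c["left"][mask] = y_stand["left"][mask] + frac * (
        toe_y["left"] - y_stand["left"][mask]
    )
    # initial support progression on the right foot while the left swings
    a0, b0 = onset - 0.15, first_toeoff["right"]
    mask = (t >= a0) & (t < b0)
    frac = (t[mask] - a0) / (b0 - a0)
    y_c["right"][mask] = cent["right"][1] + frac * (toe_y["right"] - cent["right"][1])
    for foot in feet:
        ds_frac = (stance_dur - t_step) / stance_dur  # double support / stance
        for s0 in stances[foot]:
            mask = _interval_mask(t, s0, stance_dur)
            frac = cop_progression((t[mask] - s0) / stance_dur, dwell=ds_frac)
            y_c[foot][mask] = heel_y[foot] + frac * (toe_y[foot] - heel_y[foot])
        for s0 in swings[foot]:
            # shuffling drags the forefoot
            mask = _interval_mask(t, s0, swing_dur)
            y_c[foot][mask] = 0.7 * toe_y[foot] + 0.3 * heel_y[foot]
        # balance-correction micro-motion of the loaded foot's COP while
        # walking; its amplitude scales with the COP roll rate so that it
        # textures the progression without ever stalling it
        walk_mask = (t >= onset) & (t < stop)
        roll_rate = (toe_y[foot] - heel_y[foot]) / stance_dur  # m/s
        tex = float(np.clip(roll_rate / 0.25, 0.4, 1.2))
        y_c[foot][walk_mask] += tex * (
            0.003 * np.sin(2.0 * np.pi * 2.3 * t[walk_mask] + ph[8 + feet.index(foot)])
            + 0.002 * np.sin(2.0 * np.pi * 3.1 * t[walk_mask] + ph[10 + feet.index(foot)])
        )
        # blend back to quiet standing after the final foot-down
        post = t >= stop
        if post.any():
            i0 = int(np.argmax(post))
            y_at_stop = y_c[foot][i0]
            w = _smoothstep((t[post] - stop) / 0.35)
            y_c[foot][post] = y_at_stop + w * (y_stand[foot][post] - y_at_stop)

    # ---- distribute foot totals over sensors -----------------------------
    # piecewise-linear interpolation between the two sensors bracketing the
    # load centre in the anterior-posterior direction, so the per-foot COP
    # tracks y_c exactly (up to noise)
    cols = []
    for foot in feet:
        coords = layout.coords(foot)
        order = np.argsort(coords[:, 1])
        ys = coords[order, 1]
        yc = np.clip(y_c[foot], ys[0], ys[-1])
        hi = np.clip(np.searchsorted(ys, yc), 1, len(ys) - 1)
        lo = hi - 1
        w_hi = (yc - ys[lo]) / (ys[hi] - ys[lo])
        wts = np.zeros((n, len(ys)))
        rows = np.arange(n)
        wts[rows, order[lo]] = 1.0 - w_hi
        wts[rows, order[hi]] = w_hi
        cols.append(force[foot][:, None] * wts)
    forces = np.hstack(cols)
    if profile.noise_sd > 0:
        forces = forces + rng.normal(0.0, profile.noise_sd, size=forces.shape)
    forces = np.clip(forces, 0.0, None)

    truth = StateSeries(
        sampling_rate=fs, states=((t >= onset) & (t < stop)).astype(np.int8)
    )
    recording = GrfRecording(
        sampling_rate=fs,
        forces=forces,
        layout=layout,
        subject=Subject(height=profile.height, weight=profile.weight, group=profile.group),
        trigger_marks=(0, n),
        meta={"subject_id": subject_id, "trial_id": trial_id, "seed": int(seed)},
    )
    return SimTrial(
        recording=recording,
        truth=truth,
        events={"start_s": float(onset), "stop_s": stop},
        profile=profile,
        subject_id=subject_id,
        trial_id=trial_id,
        schedule={
            "t_step": t_step,
            "stance_dur": stance_dur,
            "swing_dur": swing_dur,
            "n_steps": n_steps,
            "swing_starts": swing_starts.tolist(),
            "strikes": strikes.tolist(),
            "swing_feet": swing_foot,
        },
    )


def _draw_profile(group: str, rng: np.random.Generator) -> GaitProfile:
    """Subject-level parameter jitter around the group defaults."""
    if group == "healthy":
        if rng.random() < 19.0 / 28.0:  # male
            height = rng.normal(1.75, 0.06)
            weight = rng.normal(68.0, 7.0)
        else:
            height = rng.normal(1.61, 0.04)
            weight = rng.normal(51.0, 4.0)
        return GaitProfile.healthy(
            walking_speed=float(np.clip(rng.normal(0.83, 0.08), 0.4, 1.4)),
            cadence=float(np.clip(rng.normal(1.6, 0.12), 1.1, 2.2)),
            height=float(np.clip(height, 1.45, 2.0)),
            weight=float(np.clip(weight, 40.0, 110.0)),
        )
    if group == "patient":
        return GaitProfile.patient(
            walking_speed=float(np.clip(rng.normal(0.29, 0.06), 0.12, 0.6)),
            cadence=float(np.clip(rng.normal(0.9, 0.08), 0.6, 1.3)),
            stance_fraction=float(np.clip(rng.normal(0.68, 0.03), 0.6, 0.8)),
            shuffle_residual=float(np.clip(rng.normal(0.20, 0.04), 0.08, 0.45)),
            weight_shift_gain=float(np.clip(rng.normal(0.35, 0.08), 0.1, 0.8)),
            height=float(np.clip(rng.normal(1.67, 0.05), 1.45, 2.0)),
            weight=float(np.clip(rng.normal(68.0, 6.0), 40.0, 110.0)),
        )
    raise ValueError(f"unknown group {group!r}")


def simulate_cohort(
    n_subjects: int,
    n_trials_per_subject: int,
    group: str,
    seed: int,
    sampling_rate: float = 100.0,
    distance_m: float = 5.0,
    stand_range_s: tuple[float, float] = (3.0, 5.0),
    layout: SensorLayout | None = None,
) -> list[SimTrial]:
    """Simulate a cohort: per-subject anthropometric/speed jitter, per-trial seeds.

    Reproducible: the same arguments always produce bit-identical trials.
    """
    if n_subjects < 1 or n_trials_per_subject < 1:
        raise ValueError("cohort dimensions must be positive")
    root = np.random.SeedSequence(seed)
    trials: list[SimTrial] = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        prof = _draw_profile(group, rng)
        sid = f"{group[0]}{i:02d}"
        for j in range(n_trials_per_subject):
            t_seed = int(rng.integers(2**31))
            pre = float(rng.uniform(*stand_range_s))
            post = float(rng.uniform(*stand_range_s))
            trials.append(
                simulate_trial(
                    prof,
                    stand_pre_s=pre,
                    stand_post_s=post,
                    seed=t_seed,
                    sampling_rate=sampling_rate,
                    distance_m=distance_m,
                    layout=layout,
                    subject_id=sid,
                    trial_id=j,
                )
            )
    return trials
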