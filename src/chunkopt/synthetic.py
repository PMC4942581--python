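"""Synthetic multi-day joystick datasets with known chunking ground truth.

Emulates 1-kHz recordings of a 5-target centre-out-and-back sequence learned
over many daily sessions. Each trial executes a planted chunk structure:
within chunks the trace follows the structure's minimum-jerk model
trajectory, optionally blended with a less smooth trapezoidal-speed
per-element profile (the generator's one-parameter efficiency dial), with
dwell pauses inserted at HALT points and low-pass-filtered position noise
added. The default learning schedule emulates a cost-effective learner:
within-chunk efficiency improves first at near-constant chunk structure,
then chunks merge (HALT -> VIA drift), so efficiency rises before
complexity does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .chunking import ALL_HALT, ChunkStructure
from .kinematics import TrialKinematics
from .minjerk import SequenceGeometry, trajectory_for_structure

__all__ = [
    "DaySchedule",
    "GeneratorConfig",
    "GroundTruth",
    "default_schedule",
    "generate_trial",
    "generate_learning_dataset",
    "trapezoid_profile",
]


@dataclass(frozen=True)
class DaySchedule:
    """Per-day generator settings.

    noise_cm: std of the (low-pass-filtered) position noise.
    dwell_s: stationary pause inserted at each HALT point.
    suboptimality: blend weight in [0, 1] toward the trapezoidal profile.
    halt_to_via_prob: per-bit per-trial probability that a HALT of the
        persistent base structure melts into a VIA (chunk merging).
    via_to_halt_prob: small reverse drift.
    explore_prob: per-bit probability of a transient (non-inherited) flip,
        modelling trial-to-trial structure variability.
    """

    noise_cm: float = 0.02
    dwell_s: float = 0.1
    suboptimality: float = 0.0
    halt_to_via_prob: float = 0.0
    via_to_halt_prob: float = 0.0
    explore_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_cm < 0 or self.dwell_s < 0:
            raise ValueError("scales must be nonnegative")
        if not 0 <= self.suboptimality <= 1:
            raise ValueError("suboptimality must be in [0, 1]")
        for p in (self.halt_to_via_prob, self.via_to_halt_prob, self.explore_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def default_schedule(n_days: int, trials_per_day: int) -> tuple[DaySchedule, ...]:
    """Cost-effective (efficiency-first) learning schedule.

    First half of the days: within-chunk execution improves while the base
    structure barely changes — dwell pauses at halts shrink from 250 ms
    (reactive, cue-driven captures) to 50 ms (anticipatory), position noise
    shrinks, and the blend toward the trapezoidal profile decays. Second
    half: HALT bits melt into VIAs at a rate calibrated so the expected
    number of halts drops from 9 to about 1.5 by the final day, so
    complexity rises late. Exploration flips decay geometrically
    (0.03 -> 0.002), so the number of unique structures per day falls with
    learning while consecutive-trial Hamming distances stay small but
    nonzero.
    """
    if n_days < 1 or trials_per_day < 1:
        raise ValueError("n_days and trials_per_day must be >= 1")
    mid = max(2, n_days // 2)
    second_half_trials = max(1, (n_days - mid) * trials_per_day)
    p_hv = 1.0 - (1.5 / 9.0) ** (1.0 / second_half_trials)
    days = []
    for d in range(1, n_days + 1):
        frac_half = min(1.0, (d - 1) / max(1, mid - 1))
        frac_full = (d - 1) / max(1, n_days - 1)
        days.append(DaySchedule(
            noise_cm=0.02 - 0.015 * frac_full,
            dwell_s=0.25 - 0.20 * frac_half,
            suboptimality=0.3 * (1.0 - frac_half) + 0.02,
            halt_to_via_prob=0.0 if d <= mid else p_hv,
            via_to_halt_prob=0.0 if d <= mid else p_hv / 12.0,
            explore_prob=0.03 * (0.002 / 0.03) ** frac_full,
        ))
    return tuple(days)


@dataclass
class GeneratorConfig:
    geometry: SequenceGeometry = field(default_factory=SequenceGeometry)
    n_days: int = 20
    trials_per_day: int = 100
    sampling_hz: float = 1000.0
    schedule: tuple[DaySchedule, ...] | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = default_schedule(self.n_days, self.trials_per_day)
        if len(self.schedule) != self.n_days:
            raise ValueError("schedule length must equal n_days")


@dataclass
class GroundTruth:
    trial_id: int
    day: int
    structure: ChunkStructure
    element_times: np.ndarray


def trapezoid_profile(tau: np.ndarray, accel_frac: float = 0.1) -> np.ndarray:
    """Normalized path progress s(tau) of a trapezoidal-speed straight reach.

    Constant-acceleration ramps over the first/last ``accel_frac`` of the
    element, constant speed between; s(0)=0, s(1)=1. Less smooth than the
    minimum-jerk quintic: its acceleration is discontinuous, so its
    (smoothed, discretized) squared jerk is strictly larger.
    """
    a = accel_frac
    tau = np.asarray(tau, dtype=float)
    vmax = 1.0 / (1.0 - a)  # peak normalized speed so total progress is 1
    s = np.where(
        tau < a,
        0.5 * vmax * tau ** 2 / a,
        np.where(
            tau < 1.0 - a,
            0.5 * vmax * a + vmax * (tau - a),
            1.0 - 0.5 * vmax * (1.0 - tau) ** 2 / a,
        ),
    )
    return np.clip(s, 0.0, 1.0)


def _trapezoid_trace(geom: SequenceGeometry, t: np.ndarray) -> np.ndarray:
    """Full-sequence trace with per-element straight trapezoidal reaches."""
    pts = geom.target_xy
    el = geom.element_duration_s
    idx = np.clip((t / el).astype(int), 0, geom.n_elements - 1)
    tau = t / el - idx
    s = trapezoid_profile(tau)
    a = pts[idx]
    b = pts[idx + 1]
    return a + s[:, None] * (b - a)


def _lowpass_noise(rng: np.random.Generator, n: int, scale: float,
                   fs: float, cutoff_hz: float = 5.0) -> np.ndarray:
    """Gaussian position noise low-pass filtered and rescaled to std ``scale``."""
    if scale <= 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, raw)
    sd = smooth.std()
    return smooth * (scale / sd) if sd > 0 else np.zeros(n)


def generate_trial(
    structure: ChunkStructure,
    cfg: GeneratorConfig,
    day_params: DaySchedule,
    rng: np.random.Generator,
    trial_id: int = 0,
    day: int = 1,
) -> tuple[TrialKinematics, GroundTruth]:
    """One trial executing ``structure`` under the day's noise settings."""
    geom = cfg.geometry
    fs = cfg.sampling_hz
    model = trajectory_for_structure(structure, geom, sampling_hz=fs)
    pos = np.column_stack([model.x, model.y])
    w = day_params.suboptimality
    if w > 0:
        pos = (1.0 - w) * pos + w * _trapezoid_trace(geom, model.t)

    # insert dwell pauses at HALT boundaries (trial lengthens; downstream
    # duration normalization removes the duration effect, as in the pipeline)
    n_dwell = int(round(day_params.dwell_s * fs))
    el_samples = int(round(geom.element_duration_s * fs))
    chunks_x, chunks_y = [pos[:1, 0]], [pos[:1, 1]]
    capture = np.zeros(geom.n_elements)
    shift = 0.0
    for e in range(1, geom.n_elements + 1):
        lo, hi = (e - 1) * el_samples + 1, e * el_samples + 1
        chunks_x.append(pos[lo:hi, 0])
        chunks_y.append(pos[lo:hi, 1])
        capture[e - 1] = e * geom.element_duration_s + shift
        if e < geom.n_elements and structure.bits[e - 1] and n_dwell > 0:
            chunks_x.append(np.full(n_dwell, pos[hi - 1, 0]))
            chunks_y.append(np.full(n_dwell, pos[hi - 1, 1]))
            shift += n_dwell / fs
    x = np.concatenate(chunks_x)
    y = np.concatenate(chunks_y)
    t = np.arange(x.size) / fs
    x = x + _lowpass_noise(rng, x.size, day_params.noise_cm, fs)
    y = y + _lowpass_noise(rng, y.size, day_params.noise_cm, fs)
    trial = TrialKinematics(trial_id=trial_id, day=day, t=t, x=x, y=y,
                            capture_times=capture)
    truth = GroundTruth(trial_id=trial_id, day=day, structure=structure,
                        element_times=capture.copy())
    return trial, truth


def _evolve_bits(bits: tuple[int, ...], p_hv: float, p_vh: float,
                 rng: np.random.Generator) -> tuple[int, ...]:
    out = []
    for b in bits:
        u = rng.random()
        if b == 1 and u < p_hv:
            out.append(0)
        elif b == 0 and u < p_vh:
            out.append(1)
        else:
            out.append(b)
    return tuple(out)


def generate_learning_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[TrialKinematics], list[GroundTruth]]:
    """Multi-day dataset with a drifting base structure plus exploration.

    The persistent base structure starts at ALL-HALT and evolves by
    Markov bit flips (HALT -> VIA drift with a small reverse rate); the
    structure actually executed on a trial additionally carries transient
    exploration flips that are not inherited. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    base = ALL_HALT.bits if cfg.geometry.n_elements == 10 else \
        (1,) * (cfg.geometry.n_elements - 1)
    trials: list[TrialKinematics] = []
    truths: list[GroundTruth] = []
    trial_id = 0
    for day in range(1, cfg.n_days + 1):
        day_params = cfg.schedule[day - 1]
        for _ in range(cfg.trials_per_day):
            base = _evolve_bits(base, day_params.halt_to_via_prob,
                                day_params.via_to_halt_prob, rng)
            executed = tuple(
                1 - b if rng.random() < day_params.explore_prob else b
                for b in base
            )
            structure = ChunkStructure(cfg.geometry.n_elements, executed)
            tr, gt = generate_trial(structure, cfg, day_params, rng,
                                    trial_id=trial_id, day=day)
            trials.append(tr)
            truths.append(gt)
            trial_id += 1
    return trials, truths
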