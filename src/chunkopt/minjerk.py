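"""Minimum-jerk via-point trajectories and per-structure model trajectories.

Within a chunk the hand is modelled as the trajectory minimizing the
integrated squared jerk subject to (i) interpolating every target point at
its scheduled time, and (ii) rest-to-rest boundary conditions (zero velocity
and zero acceleration) at the chunk ends. By the Euler-Lagrange condition
(x^(6) = 0 between knots) the minimizer is a piecewise-quintic polynomial
that is C4-continuous at interior via points, which yields a square linear
system in the per-segment quintic coefficients — no iterative optimizer is
needed. A full-sequence model trajectory for a chunk structure is the
concatenation of independently solved chunks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from . import kinematics as kin
from .chunking import ChunkStructure, complexity as structure_complexity
from .kinematics import TrialKinematics

__all__ = [
    "SequenceGeometry",
    "PiecewiseQuintic",
    "ModelTrajectory",
    "minimum_jerk_chunk",
    "trajectory_for_structure",
    "fit_model_to_trial",
    "goodness_of_fit",
    "straight_reach_integrated_jerk",
]

#: outer-target angles are not constrained by the task design we emulate;
#: these defaults spread the five targets roughly evenly around the circle.
DEFAULT_OUTER_ANGLES_DEG = (90.0, 162.0, 234.0, 306.0, 18.0)


@dataclass(frozen=True)
class SequenceGeometry:
    """Scheduled geometry of the 5-target centre-out-and-back sequence.

    The hand starts at the centre (origin), visits each outer target
    (``radius_cm`` from the centre) and returns, giving 10 elemental reaches
    through 11 scheduled points, each element lasting ``element_duration_s``.
    """

    radius_cm: float = 7.0
    element_duration_s: float = 0.5
    outer_angles_deg: tuple[float, ...] = DEFAULT_OUTER_ANGLES_DEG

    def __post_init__(self) -> None:
        if self.radius_cm <= 0 or self.element_duration_s <= 0:
            raise ValueError("radius and element duration must be positive")
        if len(self.outer_angles_deg) != 5:
            raise ValueError("need exactly 5 outer-target angles")

    @property
    def n_elements(self) -> int:
        return 10

    @property
    def target_xy(self) -> np.ndarray:
        """(11, 2) scheduled points: centre, out1, centre, ..., out5, centre."""
        pts = [(0.0, 0.0)]
        for ang in self.outer_angles_deg:
            rad = math.radians(ang)
            pts.append((self.radius_cm * math.cos(rad), self.radius_cm * math.sin(rad)))
            pts.append((0.0, 0.0))
        return np.asarray(pts)

    @property
    def schedule_times(self) -> np.ndarray:
        return np.arange(self.n_elements + 1) * self.element_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.n_elements * self.element_duration_s


# ----------------------------------------------------------------------
# piecewise quintic representation
# ----------------------------------------------------------------------

def _basis_row(k: int, tau: float) -> np.ndarray:
    """d^k/dtau^k of the monomial basis (1, tau, .., tau^5) at tau."""
    row = np.zeros(6)
    for p in range(k, 6):
        c = math.perm(p, k)
        row[p] = c * tau ** (p - k)
    return row


@dataclass
class PiecewiseQuintic:
    """2-D piecewise-quintic curve on knots ``times``.

    ``coeffs[s, p, d]`` is the coefficient of tau^p for segment ``s`` and
    dimension ``d``, with local time tau = (t - times[s]) / h_s in [0, 1].
    """

    times: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.times.size - 1, 6, 2):
            raise ValueError("coeffs must have shape (n_segments, 6, 2)")

    def __call__(self, t, der: int = 0) -> np.ndarray:
        """Evaluate the curve (or its ``der``-th time derivative): (n, 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        seg = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0,
                      self.times.size - 2)
        h = np.diff(self.times)[seg]
        tau = (t - self.times[seg]) / h
        out = np.zeros((t.size, 2))
        # Horner on the differentiated polynomial
        for p in range(5, der - 1, -1):
            c = math.perm(p, der)
            out = out * tau[:, None] + c * self.coeffs[seg, p, :]
        return out / (h ** der)[:, None]

    def integrated_squared_jerk(self) -> float:
        """Exact integral of squared jerk over the curve's full duration."""
        total = 0.0
        h = np.diff(self.times)
        for s in range(h.size):
            for d in range(2):
                # jerk in tau: q(tau) = 6 c3 + 24 c4 tau + 60 c5 tau^2
                q = np.polynomial.Polynomial(
                    [6 * self.coeffs[s, 3, d],
                     24 * self.coeffs[s, 4, d],
                     60 * self.coeffs[s, 5, d]]
                )
                total += (q ** 2).integ()(1.0) / h[s] ** 5
        return float(total)


def minimum_jerk_chunk(points, times) -> PiecewiseQuintic:
    """Solve one chunk's minimum-jerk via-point problem.

    Parameters
    ----------
    points : (m, 2) array
        Points the hand must traverse, in order.
    times : (m,) strictly increasing array
        Scheduled passage times.

    The ends are rest-to-rest (zero velocity and acceleration); interior
    points are via points with position-only constraints, where optimality
    imposes continuity of derivatives 1-4.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    times = np.asarray(times, dtype=float)
    m = times.size
    if m < 2 or points.shape[0] != m:
        raise ValueError("need >= 2 points with matching times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    nseg = m - 1
    h = np.diff(times)
    n = 6 * nseg
    A = np.zeros((n, n))
    B = np.zeros((n, 2))
    r = 0

    def sl(s):
        return slice(6 * s, 6 * s + 6)

    # interpolation at both ends of every segment
    for s in range(nseg):
        A[r, sl(s)] = _basis_row(0, 0.0)
        B[r] = points[s]
        r += 1
        A[r, sl(s)] = _basis_row(0, 1.0)
        B[r] = points[s + 1]
        r += 1
    # rest-to-rest chunk ends
    for k in (1, 2):
        A[r, sl(0)] = _basis_row(k, 0.0)
        r += 1
        A[r, sl(nseg - 1)] = _basis_row(k, 1.0)
        r += 1
    # C1..C4 continuity at interior via points
    for s in range(nseg - 1):
        for k in range(1, 5):
            A[r, sl(s)] = _basis_row(k, 1.0) / h[s] ** k
            A[r, sl(s + 1)] = -_basis_row(k, 0.0) / h[s + 1] ** k
            r += 1
    assert r == n
    try:
        C = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate input
        raise ValueError(f"singular via-point system: {err}") from err
    return PiecewiseQuintic(times=times, coeffs=C.reshape(nseg, 6, 2))


def straight_reach_integrated_jerk(distance: float, duration: float) -> float:
    """Closed-form minimum cost of a rest-to-rest straight reach: 720 D^2/T^5."""
    return 720.0 * distance ** 2 / duration ** 5


# ----------------------------------------------------------------------
# model trajectories for chunk structures
# ----------------------------------------------------------------------

@dataclass
class ModelTrajectory:
    """Concatenated per-chunk minimum-jerk fit for one chunk structure."""

    structure: ChunkStructure
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    efficiency: float
    complexity: float
    integrated_squared_jerk: float
    pieces: list[PiecewiseQuintic] = field(repr=False, default_factory=list)

    def as_trial(self, trial_id: int = -1, day: int = 0) -> TrialKinematics:
        return TrialKinematics(trial_id=trial_id, day=day, t=self.t,
                               x=self.x, y=self.y)

    def speed(self) -> np.ndarray:
        """Exact model speed on the sample grid (from the quintic pieces)."""
        v = np.full(self.t.size, np.nan)
        for piece in self.pieces:
            mask = (self.t >= piece.times[0] - 1e-12) & (self.t <= piece.times[-1] + 1e-12)
            vel = piece(self.t[mask], der=1)
            v[mask] = np.hypot(vel[:, 0], vel[:, 1])
        return v


def _chunk_slices(structure: ChunkStructure) -> list[tuple[int, int]]:
    """Point-index ranges [i, j] of each chunk over the n+1 scheduled points."""
    halts = [0] + [i + 1 for i, b in enumerate(structure.bits) if b] + [structure.n_elements]
    return [(halts[k], halts[k + 1]) for k in range(len(halts) - 1)]


def _solve_pieces(structure: ChunkStructure, points: np.ndarray,
                  times: np.ndarray) -> list[PiecewiseQuintic]:
    pieces = []
    for i, j in _chunk_slices(structure):
        pieces.append(minimum_jerk_chunk(points[i:j + 1], times[i:j + 1]))
    return pieces


def _sample_pieces(pieces: list[PiecewiseQuintic], t: np.ndarray) -> np.ndarray:
    pos = np.zeros((t.size, 2))
    filled = np.zeros(t.size, dtype=bool)
    for piece in pieces:
        mask = (t >= piece.times[0] - 1e-12) & (t <= piece.times[-1] + 1e-12) & ~filled
        pos[mask] = piece(t[mask])
        filled |= mask
    return pos


@lru_cache(maxsize=2048)
def trajectory_for_structure(
    structure: ChunkStructure,
    geom: SequenceGeometry = SequenceGeometry(),
    sampling_hz: float = 1000.0,
) -> ModelTrajectory:
    """Locally optimal model trajectory for one chunk structure.

    Chunks (maximal runs between HALT boundaries) are solved independently
    and concatenated; efficiency is the negative normalized squared jerk of
    the sampled 5-s trace and complexity the structure's log-sum-exp of
    chunk lengths. Results are cached (structures are reused heavily when
    scanning the 512-structure landscape); treat the returned object as
    read-only.
    """
    if structure.n_elements != geom.n_elements:
        raise ValueError("structure and geometry disagree on n_elements")
    points = geom.target_xy
    times = geom.schedule_times
    pieces = _solve_pieces(structure, points, times)
    n = int(round(geom.total_duration_s * sampling_hz)) + 1
    t = np.linspace(0.0, geom.total_duration_s, n)
    pos = _sample_pieces(pieces, t)
    trial = TrialKinematics(trial_id=-1, day=0, t=t, x=pos[:, 0], y=pos[:, 1])
    eff = kin.efficiency(trial, target_s=geom.total_duration_s)
    isj = sum(p.integrated_squared_jerk() for p in pieces)
    return ModelTrajectory(
        structure=structure, t=t, x=pos[:, 0], y=pos[:, 1],
        efficiency=eff, complexity=structure_complexity(structure),
        integrated_squared_jerk=float(isj), pieces=pieces,
    )


def fit_model_to_trial(
    traj: TrialKinematics,
    detection,
    geom: SequenceGeometry = SequenceGeometry(),
) -> ModelTrajectory:
    """Minimum-jerk model for a trial, using its detected chunk structure.

    The trial should be duration-normalized. Via/halt passage times are the
    trial's own capture times when present (rescaled with the trial),
    otherwise the scheduled uniform times.
    """
    structure = detection.structure if hasattr(detection, "structure") else detection
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    if traj.capture_times is not None and np.all(np.diff(traj.capture_times) > 0) \
            and traj.capture_times[0] > t0:
        times = np.concatenate(([t0], traj.capture_times))
    else:
        times = t0 + (t1 - t0) * np.linspace(0.0, 1.0, geom.n_elements + 1)
    pieces = _solve_pieces(structure, geom.target_xy, times)
    pos = _sample_pieces(pieces, traj.t)
    trial = TrialKinematics(trial_id=traj.trial_id, day=traj.day,
                            t=traj.t, x=pos[:, 0], y=pos[:, 1])
    eff = kin.efficiency(trial, target_s=t1 - t0)
    return ModelTrajectory(
        structure=structure, t=traj.t.copy(), x=pos[:, 0], y=pos[:, 1],
        efficiency=eff, complexity=structure_complexity(structure),
        integrated_squared_jerk=float(sum(p.integrated_squared_jerk() for p in pieces)),
        pieces=pieces,
    )


def goodness_of_fit(model: ModelTrajectory, traj: TrialKinematics) -> float:
    """Pearson correlation between model and data speed profiles."""
    data_speed = kin.compute_speed(kin.smooth_positions(traj)).v
    model_trial = model.as_trial()
    if model_trial.t.size != traj.t.size or not np.allclose(model_trial.t, traj.t):
        pos = _sample_pieces(model.pieces, traj.t)
        model_trial = TrialKinematics(trial_id=-1, day=0, t=traj.t,
                                      x=pos[:, 0], y=pos[:, 1])
    model_speed = kin.compute_speed(kin.smooth_positions(model_trial)).v
    if np.std(data_speed) == 0 or np.std(model_speed) == 0:
        raise ValueError("goodness of fit undefined for zero-variance speed")
    r, _ = stats.pearsonr(model_speed, data_speed)
    return float(r)
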