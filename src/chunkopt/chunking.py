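"""Chunk structures of a reach sequence and their combinatorics.

A 10-element sequence has 9 internal target crossings, each of which is
either a HALT (the hand stops: a chunk boundary) or a VIA point (traversed
in flight). A chunk structure is therefore a 9-bit vector; 2^9 = 512
structures exist. The planning cost of a chunk grows exponentially with its
length, so the de-novo computational complexity of a structure with chunk
lengths M_1..M_k is log(sum_j exp(M_j)) — an effective planning horizon in
units of chunk length (single 10-element chunk -> 10; ten 1-element chunks
-> 1 + ln 10).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .kinematics import SpeedProfile

__all__ = [
    "ChunkStructure",
    "BoundaryDetection",
    "enumerate_structures",
    "complexity",
    "hamming",
    "degenerate_sets",
    "detect_chunk_boundaries",
    "ALL_HALT",
    "ALL_VIA",
]


@dataclass(frozen=True)
class ChunkStructure:
    """HALT/VIA assignment for the internal boundaries of a sequence.

    ``bits[i] == 1`` means the hand halts after element ``i + 1``.
    """

    n_elements: int
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if len(self.bits) != self.n_elements - 1:
            raise ValueError("need n_elements - 1 boundary bits")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 (VIA) or 1 (HALT)")
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))

    # -- constructors -------------------------------------------------
    @classmethod
    def from_bitstring(cls, s: str, n_elements: int | None = None) -> "ChunkStructure":
        bits = tuple(int(c) for c in s.strip())
        return cls(n_elements=n_elements or len(bits) + 1, bits=bits)

    @classmethod
    def from_lengths(cls, lengths, n_elements: int | None = None) -> "ChunkStructure":
        """Build from ordered chunk lengths, e.g. (3, 2, 3, 2) or "3-2-3-2"."""
        if isinstance(lengths, str):
            lengths = [int(p) for p in lengths.split("-")]
        lengths = [int(m) for m in lengths]
        if any(m < 1 for m in lengths):
            raise ValueError("chunk lengths must be positive")
        n = sum(lengths)
        if n_elements is not None and n_elements != n:
            raise ValueError("chunk lengths must sum to n_elements")
        bits = []
        for m in lengths[:-1]:
            bits.extend([0] * (m - 1) + [1])
        bits.extend([0] * (lengths[-1] - 1))
        return cls(n_elements=n, bits=tuple(bits))

    # -- views --------------------------------------------------------
    @property
    def chunk_lengths(self) -> tuple[int, ...]:
        lengths, run = [], 1
        for b in self.bits:
            if b:
                lengths.append(run)
                run = 1
            else:
                run += 1
        lengths.append(run)
        return tuple(lengths)

    @property
    def n_chunks(self) -> int:
        return sum(self.bits) + 1

    @property
    def signature(self) -> tuple[int, ...]:
        """Degenerate-set label: chunk lengths as a sorted-descending multiset."""
        return tuple(sorted(self.chunk_lengths, reverse=True))

    def to_bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    def to_lengths_string(self) -> str:
        return "-".join(str(m) for m in self.chunk_lengths)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.to_lengths_string()} [{self.to_bitstring()}]"


ALL_HALT = ChunkStructure(10, (1,) * 9)
ALL_VIA = ChunkStructure(10, (0,) * 9)


def enumerate_structures(n_elements: int) -> list[ChunkStructure]:
    """All 2^(n-1) chunk structures in deterministic binary-counting order."""
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    out = []
    for bits in itertools.product((0, 1), repeat=n_elements - 1):
        out.append(ChunkStructure(n_elements, bits))
    return out


def complexity(structure: ChunkStructure) -> float:
    """De-novo planning cost: log-sum-exp of chunk lengths.

    Permutation-invariant in the chunk lengths and strictly increased by
    merging any two adjacent chunks.
    """
    return float(logsumexp(np.asarray(structure.chunk_lengths, dtype=float)))


def hamming(s1: ChunkStructure, s2: ChunkStructure) -> int:
    """Number of boundary bits on which two structures differ."""
    if s1.n_elements != s2.n_elements:
        raise ValueError("structures must share n_elements")
    return sum(a != b for a, b in zip(s1.bits, s2.bits))


def degenerate_sets(
    n_elements: int,
) -> dict[tuple[int, ...], list[ChunkStructure]]:
    """Group all structures by signature (identical-complexity classes).

    The number of groups equals the number of integer partitions of
    ``n_elements`` (42 for the 10-element task).
    """
    groups: dict[tuple[int, ...], list[ChunkStructure]] = {}
    for s in enumerate_structures(n_elements):
        groups.setdefault(s.signature, []).append(s)
    return groups


# ----------------------------------------------------------------------
# boundary detection
# ----------------------------------------------------------------------

@dataclass
class BoundaryDetection:
    """Result of speed-based HALT detection for one trial."""

    structure: ChunkStructure
    halt_times: np.ndarray
    min_frac: float
    max_frac: float
    min_halt_ms: float = 25.0


def _run_compressed_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima/maxima indices; plateaus collapse to their first sample."""
    # compress runs of equal consecutive values
    change = np.flatnonzero(np.diff(v) != 0)
    run_starts = np.concatenate(([0], change + 1))
    rv = v[run_starts]
    minima, maxima = [], []
    for k in range(1, rv.size - 1):
        if rv[k] < rv[k - 1] and rv[k] < rv[k + 1]:
            minima.append(run_starts[k])
        elif rv[k] > rv[k - 1] and rv[k] > rv[k + 1]:
            maxima.append(run_starts[k])
    return np.asarray(minima, dtype=int), np.asarray(maxima, dtype=int)


def detect_chunk_boundaries(
    speed: SpeedProfile,
    element_times,
    min_frac: float = 0.05,
    max_frac: float = 0.25,
    n_elements: int = 10,
    min_halt_ms: float = 25.0,
) -> BoundaryDetection:
    """Infer the trial's chunk structure from its speed profile.

    HALT candidates are interior local minima below ``min_frac`` of the
    trial's peak speed; between each consecutive pair of local maxima
    exceeding ``max_frac`` of peak, only the lowest candidate is retained.
    Each retained minimum is then assigned to the nearest internal element
    boundary (element completion times 1..n-1); ambiguous ties go to the
    earlier boundary.

    A candidate only qualifies as a halt if the speed stays below threshold
    for at least ``min_halt_ms``: a genuine halt involves a dwell at (or a
    rest-to-rest passage through) the target, whereas a fly-through whose
    path momentarily reverses (an out-and-back via point) crosses zero speed
    only instantaneously. Set ``min_halt_ms=0`` to recover the bare
    threshold rule.
    """
    v = np.asarray(speed.v, dtype=float)
    t = np.asarray(speed.t, dtype=float)
    peak = float(v.max(initial=0.0))
    if peak <= 0:
        raise ValueError("all-zero speed profile")
    element_times = np.asarray(element_times, dtype=float)
    if element_times.size != n_elements:
        raise ValueError(f"need {n_elements} element completion times")
    boundary_times = element_times[:-1]  # internal boundaries only

    minima, maxima = _run_compressed_extrema(v)
    cand = minima[v[minima] < min_frac * peak]
    big_max = maxima[v[maxima] > max_frac * peak]

    if min_halt_ms > 0 and cand.size:
        below = v < min_frac * peak
        # contiguous below-threshold run length (in time) around each candidate
        edges = np.flatnonzero(np.diff(below.astype(int)))
        starts = np.concatenate(([0], edges + 1))
        run_id = np.cumsum(np.concatenate(([0], np.diff(below.astype(int)) != 0)))
        keep = []
        for idx in cand:
            rid = run_id[idx]
            members = np.flatnonzero(run_id == rid)
            dur_s = t[members[-1]] - t[members[0]]
            if dur_s * 1000.0 >= min_halt_ms:
                keep.append(idx)
        cand = np.asarray(keep, dtype=int)

    # partition candidates by the big maxima; keep the lowest per region
    edges = np.concatenate(([-1], big_max, [v.size]))
    retained = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = cand[(cand > lo) & (cand < hi)]
        if seg.size:
            retained.append(seg[np.argmin(v[seg])])
    retained = np.asarray(sorted(retained), dtype=int)

    # assignment knots: sequence start, the 9 internal boundaries, sequence
    # end; minima nearest the start/end belong to the rest phases bracketing
    # the sequence, not to an internal boundary
    knots = np.concatenate(([t[0]], boundary_times, [element_times[-1]]))
    bits = [0] * (n_elements - 1)
    halt_times = []
    for idx in retained:
        j = int(np.argmin(np.abs(knots - t[idx])))  # earlier knot wins ties
        if j == 0 or j == knots.size - 1:
            continue
        if bits[j - 1] == 0:
            bits[j - 1] = 1
            halt_times.append(float(t[idx]))
    structure = ChunkStructure(n_elements, tuple(bits))
    return BoundaryDetection(
        structure=structure,
        halt_times=np.asarray(sorted(halt_times)),
        min_frac=min_frac,
        max_frac=max_frac,
        min_halt_ms=min_halt_ms,
    )
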