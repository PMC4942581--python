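"""Efficiency-computation trade-off landscape and its Pareto frontier.

Every chunk structure maps to one (complexity, efficiency) point: the
de-novo planning cost and the best efficiency attainable under that
structure's locally optimal trajectory. The Pareto frontier is the convex
upper envelope of the landscape; the staircase of merely nondominated
points is also exposed since the two differ at non-hull-vertex points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chunking import ChunkStructure, enumerate_structures
from .minjerk import SequenceGeometry, trajectory_for_structure

__all__ = [
    "TradeoffPoint",
    "ParetoFrontier",
    "tradeoff_landscape",
    "pareto_frontier",
    "nondominated",
    "landscape_table",
]


@dataclass(frozen=True)
class TradeoffPoint:
    structure: ChunkStructure
    complexity: float
    efficiency: float


@dataclass
class ParetoFrontier:
    """Convex upper envelope of the trade-off landscape, sorted by complexity."""

    points: list[TradeoffPoint]

    @property
    def complexities(self) -> np.ndarray:
        return np.asarray([p.complexity for p in self.points])

    @property
    def efficiencies(self) -> np.ndarray:
        return np.asarray([p.efficiency for p in self.points])

    def envelope(self, complexity: np.ndarray) -> np.ndarray:
        """Piecewise-linear frontier efficiency at the given complexities."""
        return np.interp(complexity, self.complexities, self.efficiencies)


def tradeoff_landscape(
    geom: SequenceGeometry = SequenceGeometry(),
) -> list[TradeoffPoint]:
    """One trade-off point per chunk structure (512 for the 10-element task)."""
    out = []
    for s in enumerate_structures(geom.n_elements):
        m = trajectory_for_structure(s, geom)
        out.append(TradeoffPoint(structure=s, complexity=m.complexity,
                                 efficiency=m.efficiency))
    return out


def nondominated(points: list[TradeoffPoint]) -> list[TradeoffPoint]:
    """Staircase of Pareto-nondominated points (no point is at least as good
    on both objectives and strictly better on one)."""
    out = []
    for p in points:
        dominated = any(
            (q.complexity <= p.complexity and q.efficiency >= p.efficiency)
            and (q.complexity < p.complexity or q.efficiency > p.efficiency)
            for q in points
        )
        if not dominated:
            out.append(p)
    return sorted(out, key=lambda p: (p.complexity, p.efficiency))


def pareto_frontier(points: list[TradeoffPoint]) -> ParetoFrontier:
    """Convex upper envelope restricted to nondominated points.

    Computed with a monotone-chain upper hull over (complexity, efficiency);
    hull vertices that are themselves dominated (possible at the low-
    complexity end when efficiency dips) are pruned so the frontier has
    strictly increasing complexity and nondecreasing efficiency.
    """
    if not points:
        raise ValueError("need at least one trade-off point")
    frontier_candidates = nondominated(points)
    pts = sorted(points, key=lambda p: (p.complexity, -p.efficiency))
    # keep one point (the most efficient) per distinct complexity
    dedup: list[TradeoffPoint] = []
    for p in pts:
        if dedup and np.isclose(p.complexity, dedup[-1].complexity):
            continue
        dedup.append(p)
    hull: list[TradeoffPoint] = []
    for p in dedup:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = (hull[-2].complexity, hull[-2].efficiency), \
                (hull[-1].complexity, hull[-1].efficiency)
            # drop hull[-1] if it lies on or below chord hull[-2] -> p
            if (x2 - x1) * (p.efficiency - y1) >= (p.complexity - x1) * (y2 - y1):
                hull.pop()
            else:
                break
        hull.append(p)
    keep = {id(p) for p in frontier_candidates}
    nd_keys = {(p.complexity, p.efficiency, p.structure) for p in frontier_candidates}
    hull = [p for p in hull
            if id(p) in keep or (p.complexity, p.efficiency, p.structure) in nd_keys]
    return ParetoFrontier(points=hull)


def landscape_table(points: list[TradeoffPoint],
                    frontier: ParetoFrontier | None = None) -> pd.DataFrame:
    """Tabular view: structure bitstring/lengths, complexity, efficiency."""
    rows = []
    on_frontier = set()
    if frontier is not None:
        on_frontier = {p.structure for p in frontier.points}
    for p in points:
        rows.append({
            "structure": p.structure.to_bitstring(),
            "chunk_lengths": p.structure.to_lengths_string(),
            "n_chunks": p.structure.n_chunks,
            "complexity": p.complexity,
            "efficiency": p.efficiency,
            "on_frontier": p.structure in on_frontier,
        })
    return pd.DataFrame(rows)
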