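"""Two-phase topological partition of a trained map into gene clusters.

Phase one locates *seed units*: local minima of the per-unit mean
codebook distance to lattice neighbors (the U-height).  A low U-height
marks a unit sitting inside a homogeneous region of the map, so seeds are
the interiors of natural expression-pattern domains — no cluster count or
shape is assumed up front.  Phase two grows clusters outward over the
lattice: the unassigned unit that is lattice-adjacent to an existing
cluster and closest (in codebook space) to that cluster's seed codebook is
attached, one unit at a time, until the map is covered.  Transcripts then
inherit the cluster of their best-matching unit, and each cluster is
summarized by its seed unit's codebook — the cluster's representative
expression pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .som import BMUMap, SOMGrid

__all__ = [
    "ClusterPartition",
    "neighbor_distance",
    "find_seeds",
    "merge_closest_seeds",
    "partition",
    "cluster_sizes",
]


@dataclass(frozen=True)
class ClusterPartition:
    """Unit- and gene-level cluster assignments with one seed unit per cluster.

    Clusters are numbered 1..K in seed-unit index order.
    """

    n_clusters: int
    unit_cluster: np.ndarray  # (n_units,) int, values in 1..K
    seed_units: dict[int, int]  # cluster ID -> unit index
    gene_cluster: dict[str, int]  # transcript ID -> cluster ID
    seed_profiles: dict[int, np.ndarray]  # cluster ID -> codebook vector

    def __post_init__(self) -> None:
        uc = np.asarray(self.unit_cluster, dtype=int)
        object.__setattr__(self, "unit_cluster", uc)
        if sorted(self.seed_units) != list(range(1, self.n_clusters + 1)):
            raise ValueError("seed_units must cover cluster IDs 1..K exactly")
        if uc.min() < 1 or uc.max() > self.n_clusters:
            raise ValueError("unit_cluster values must lie in 1..K")
        for k, u in self.seed_units.items():
            if uc[u] != k:
                raise ValueError(f"seed unit {u} is not assigned to its own cluster {k}")

    def cluster_table(self, bmu: BMUMap) -> pd.DataFrame:
        rows = [
            {"transcript_id": tid, "cluster": self.gene_cluster[tid], "unit": bmu.assignment[tid]}
            for tid in sorted(self.gene_cluster)
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "cluster", "unit"])

    def seed_profile_table(self, stage_labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        n_stages = len(next(iter(self.seed_profiles.values())))
        labels = list(stage_labels) if stage_labels else [f"stage_{i+1}" for i in range(n_stages)]
        rows = []
        for k in range(1, self.n_clusters + 1):
            row: dict[str, object] = {"cluster": k, "seed_unit": self.seed_units[k]}
            row.update({f"v_{lab}": v for lab, v in zip(labels, self.seed_profiles[k])})
            rows.append(row)
        return pd.DataFrame(rows)


def neighbor_distance(grid: SOMGrid) -> np.ndarray:
    """U-height per unit: mean codebook distance to immediate lattice neighbors.

    Boundary units average over the neighbors they have; a single-unit grid
    gets height 0 by convention.
    """
    if not grid.trained:
        raise ValueError("grid must be trained before computing neighbor distances")
    heights = np.zeros(grid.n_units)
    for u, nbrs in enumerate(grid.neighbor_lists()):
        if len(nbrs):
            diffs = grid.codebook[nbrs] - grid.codebook[u]
            heights[u] = float(np.linalg.norm(diffs, axis=1).mean())
    return heights


def find_seeds(grid: SOMGrid, heights: np.ndarray) -> list[int]:
    """Local minima of the U-height surface, one seed per equal-height plateau.

    A unit is a candidate when its height is <= every lattice neighbor's.
    Candidates that are mutually adjacent with exactly equal heights form a
    plateau and collapse to their lowest-index member, so degenerate (flat)
    maps yield a single seed rather than one per unit.  Seeds are returned
    in increasing unit-index order.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.shape != (grid.n_units,):
        raise ValueError(
            f"heights length {heights.shape} does not match {grid.n_units} units"
        )
    neighbor_lists = grid.neighbor_lists()
    minima = [
        u
        for u in range(grid.n_units)
        if all(heights[u] <= heights[v] for v in neighbor_lists[u])
    ]
    minima_set = set(minima)
    # collapse equal-height plateaus of adjacent minima via union-find flood fill
    seeds: list[int] = []
    visited: set[int] = set()
    for u in minima:
        if u in visited:
            continue
        component = {u}
        frontier = [u]
        while frontier:
            w = frontier.pop()
            for v in neighbor_lists[w]:
                if v in minima_set and v not in component and heights[v] == heights[w]:
                    component.add(v)
                    frontier.append(v)
        visited |= component
        seeds.append(min(component))
    return sorted(seeds)


def merge_closest_seeds(grid: SOMGrid, seeds: list[int], max_clusters: int) -> list[int]:
    """Reduce an emergent seed list to at most ``max_clusters`` seeds.

    Repeatedly drops the higher-index member of the seed pair with the
    closest codebooks, so the cap merges the two most similar would-be
    clusters at each step.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    seeds = sorted(seeds)
    while len(seeds) > max_clusters:
        best: tuple[float, int, int] | None = None
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                d = float(np.linalg.norm(grid.codebook[seeds[i]] - grid.codebook[seeds[j]]))
                if best is None or (d, seeds[i], seeds[j]) < best:
                    best = (d, seeds[i], seeds[j])
        assert best is not None
        seeds.remove(best[2])
    return seeds


def partition(grid: SOMGrid, seeds: list[int], bmu: BMUMap) -> ClusterPartition:
    """Grow clusters from seed units over the lattice, then assign transcripts.

    At each step the unassigned unit that is lattice-adjacent to some
    cluster and has minimal codebook distance to that cluster's *seed*
    codebook is attached (ties: lower cluster ID, then lower unit index).
    Comparing to the fixed seed codebook — not a running centroid — keeps
    the partition a pure function of the trained map.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    seeds = sorted(seeds)
    n_units = grid.n_units
    unit_cluster = np.zeros(n_units, dtype=int)
    for k, s in enumerate(seeds, start=1):
        if not 0 <= s < n_units:
            raise IndexError(f"seed unit {s} out of range")
        unit_cluster[s] = k
    neighbor_lists = grid.neighbor_lists()
    seed_cb = {k: grid.codebook[s] for k, s in enumerate(seeds, start=1)}

    unassigned = set(np.flatnonzero(unit_cluster == 0))
    while unassigned:
        best: tuple[float, int, int] | None = None
        for u in unassigned:
            adjacent_clusters = {
                int(unit_cluster[v]) for v in neighbor_lists[u] if unit_cluster[v] > 0
            }
            for k in adjacent_clusters:
                d = float(np.linalg.norm(grid.codebook[u] - seed_cb[k]))
                cand = (d, k, u)
                if best is None or cand < best:
                    best = cand
        if best is None:  # disconnected lattice cannot happen on a supra-hexagon
            raise RuntimeError("no unassigned unit is adjacent to any cluster")
        _, k, u = best
        unit_cluster[u] = k
        unassigned.remove(u)

    gene_cluster = {tid: int(unit_cluster[u]) for tid, u in bmu.assignment.items()}
    return ClusterPartition(
        n_clusters=len(seeds),
        unit_cluster=unit_cluster,
        seed_units={k: s for k, s in enumerate(seeds, start=1)},
        gene_cluster=gene_cluster,
        seed_profiles={k: grid.codebook[s].copy() for k, s in enumerate(seeds, start=1)},
    )


def cluster_sizes(p: ClusterPartition) -> dict[int, int]:
    """Transcript count per cluster ID (clusters with no genes report 0)."""
    sizes = {k: 0 for k in range(1, p.n_clusters + 1)}
    for k in p.gene_cluster.values():
        sizes[k] += 1
    return sizes
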