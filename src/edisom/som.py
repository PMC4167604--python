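"""Supra-hexagonal self-organizing map with a Gaussian neighborhood kernel.

The lattice is a hexagon-shaped arrangement of hexagonal units: ``r`` rings
contain ``3r(r-1)+1`` units.  Units live on axial coordinates ``(q, row)``
with ``max(|q|, |row|, |q+row|) <= r-1`` and are converted to Cartesian
positions by ``x = q + row/2``, ``y = row * sqrt(3)/2``, which puts lattice
neighbors at unit Euclidean spacing.  Units are indexed in (row, q)
lexicographic order, so unit indices — used for every tie-break downstream —
are a pure function of the ring count.

Each unit carries a codebook vector of prototype stage-wise log2
fold-change values.  Training follows the classical Kohonen update with a
Gaussian neighborhood ``h(c, i) = exp(-d(c, i)^2 / (2 sigma^2))`` where
``d`` is lattice (Cartesian) distance and ``c`` the best-matching unit;
sigma and (in sequential mode) the learning rate are interpolated linearly
within each phase of the schedule.  Batch mode is the default: it needs no
sample ordering, so results are independent of the random seed given the
deterministic principal-plane initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import FoldChangeMatrix

__all__ = [
    "SOMGrid",
    "TrainingPhase",
    "TrainingSchedule",
    "BMUMap",
    "choose_rings",
    "build_grid",
    "hex_distance",
    "default_schedule",
    "train",
    "map_bmu",
    "quantization_error",
]


def _axial_coords(rings: int) -> np.ndarray:
    """Axial (q, row) coordinates of a hexagon with ``rings`` rings, sorted by (row, q)."""
    radius = rings - 1
    coords = [
        (q, row)
        for row in range(-radius, radius + 1)
        for q in range(max(-radius, -row - radius), min(radius, radius - row) + 1)
    ]
    return np.array(coords, dtype=int).reshape(-1, 2)


def _to_cartesian(axial: np.ndarray) -> np.ndarray:
    q = axial[:, 0].astype(float)
    row = axial[:, 1].astype(float)
    return np.column_stack([q + row / 2.0, row * (math.sqrt(3.0) / 2.0)])


@dataclass(frozen=True)
class SOMGrid:
    """A supra-hexagonal lattice with one codebook vector per unit."""

    rings: int
    unit_coords: np.ndarray  # (n_units, 2) axial (q, row)
    codebook: np.ndarray  # (n_units, n_stages)
    trained: bool = False
    stage_labels: tuple[str, ...] | None = None
    cartesian: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rings < 1:
            raise ValueError(f"rings must be >= 1, got {self.rings}")
        expected = 3 * self.rings * (self.rings - 1) + 1
        if len(self.unit_coords) != expected:
            raise ValueError(
                f"grid with {self.rings} rings must have {expected} units, "
                f"got {len(self.unit_coords)}"
            )
        cb = np.asarray(self.codebook, dtype=float)
        object.__setattr__(self, "codebook", cb)
        if cb.shape[0] != expected:
            raise ValueError("codebook must have one row per unit")
        if not np.all(np.isfinite(cb)):
            raise ValueError("codebook entries must be finite")
        if self.cartesian is None:
            object.__setattr__(self, "cartesian", _to_cartesian(self.unit_coords))

    @property
    def n_units(self) -> int:
        return len(self.unit_coords)

    @property
    def n_stages(self) -> int:
        return self.codebook.shape[1]

    def lattice_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between unit centers on the lattice."""
        return cdist(self.cartesian, self.cartesian)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Indices of immediate lattice neighbors (distance 1) per unit."""
        dist = self.lattice_distances()
        mask = np.isclose(dist, 1.0)
        return [np.flatnonzero(mask[u]) for u in range(self.n_units)]


def choose_rings(n_profiles: int, max_rings: int = 50) -> int:
    """Ring count whose unit total best matches the ~5*sqrt(N) map-size heuristic.

    Minimizes ``|3r(r-1)+1 - 5*sqrt(n_profiles)|`` over ``r`` in 1..max_rings,
    preferring the smaller ``r`` on ties.
    """
    if n_profiles < 1:
        raise ValueError(f"n_profiles must be >= 1, got {n_profiles}")
    target = 5.0 * math.sqrt(n_profiles)
    best_r, best_gap = 1, float("inf")
    for r in range(1, max_rings + 1):
        gap = abs(3 * r * (r - 1) + 1 - target)
        if gap < best_gap:
            best_r, best_gap = r, gap
    return best_r


def build_grid(
    data: FoldChangeMatrix | np.ndarray,
    rings_override: int | None = None,
    seed: int = 0,
) -> SOMGrid:
    """Create an untrained grid sized to the data and initialize its codebook.

    Sizing: ``rings_override`` if given, else :func:`choose_rings` on the
    profile count.  Initialization: linear interpolation over the plane
    spanned by the data's first two principal directions (deterministic),
    mapping each unit's normalized lattice position to ``mean ± 2 sd`` along
    each component; falls back to a seeded uniform draw inside the data's
    per-column range when the data are rank-deficient.
    """
    if isinstance(data, FoldChangeMatrix):
        X = data.values
        stage_labels: tuple[str, ...] | None = data.stage_labels
    else:
        X = np.asarray(data, dtype=float)
        stage_labels = None
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D array of profiles")
    n, k = X.shape
    if rings_override is not None:
        if rings_override < 1:
            raise ValueError(f"rings_override must be >= 1, got {rings_override}")
        rings = int(rings_override)
    else:
        rings = choose_rings(n)
    axial = _axial_coords(rings)
    cart = _to_cartesian(axial)
    n_units = len(axial)

    mean = X.mean(axis=0)
    centered = X - mean
    codebook = np.tile(mean, (n_units, 1))
    rank_ok = False
    if n >= 2 and k >= 2:
        _, svals, vecs = np.linalg.svd(centered, full_matrices=False)
        if len(svals) >= 2 and svals[1] > 1e-10 * max(svals[0], 1.0):
            rank_ok = True
            # deterministic component signs: largest-|.| loading positive
            for i in range(2):
                pivot = np.argmax(np.abs(vecs[i]))
                if vecs[i, pivot] < 0:
                    vecs[i] = -vecs[i]
            sds = svals[:2] / math.sqrt(max(n - 1, 1))
            for axis in range(2):
                pos = cart[:, axis]
                span = np.max(np.abs(pos - pos.mean())) if n_units > 1 else 0.0
                if span > 0:
                    frac = (pos - pos.mean()) / span  # in [-1, 1]
                    codebook = codebook + np.outer(frac, 2.0 * sds[axis] * vecs[axis])
    if not rank_ok:
        rng = np.random.default_rng(seed)
        lo, hi = X.min(axis=0), X.max(axis=0)
        width = np.where(hi > lo, hi - lo, 1.0)
        codebook = lo + rng.uniform(size=(n_units, k)) * width

    return SOMGrid(
        rings=rings,
        unit_coords=axial,
        codebook=codebook,
        trained=False,
        stage_labels=stage_labels,
        cartesian=cart,
    )


def hex_distance(u: int, v: int, grid: SOMGrid) -> float:
    """Euclidean distance between unit centers ``u`` and ``v`` on the lattice."""
    for idx in (u, v):
        if not 0 <= idx < grid.n_units:
            raise IndexError(f"unit index {idx} out of range 0..{grid.n_units - 1}")
    return float(np.linalg.norm(grid.cartesian[u] - grid.cartesian[v]))


@dataclass(frozen=True)
class TrainingPhase:
    epochs: int
    sigma_start: float
    sigma_end: float
    rate_start: float = 0.5
    rate_end: float = 0.05

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("each phase needs epochs >= 1")
        if min(self.sigma_start, self.sigma_end) <= 0:
            raise ValueError("sigma values must be > 0")
        for rate in (self.rate_start, self.rate_end):
            if not 0 < rate <= 1:
                raise ValueError("learning rates must lie in (0, 1]")


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered training phases plus the update mode and sample-order seed."""

    phases: tuple[TrainingPhase, ...]
    mode: str = "batch"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        if self.mode not in ("batch", "sequential"):
            raise ValueError(f"mode must be 'batch' or 'sequential', got {self.mode!r}")


def default_schedule(
    grid: SOMGrid, n_profiles: int, mode: str = "batch", seed: int = 0,
    epochs_scale: float = 1.0,
) -> TrainingSchedule:
    """Two-phase rough/fine-tune schedule.

    Rough: ``max(5, ceil(10 * units / n))`` epochs shrinking sigma from the
    grid radius to 1; fine-tune: four times as many epochs, sigma 1 -> 0.5.
    ``epochs_scale`` multiplies both for quick smoke runs or longer training.
    """
    rough = max(5, math.ceil(10 * grid.n_units / max(n_profiles, 1)))
    rough = max(1, math.ceil(rough * epochs_scale))
    fine = max(1, 4 * rough)
    return TrainingSchedule(
        phases=(
            TrainingPhase(rough, sigma_start=float(max(grid.rings, 1)), sigma_end=1.0,
                          rate_start=0.5, rate_end=0.05),
            TrainingPhase(fine, sigma_start=1.0, sigma_end=0.5,
                          rate_start=0.05, rate_end=0.01),
        ),
        mode=mode,
        seed=seed,
    )


def _interp(start: float, end: float, step: int, total: int) -> float:
    if total <= 1:
        return start
    return start + (end - start) * step / (total - 1)


def train(
    grid: SOMGrid,
    fc: FoldChangeMatrix | np.ndarray,
    schedule: TrainingSchedule | None = None,
    allow_retrain: bool = False,
) -> SOMGrid:
    """Train the codebook on fold-change profiles; returns a new trained grid.

    Batch mode recomputes every codebook as the neighborhood-weighted mean
    of all samples each epoch; sequential mode streams samples in a seeded
    random order with the incremental rule ``m += alpha * h * (x - m)``.
    Identical grid, schedule and input give bit-identical output.
    """
    if grid.trained and not allow_retrain:
        raise ValueError("grid is already trained; pass allow_retrain=True to retrain")
    if isinstance(fc, FoldChangeMatrix):
        X = fc.values
        stage_labels: tuple[str, ...] | None = fc.stage_labels
    else:
        X = np.asarray(fc, dtype=float)
        stage_labels = grid.stage_labels
    if X.shape[1] != grid.n_stages:
        raise ValueError(
            f"profile length {X.shape[1]} does not match codebook width {grid.n_stages}"
        )
    if schedule is None:
        schedule = default_schedule(grid, len(X))

    M = grid.codebook.copy()
    D2 = grid.lattice_distances() ** 2

    if schedule.mode == "batch":
        for phase in schedule.phases:
            for epoch in range(phase.epochs):
                sigma = _interp(phase.sigma_start, phase.sigma_end, epoch, phase.epochs)
                bmu = np.argmin(cdist(X, M), axis=1)
                H = np.exp(-D2 / (2.0 * sigma * sigma))
                W = H[bmu]  # (n_samples, n_units)
                denom = W.sum(axis=0)
                numer = W.T @ X
                update = denom > 1e-300
                M[update] = numer[update] / denom[update, None]
    else:
        rng = np.random.default_rng(schedule.seed)
        for phase in schedule.phases:
            total = phase.epochs * len(X)
            step = 0
            for _ in range(phase.epochs):
                for j in rng.permutation(len(X)):
                    sigma = _interp(phase.sigma_start, phase.sigma_end, step, total)
                    alpha = _interp(phase.rate_start, phase.rate_end, step, total)
                    x = X[j]
                    c = int(np.argmin(np.linalg.norm(M - x, axis=1)))
                    h = np.exp(-D2[c] / (2.0 * sigma * sigma))
                    M += alpha * h[:, None] * (x - M)
                    step += 1

    return replace(grid, codebook=M, trained=True, stage_labels=stage_labels)


@dataclass(frozen=True)
class BMUMap:
    """Best-matching-unit assignment of each transcript, plus the map's fit."""

    assignment: dict[str, int]
    quantization_error: float

    def __post_init__(self) -> None:
        if self.quantization_error < 0:
            raise ValueError("quantization error cannot be negative")

    def unit_of(self, transcript_id: str) -> int:
        return self.assignment[transcript_id]


def _bmu_indices(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    # np.argmin returns the first (lowest-index) minimizer, which is the
    # documented tie-break for identical codebooks.
    return np.argmin(cdist(X, codebook), axis=1)


def quantization_error(grid: SOMGrid, fc: FoldChangeMatrix | np.ndarray) -> float:
    """Mean Euclidean distance from each profile to its nearest codebook."""
    X = fc.values if isinstance(fc, FoldChangeMatrix) else np.asarray(fc, dtype=float)
    dists = cdist(X, grid.codebook)
    return float(dists.min(axis=1).mean())


def map_bmu(grid: SOMGrid, fc: FoldChangeMatrix) -> BMUMap:
    """Assign every transcript to its best-matching unit on a trained grid."""
    if not grid.trained:
        raise ValueError("grid must be trained before BMU mapping")
    if fc.n_stages != grid.n_stages:
        raise ValueError(
            f"profile length {fc.n_stages} does not match codebook width {grid.n_stages}"
        )
    dists = cdist(fc.values, grid.codebook)
    bmu = np.argmin(dists, axis=1)
    qe = float(dists[np.arange(len(bmu)), bmu].mean())
    assignment = {tid: int(u) for tid, u in zip(fc.transcript_ids, bmu)}
    return BMUMap(assignment=assignment, quantization_error=qe)
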