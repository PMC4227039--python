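"""Monte-Carlo null for sphere coverage: simulation matrix, Z statistic, p-value.

The null hypothesis is spatial uniformity: each mutation occurrence falls on
any of the structure's N residues with equal probability.  For the observed
tally and for each of T simulated tallies we compute, over a grid of
(sphere count s, radius r) cells, the maximal mutation coverage achievable by
s non-overlapping spheres of radius r.  Each cell (column) is standardized by
the mean and standard deviation of its T simulated values, every row is
reduced to its maximum standardized value Z, and the p-value is the fraction
of simulations whose Z reaches the observed Z_0.  One p-value covers all
reported hotspots jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import StructureModel
from .mutmap import MutationTally, is_blank
from .spherescan import SphereConfiguration, _search, best_spheres

logger = logging.getLogger(__name__)

DEFAULT_RADII = tuple(float(r) for r in range(1, 11))
DEFAULT_SPHERE_COUNTS = (1, 2, 3)
DEFAULT_T = 1000


def default_grid(
    radii=DEFAULT_RADII, sphere_counts=DEFAULT_SPHERE_COUNTS
) -> list[tuple[int, float]]:
    """The (s, r) grid in its canonical order: s-major, r ascending."""
    return [(s, float(r)) for s in sphere_counts for r in radii]


class DegenerateAnalysisError(ValueError):
    """Every grid cell was excluded (infeasible or zero-variance)."""


@dataclass
class SimulationMatrix:
    """Observed + simulated sphere-coverage counts over the (s, r) grid.

    Row 0 of ``X`` is the observed dataset; rows 1..T are the null
    simulations.  ``mu``/``sigma`` are computed over the simulation rows
    only.  ``included`` marks cells that are geometrically feasible and have
    nonzero simulation variance; excluded cells are dropped from the row
    maximum for ALL rows.  ``Z`` has length T+1, ``Z[0]`` being the observed
    statistic.
    """

    T: int
    grid: list[tuple[int, float]]
    X: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    included: np.ndarray
    Z: np.ndarray
    seed: int
    observed_configs: dict[tuple[int, float], SphereConfiguration] = field(
        default_factory=dict
    )

    @property
    def n_cells(self) -> int:
        return len(self.grid)


@dataclass
class HotspotResult:
    """Joint significance of the best sphere configuration over the grid."""

    p_value: float
    p_floor: bool
    p_text: str
    T: int
    seed: int
    best_cell: tuple[int, float] | None
    hotspots: SphereConfiguration | None
    per_cell: dict[tuple[int, float], SphereConfiguration]
    degenerate: bool = False

    def to_dict(self, model: StructureModel | None = None) -> dict:
        return {
            "p_value": self.p_value,
            "p_floor": self.p_floor,
            "p_text": self.p_text,
            "T": self.T,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "best_cell": list(self.best_cell) if self.best_cell else None,
            "hotspots": self.hotspots.to_dict(model) if self.hotspots else None,
            "per_cell": [cfg.to_dict(model) for cfg in self.per_cell.values()],
        }


def simulate_null(
    model: StructureModel,
    tally: MutationTally,
    seed: int,
    T: int = DEFAULT_T,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Draw T null tallies: (T, N) integer matrix, each row placing
    ``tally.total`` mutation occurrences independently and uniformly over the
    N residues.

    ``weights`` is an experimental hook for non-uniform per-residue mutation
    probabilities; the supported null is uniform.
    """
    rng = np.random.default_rng(seed)
    if weights is None:
        p = np.full(model.N, 1.0 / model.N)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (model.N,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be N non-negative values with positive sum")
        p = w / w.sum()
    return rng.multinomial(tally.total, p, size=T)


def build_matrix(
    model: StructureModel,
    tally: MutationTally,
    grid: list[tuple[int, float]] | None = None,
    T: int = DEFAULT_T,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> SimulationMatrix:
    """Assemble the observed + simulated coverage matrix and the Z statistic.

    For every grid cell, row 0 is the observed optimal coverage and rows
    1..T are re-optimized coverages of the simulated tallies.  Infeasibility
    of a cell (no s centers pairwise >= 2r apart) is a property of the
    geometry alone, so it is determined once on the observed row and the cell
    is skipped entirely.  Cells whose simulated values are constant
    (sigma == 0) carry no ordering information and are likewise excluded from
    every row's maximum.
    """
    if is_blank(tally):
        raise ValueError("blank tally: need at least two mapped mutation occurrences")
    if grid is None:
        grid = default_grid()
    grid = sorted(set((int(s), float(r)) for s, r in grid))
    if not grid:
        raise ValueError("grid must be non-empty")

    sims = simulate_null(model, tally, seed=seed, T=T, weights=weights)
    all_counts = np.vstack([tally.structure_counts[None, :], sims])  # (T+1, N)

    n_cells = len(grid)
    X = np.zeros((T + 1, n_cells), dtype=np.int64)
    feasible = np.zeros(n_cells, dtype=bool)
    observed_configs: dict[tuple[int, float], SphereConfiguration] = {}

    D = model.distance_matrix
    radii = sorted({r for _, r in grid})
    for r in radii:
        M = D <= r
        cells_r = [(j, s) for j, (s, rr) in enumerate(grid) if rr == r]
        # Coverage vectors for all rows at once: C[t, i] = sum counts within r of i.
        C = all_counts @ M  # M symmetric
        # Observed row first: detects infeasible cells and records configurations.
        for j, s in cells_r:
            cfg = best_spheres(model, tally, s, r)
            observed_configs[grid[j]] = cfg
            feasible[j] = cfg.feasible
            X[0, j] = cfg.covered
        active = [(j, s) for j, s in cells_r if feasible[j]]
        single = [j for j, s in active if s == 1]
        multi = [(j, s) for j, s in active if s > 1]
        if single:
            X[1:, single] = C[1:].max(axis=1)[:, None]
        if multi:
            Dok = D >= 2.0 * r
            for t in range(1, T + 1):
                counts_t = all_counts[t]
                c_t = C[t]
                order = np.argsort(-c_t, kind="stable")
                for j, s in multi:
                    found = _search(counts_t, M, Dok, s, order=order, c=c_t)
                    # feasibility is geometric, identical for every row
                    assert found is not None
                    X[t, j] = found[1]

    mu = X[1:].mean(axis=0)
    sigma = X[1:].std(axis=0)  # population SD over the T simulation rows
    included = feasible & (sigma > 0)
    if not included.any():
        logger.warning("all grid cells excluded (infeasible or constant); degenerate")
        Z = np.zeros(T + 1)
    else:
        std = (X[:, included] - mu[included]) / sigma[included]
        Z = std.max(axis=1)
    return SimulationMatrix(
        T=T,
        grid=grid,
        X=X,
        mu=mu,
        sigma=sigma,
        included=included,
        Z=Z,
        seed=seed,
        observed_configs=observed_configs,
    )


def p_value(matrix: SimulationMatrix) -> HotspotResult:
    """Monte-Carlo tail probability of the observed Z statistic.

    p = #{i in 1..T : Z_i >= Z_0} / T.  Ties count against significance.
    When no simulation reaches Z_0 the p-value is reported as a floor,
    "< 1/T" (e.g. "<1.00E-03" at T = 1000).  The best cell is the included
    cell with the largest observed standardized coverage, ties broken toward
    smaller s then smaller r.
    """
    T = matrix.T
    if not matrix.included.any():
        return HotspotResult(
            p_value=1.0,
            p_floor=False,
            p_text="1.000E+00",
            T=T,
            seed=matrix.seed,
            best_cell=None,
            hotspots=None,
            per_cell=dict(matrix.observed_configs),
            degenerate=True,
        )
    exceed = int((matrix.Z[1:] >= matrix.Z[0]).sum())
    floor = exceed == 0
    p = exceed / T
    text = f"<{1.0 / T:.2E}" if floor else f"{p:.3E}"

    std0 = np.full(matrix.n_cells, -np.inf)
    inc = matrix.included
    std0[inc] = (matrix.X[0, inc] - matrix.mu[inc]) / matrix.sigma[inc]
    best_j = int(np.argmax(std0))  # grid sorted by (s, r): first max wins ties
    best_cell = matrix.grid[best_j]
    return HotspotResult(
        p_value=p,
        p_floor=floor,
        p_text=text,
        T=T,
        seed=matrix.seed,
        best_cell=best_cell,
        hotspots=matrix.observed_configs[best_cell],
        per_cell=dict(matrix.observed_configs),
    )


def analyze(
    model: StructureModel,
    tally: MutationTally,
    grid: list[tuple[int, float]] | None = None,
    T: int = DEFAULT_T,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> HotspotResult:
    """Convenience wrapper: build the simulation matrix and return the result."""
    return p_value(build_matrix(model, tally, grid=grid, T=T, seed=seed, weights=weights))
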