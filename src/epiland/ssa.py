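"""Exact stochastic simulation (Gillespie direct method) of the circuits.

The two-gene circuit is treated as a four-channel jump process on molecule
counts: one lumped production channel per gene, with propensity equal to the
system size Omega times the deterministic production rate evaluated at
concentrations counts/Omega, and one first-order degradation channel per
gene.  With the default Omega = 1 the dimensionless concentrations are read
directly as copy numbers, which is the regime where intrinsic expression
noise drives transitions between the attractors of the landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .attractors import (
    MATCH_RADIUS,
    UNASSIGNED,
    FixedPoint,
    find_fixed_points,
    match_attractor,
    stable_points as _stable_subset,
)
from .circuits import CircuitParams
from .errors import ConfigurationError, DomainError
from .landscape import AlignedLandscape, elevation_at
from .quasipotential import IntegratorConfig, integrate

__all__ = [
    "ReactionSystem",
    "GillespieResult",
    "CellPopulation",
    "gillespie_run",
    "simulate_population",
    "occupancy",
    "jitter_overlay",
]


@dataclass(frozen=True)
class ReactionSystem:
    """The jump process derived from a circuit at system size Omega."""

    params: CircuitParams
    omega: float = 1.0

    def __post_init__(self):
        if self.omega <= 0:
            raise DomainError("omega must be > 0")

    def propensities(self, x: int, y: int) -> np.ndarray:
        """Propensities (prod_x, deg_x, prod_y, deg_y) at counts (x, y)."""
        if x < 0 or y < 0:
            raise DomainError("counts must be non-negative")
        px, py = _kernels.production(
            self.params.to_array(), x / self.omega, y / self.omega
        )
        return np.array([
            self.omega * px,
            self.params.deg_X * x,
            self.omega * py,
            self.params.deg_Y * y,
        ])


@dataclass
class GillespieResult:
    x: int
    y: int
    t: float
    absorbed: bool
    sample_times: Optional[np.ndarray] = None
    sample_x: Optional[np.ndarray] = None
    sample_y: Optional[np.ndarray] = None


def gillespie_run(
    system: ReactionSystem,
    init,
    t_end: float,
    seed: int,
    sample_times: Optional[np.ndarray] = None,
) -> GillespieResult:
    """One exact SSA realization from integer counts ``init`` up to ``t_end``.

    Reproducible given ``seed``.  If every propensity vanishes the state is
    absorbing and the run returns early with ``absorbed=True``.  Optional
    ``sample_times`` (sorted) record the state just before each time.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    x0, y0 = (int(v) for v in init)
    if x0 < 0 or y0 < 0:
        raise DomainError("initial counts must be non-negative")
    st = (np.empty(0) if sample_times is None
          else np.ascontiguousarray(sample_times, dtype=np.float64))
    x, y, t, absorbed, sx, sy = _kernels.ssa_path(
        system.params.to_array(), float(system.omega),
        x0, y0, float(t_end), int(seed) & 0x7FFFFFFF, st,
    )
    res = GillespieResult(int(x), int(y), float(t), bool(absorbed))
    if sample_times is not None:
        res.sample_times = st
        res.sample_x = np.asarray(sx)
        res.sample_y = np.asarray(sy)
    return res


def derive_cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    """Counter-based per-cell seeds: identical regardless of execution order."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n_cells, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass
class CellPopulation:
    """Final states of independent SSA 'cells' plus their basin labels."""

    params: CircuitParams
    omega: float
    t_end: float
    seed: int
    x: np.ndarray  # (n,) final counts
    y: np.ndarray
    basin: np.ndarray  # (n,) labels from the attractor set, or UNASSIGNED
    stable_points: Sequence[FixedPoint] = field(default_factory=list)
    cell_seeds: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.x.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(self.n_cells),
            "x": self.x,
            "y": self.y,
            "basin": self.basin,
        })

    def to_csv(self, path, aligned: Optional[AlignedLandscape] = None) -> None:
        df = self.to_dataframe()
        if aligned is not None:
            df["elevation"] = [
                elevation_at(aligned, (xi / self.omega, yi / self.omega))
                for xi, yi in zip(self.x, self.y)
            ]
        df.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "omega": self.omega,
            "t_end": self.t_end,
            "n_cells": int(self.n_cells),
            "parameters": self.params.to_dict(),
        }

    def metadata_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def simulate_population(
    params: CircuitParams,
    init,
    n_cells: int,
    t_end: float,
    omega: float = 1.0,
    seed: int = 0,
    stable_pts: Optional[Sequence[FixedPoint]] = None,
    cfg: Optional[IntegratorConfig] = None,
    match_radius: float = MATCH_RADIUS,
) -> CellPopulation:
    """Run ``n_cells`` independent SSA realizations from concentration ``init``.

    Per-cell seeds derive from ``seed`` by a counter-based scheme.  Basin
    labels are assigned by integrating the deterministic flow from each
    cell's scaled final counts and matching the endpoint to a stable fixed
    point (:data:`~epiland.attractors.UNASSIGNED` when that fails).
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if stable_pts is None:
        stable_pts = _stable_subset(find_fixed_points(params, seed=seed))
    system = ReactionSystem(params, omega)
    x0 = int(round(init[0] * omega))
    y0 = int(round(init[1] * omega))
    seeds = derive_cell_seeds(seed, n_cells)
    xs = np.empty(n_cells, dtype=np.int64)
    ys = np.empty(n_cells, dtype=np.int64)
    if t_end == 0:
        xs[:] = x0
        ys[:] = y0
    else:
        for k in range(n_cells):
            res = gillespie_run(system, (x0, y0), t_end, int(seeds[k]))
            xs[k] = res.x
            ys[k] = res.y
    basins = np.empty(n_cells, dtype=int)
    cache: dict = {}
    for k in range(n_cells):
        key = (int(xs[k]), int(ys[k]))
        if key not in cache:
            traj = integrate((key[0] / omega, key[1] / omega), params, cfg)
            cache[key] = (
                match_attractor(traj.final_state, stable_pts, match_radius)
                if traj.converged else UNASSIGNED
            )
        basins[k] = cache[key]
    return CellPopulation(
        params=params, omega=omega, t_end=float(t_end), seed=int(seed),
        x=xs, y=ys, basin=basins, stable_points=list(stable_pts),
        cell_seeds=seeds,
    )


def occupancy(pop: CellPopulation) -> pd.Series:
    """Fraction of cells per basin label (UNASSIGNED included); sums to 1."""
    if pop.n_cells == 0:
        raise ConfigurationError("occupancy of an empty population is undefined")
    labels = [fp.label for fp in pop.stable_points] + [UNASSIGNED]
    counts = pd.Series(0.0, index=labels)
    for lab, cnt in zip(*np.unique(pop.basin, return_counts=True)):
        counts[int(lab)] = cnt
    return counts / pop.n_cells


def jitter_overlay(
    pop: CellPopulation,
    aligned: AlignedLandscape,
    mode: str = "uniform",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell plotting coordinates with sub-unit jitter plus surface elevation.

    ``mode="uniform"`` adds U[0, 0.5) to each coordinate (so multiple cells
    at the same integer counts are distinguishable), ``"centered"`` adds
    U(-0.5, 0.5), ``"none"`` adds nothing.  Jitter affects only the returned
    copies; stored counts are untouched.  Elevation is looked up at the
    jittered position scaled to concentrations; cells outside the surface
    support get NaN.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_cells
    if mode == "uniform":
        jx = 0.5 * rng.random(n)
        jy = 0.5 * rng.random(n)
    elif mode == "centered":
        jx = rng.random(n) - 0.5
        jy = rng.random(n) - 0.5
    elif mode == "none":
        jx = np.zeros(n)
        jy = np.zeros(n)
    else:
        raise ConfigurationError(f"unknown jitter mode {mode!r}")
    px = pop.x + jx
    py = pop.y + jy
    elev = np.array([
        elevation_at(aligned, (xi / pop.omega, yi / pop.omega))
        for xi, yi in zip(px, py)
    ])
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "x": px,
        "y": py,
        "basin": pop.basin,
        "elevation": elev,
    })
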