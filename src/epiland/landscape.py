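"""Trajectory alignment and quasi-potential surface construction.

A fan of Euler trajectories is launched from a regular grid of initial
conditions.  Each converged trajectory carries its quasi-potential drop and a
basin label.  Two continuity rules then fix the relative elevation of the
basins:

(i)  trajectories converging to the same attractor end at the same final
     elevation (the basin offset c_b);
(ii) trajectories starting at adjacent grid points but converging to
     different attractors start at the same elevation.

Rule (ii) is enforced in least squares over *all* 4-neighbor cross-basin
start pairs, and the resulting offsets are shifted so the deepest attractor
sits at elevation 0.  Piecewise-linear interpolation over a Delaunay
triangulation of the aligned trajectory points then yields the surface, from
which barrier heights (ridge minimum on a basin boundary minus the attractor
elevation) are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import spatial
from scipy.interpolate import LinearNDInterpolator

from .attractors import (
    MATCH_RADIUS,
    UNASSIGNED,
    FixedPoint,
    find_fixed_points,
    match_attractor,
    stable_points as _stable_subset,
)
from .circuits import CircuitParams, invariant_box
from .errors import AlignmentError, ConfigurationError, NoSharedBoundaryError
from .quasipotential import IntegratorConfig, Trajectory, integrate

__all__ = [
    "GridSpec",
    "TrajectoryFan",
    "AlignedLandscape",
    "QuasiPotentialSurface",
    "build_trajectory_fan",
    "align",
    "interpolate_surface",
    "barrier_height",
    "elevation_at",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of initial conditions over a rectangle."""

    x_min: float = 0.0
    x_max: float = 1.0
    y_min: float = 0.0
    y_max: float = 1.0
    nx: int = 41
    ny: int = 41

    @classmethod
    def for_params(cls, params: CircuitParams, n: int = 41,
                   factor: float = 1.2) -> "GridSpec":
        """Default start grid: n x n over [0, factor * (B + sum folds)/deg] per axis."""
        x_max, y_max = invariant_box(params, factor=factor)
        return cls(0.0, x_max, 0.0, y_max, n, n)

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx)

    @property
    def ys(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny)

    @property
    def cell(self) -> float:
        """Representative start-grid cell size (mean of the two spacings)."""
        dx = (self.x_max - self.x_min) / max(self.nx - 1, 1)
        dy = (self.y_max - self.y_min) / max(self.ny - 1, 1)
        return 0.5 * (dx + dy)


@dataclass
class TrajectoryFan:
    """One basin-labeled trajectory per converged grid start.

    ``trajectories`` is row-major over the start grid (index j * nx + i for
    start (i, j)) with ``None`` for excluded (non-converged) starts, which
    are reported in ``excluded`` as (i, j, reason).
    """

    params: CircuitParams
    grid: GridSpec
    trajectories: List[Optional[Trajectory]]
    labels: np.ndarray  # (ny, nx) int basin labels, UNASSIGNED where excluded
    fixed_points: List[FixedPoint]
    excluded: List[Tuple[int, int, str]]

    @property
    def stable_points(self) -> List[FixedPoint]:
        return _stable_subset(self.fixed_points)

    def basin_map_to_csv(self, path) -> None:
        xs, ys = self.grid.xs, self.grid.ys
        ii, jj = np.meshgrid(np.arange(self.grid.nx), np.arange(self.grid.ny))
        pd.DataFrame({
            "x": xs[ii.ravel()],
            "y": ys[jj.ravel()],
            "basin": self.labels.ravel(),
        }).to_csv(path, index=False)


def build_trajectory_fan(
    params: CircuitParams,
    grid: Optional[GridSpec] = None,
    cfg: Optional[IntegratorConfig] = None,
    fixed_points: Optional[Sequence[FixedPoint]] = None,
    match_radius: float = MATCH_RADIUS,
    seed: int = 0,
) -> TrajectoryFan:
    """Integrate one trajectory from every grid start and label it by basin.

    Recorded samples are decimated to half a start-grid cell along each
    trajectory (unless the integrator config specifies its own spacing) to
    condition the later triangulation.  Non-converged trajectories are
    excluded and reported, never silently kept.
    """
    grid = grid or GridSpec.for_params(params)
    if cfg is None:
        cfg = IntegratorConfig(record_spacing=0.5 * grid.cell)
    elif cfg.record_spacing == 0.0:
        cfg = IntegratorConfig(**{**cfg.__dict__, "record_spacing": 0.5 * grid.cell})
    if fixed_points is None:
        fixed_points = find_fixed_points(params, seed=seed)
    stable = _stable_subset(fixed_points)
    if not stable:
        raise ConfigurationError("circuit has no stable fixed point in the search box")

    labels = np.full((grid.ny, grid.nx), UNASSIGNED, dtype=int)
    trajs: List[Optional[Trajectory]] = [None] * (grid.nx * grid.ny)
    excluded: List[Tuple[int, int, str]] = []
    xs, ys = grid.xs, grid.ys
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            traj = integrate((x0, y0), params, cfg)
            if not traj.converged:
                excluded.append((i, j, "not converged within step budget"))
                continue
            lab = match_attractor(traj.final_state, stable, match_radius)
            if lab == UNASSIGNED:
                excluded.append((i, j, "endpoint matched no stable fixed point"))
                continue
            traj.basin = lab
            labels[j, i] = lab
            trajs[j * grid.nx + i] = traj
    return TrajectoryFan(params, grid, trajs, labels, list(fixed_points), excluded)


@dataclass
class AlignedLandscape:
    """Trajectories aligned across basins, with per-basin elevation offsets.

    ``offsets[b]`` is the terminal elevation c_b shared by every trajectory
    of basin b; the deepest attractor is pinned at 0.  ``pairs`` holds the
    separatrix start pairs used in the rule-(ii) least squares, with their
    post-solution residuals.
    """

    fan: TrajectoryFan
    offsets: Dict[int, float]
    pairs: List[dict]
    reference_basin: int
    # Concatenated decimated samples from all trajectories:
    points: np.ndarray = field(repr=False)  # (N, 2)
    elevations: np.ndarray = field(repr=False)  # (N,)
    point_basins: np.ndarray = field(repr=False)  # (N,)
    _tri: Optional[spatial.Delaunay] = field(default=None, repr=False)
    _kdtree: Optional[spatial.cKDTree] = field(default=None, repr=False)

    @property
    def params(self) -> CircuitParams:
        return self.fan.params

    @property
    def attractor_locations(self) -> Dict[int, tuple]:
        return {fp.label: fp.location for fp in self.fan.stable_points}

    @property
    def attractor_elevations(self) -> Dict[int, float]:
        return dict(self.offsets)

    @property
    def triangulation(self) -> spatial.Delaunay:
        if self._tri is None:
            self._tri = spatial.Delaunay(self.points)
        return self._tri

    @property
    def kdtree(self) -> spatial.cKDTree:
        if self._kdtree is None:
            self._kdtree = spatial.cKDTree(self.points)
        return self._kdtree

    def residuals(self) -> np.ndarray:
        return np.array([p["residual"] for p in self.pairs])


def _adjacent_cross_basin_pairs(fan: TrajectoryFan):
    """4-neighbor start pairs whose trajectories converge to different basins."""
    nx, ny = fan.grid.nx, fan.grid.ny
    lab = fan.labels
    pairs = []
    for j in range(ny):
        for i in range(nx):
            a = lab[j, i]
            if a == UNASSIGNED:
                continue
            for di, dj in ((1, 0), (0, 1)):
                i2, j2 = i + di, j + dj
                if i2 >= nx or j2 >= ny:
                    continue
                b = lab[j2, i2]
                if b == UNASSIGNED or b == a:
                    continue
                pairs.append(((i, j, a), (i2, j2, b)))
    return pairs


def align(fan: TrajectoryFan) -> AlignedLandscape:
    """Solve the continuity rules for per-basin elevation offsets.

    Rule (i) is satisfied by construction (each trajectory's terminal
    elevation is its basin offset).  Rule (ii) becomes one linear constraint
    c_a + drop(p) = c_b + drop(q) per adjacent cross-basin start pair,
    solved in least squares with the offsets then shifted so the deepest
    attractor sits at elevation 0.  A disconnected basin adjacency graph
    raises :class:`~epiland.errors.AlignmentError`.
    """
    basins = sorted({int(b) for b in fan.labels.ravel() if b != UNASSIGNED})
    if not basins:
        raise AlignmentError("fan contains no assigned trajectories")
    index = {b: k for k, b in enumerate(basins)}
    nb = len(basins)
    pairs = _adjacent_cross_basin_pairs(fan)

    if nb > 1:
        # Connectivity check on the basin adjacency graph.
        adj = {b: set() for b in basins}
        for (i, j, a), (i2, j2, b) in pairs:
            adj[a].add(b)
            adj[b].add(a)
        seen = {basins[0]}
        frontier = [basins[0]]
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        missing = [b for b in basins if b not in seen]
        if missing:
            raise AlignmentError(
                f"basin adjacency graph is disconnected; unreachable basins: {missing}"
            )

    def drop_at(i, j):
        traj = fan.trajectories[j * fan.grid.nx + i]
        return traj.drop

    # Least squares: rows c_a - c_b = drop(q) - drop(p); pin c[basins[0]] = 0.
    rows = []
    rhs = []
    for (i, j, a), (i2, j2, b) in pairs:
        row = np.zeros(nb)
        row[index[a]] = 1.0
        row[index[b]] = -1.0
        rows.append(row)
        rhs.append(drop_at(i2, j2) - drop_at(i, j))
    pin = np.zeros(nb)
    pin[0] = 1.0
    rows.append(pin)
    rhs.append(0.0)
    A = np.vstack(rows)
    r = np.asarray(rhs)
    c, *_ = np.linalg.lstsq(A, r, rcond=None)
    c = c - c.min()  # deepest attractor at elevation 0

    offsets = {b: float(c[index[b]]) for b in basins}
    pair_records = []
    for (i, j, a), (i2, j2, b) in pairs:
        res = (offsets[a] + drop_at(i, j)) - (offsets[b] + drop_at(i2, j2))
        pair_records.append({
            "start_a": (i, j), "start_b": (i2, j2),
            "basin_a": a, "basin_b": b, "residual": float(res),
        })
    reference = min(offsets, key=offsets.get)

    pts, elevs, pbs = [], [], []
    for traj in fan.trajectories:
        if traj is None:
            continue
        pts.append(np.column_stack([traj.x, traj.y]))
        elevs.append(offsets[traj.basin] + traj.elevation())
        pbs.append(np.full(len(traj), traj.basin))
    points = np.concatenate(pts)
    elevations = np.concatenate(elevs)
    point_basins = np.concatenate(pbs)
    return AlignedLandscape(
        fan=fan, offsets=offsets, pairs=pair_records, reference_basin=reference,
        points=points, elevations=elevations, point_basins=point_basins,
    )


@dataclass
class QuasiPotentialSurface:
    """Regular-grid elevation field with a validity mask and basin labels."""

    x: np.ndarray  # (nx,)
    y: np.ndarray  # (ny,)
    z: np.ndarray  # (ny, nx), NaN outside support
    valid: np.ndarray  # (ny, nx) bool
    basin: np.ndarray  # (ny, nx) int, UNASSIGNED where invalid
    attractor_locations: Dict[int, tuple]
    attractor_elevations: Dict[int, float]

    def value_at(self, point) -> float:
        """Bilinear elevation at ``point``; NaN outside the valid region."""
        px, py = point
        if not (self.x[0] <= px <= self.x[-1] and self.y[0] <= py <= self.y[-1]):
            return float("nan")
        i = min(np.searchsorted(self.x, px) - 1, self.x.size - 2)
        j = min(np.searchsorted(self.y, py) - 1, self.y.size - 2)
        i = max(i, 0)
        j = max(j, 0)
        patch = self.z[j:j + 2, i:i + 2]
        if not np.all(np.isfinite(patch)):
            return float("nan")
        tx = (px - self.x[i]) / (self.x[i + 1] - self.x[i])
        ty = (py - self.y[j]) / (self.y[j + 1] - self.y[j])
        top = patch[0, 0] * (1 - tx) + patch[0, 1] * tx
        bot = patch[1, 0] * (1 - tx) + patch[1, 1] * tx
        return float(top * (1 - ty) + bot * ty)

    def local_minima(self, min_persistence: float = 0.0):
        """Local minima of the elevation field with their topological persistence.

        Returns a list of (x, y, z, persistence) sorted by descending
        persistence.  Persistence is the merge depth from a sweep in
        ascending elevation (union-find over the 8-connected valid grid):
        a minimum persists until its growing sub-level component merges with
        one born from a deeper minimum.  Shallow sawtooth pits produced by
        piecewise-linear interpolation have persistence on the order of the
        interpolation error, while genuine attractor valleys persist to the
        height of their lowest escape ridge, so ``min_persistence`` cleanly
        separates the two.  The deepest minimum never merges and is assigned
        infinite persistence.
        """
        z = self.z
        ny, nx = z.shape
        flat = np.flatnonzero(self.valid.ravel())
        order = flat[np.argsort(z.ravel()[flat], kind="stable")]
        parent = {}
        birth_z = {}
        birth_node = {}

        def find(a):
            root = a
            while parent[root] != root:
                root = parent[root]
            while parent[a] != root:
                parent[a], a = root, parent[a]
            return root

        minima = []  # (node, birth, death)
        zr = z.ravel()
        for node in order:
            j, i = divmod(int(node), nx)
            neighbor_roots = set()
            for dj in (-1, 0, 1):
                for di in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    j2, i2 = j + dj, i + di
                    if 0 <= j2 < ny and 0 <= i2 < nx:
                        n2 = j2 * nx + i2
                        if n2 in parent:
                            neighbor_roots.add(find(n2))
            if not neighbor_roots:
                parent[node] = node
                birth_z[node] = float(zr[node])
                birth_node[node] = int(node)
                continue
            roots = sorted(neighbor_roots, key=lambda r: birth_z[r])
            survivor = roots[0]
            parent[node] = survivor
            for r in roots[1:]:  # elder rule: shallower components die here
                minima.append((birth_node[r], birth_z[r], float(zr[node])))
                parent[r] = survivor
        # Surviving components (never merged) get infinite persistence.
        survivors = {find(n) for n in parent}
        for r in survivors:
            minima.append((birth_node[r], birth_z[r], np.inf))
        out = []
        for node, birth, death in minima:
            pers = death - birth
            if pers >= min_persistence:
                j, i = divmod(node, nx)
                out.append((float(self.x[i]), float(self.y[j]), birth, pers))
        out.sort(key=lambda t: -t[3])
        return out

    def significant_minima(self, rel_persistence: float = 0.02):
        """Minima whose persistence exceeds a fraction of the elevation range.

        Piecewise-linear interpolation artifacts sit well below 2% of the
        range on both presets while genuine attractor valleys sit well
        above, so the default separates them with margin.
        """
        z_range = float(np.nanmax(self.z) - np.nanmin(self.z))
        return self.local_minima(min_persistence=rel_persistence * z_range)

    def to_csv(self, path) -> None:
        """Long-format export: one row per grid node (x, y, elevation, valid)."""
        ii, jj = np.meshgrid(np.arange(self.x.size), np.arange(self.y.size))
        pd.DataFrame({
            "x": self.x[ii.ravel()],
            "y": self.y[jj.ravel()],
            "elevation": self.z.ravel(),
            "valid": self.valid.ravel(),
        }).to_csv(path, index=False)

    def to_json(self, path) -> None:
        """Mesh export: axes plus the value matrix (NaN encoded as null)."""
        import json

        z = [[None if not np.isfinite(v) else float(v) for v in row]
             for row in self.z]
        with open(path, "w") as fh:
            json.dump({
                "x": self.x.tolist(),
                "y": self.y.tolist(),
                "elevation": z,
                "attractor_locations": {
                    str(k): list(v) for k, v in self.attractor_locations.items()
                },
                "attractor_elevations": {
                    str(k): v for k, v in self.attractor_elevations.items()
                },
            }, fh)

    def basin_to_csv(self, path) -> None:
        ii, jj = np.meshgrid(np.arange(self.x.size), np.arange(self.y.size))
        pd.DataFrame({
            "x": self.x[ii.ravel()],
            "y": self.y[jj.ravel()],
            "basin": self.basin.ravel(),
        }).to_csv(path, index=False)


def interpolate_surface(
    aligned: AlignedLandscape,
    nx: int = 201,
    ny: int = 201,
    box=None,
) -> QuasiPotentialSurface:
    """Piecewise-linear interpolation of the aligned trajectory points.

    Grid cells outside the convex hull of the trajectory data are masked
    invalid.  Each valid node also carries the basin label of its nearest
    trajectory point, which defines the discrete basin boundaries used for
    barrier extraction.
    """
    if aligned.points.shape[0] < 3:
        raise ConfigurationError("surface interpolation needs >= 3 trajectory points")
    g = aligned.fan.grid
    if box is None:
        box = (g.x_min, g.x_max, g.y_min, g.y_max)
    x_lo, x_hi, y_lo, y_hi = box
    xs = np.linspace(x_lo, x_hi, nx)
    ys = np.linspace(y_lo, y_hi, ny)
    xx, yy = np.meshgrid(xs, ys)
    try:
        interp = LinearNDInterpolator(aligned.triangulation, aligned.elevations)
    except Exception as exc:  # degenerate (e.g. collinear) point sets
        raise ConfigurationError(
            f"surface interpolation failed (degenerate trajectory point set): {exc}"
        ) from exc
    zz = interp(xx, yy)
    valid = np.isfinite(zz)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    _, nearest = aligned.kdtree.query(nodes)
    basin = aligned.point_basins[nearest].reshape(zz.shape).astype(int)
    basin[~valid] = UNASSIGNED
    return QuasiPotentialSurface(
        x=xs, y=ys, z=zz, valid=valid, basin=basin,
        attractor_locations=aligned.attractor_locations,
        attractor_elevations=aligned.attractor_elevations,
    )


def _boundary_levels(surface: QuasiPotentialSurface):
    """Map (a, b) basin pairs -> minimal crossing elevation on their boundary.

    Boundary crossings are 4-neighbor valid node pairs with different labels;
    each crossing's level is the midpoint elevation of the two nodes.
    """
    z, lab, valid = surface.z, surface.basin, surface.valid
    levels: Dict[tuple, float] = {}
    for (sl_a, sl_b) in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),  # horizontal
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),  # vertical
    ):
        la, lb = lab[sl_a], lab[sl_b]
        va, vb = valid[sl_a], valid[sl_b]
        mask = va & vb & (la != lb)
        if not np.any(mask):
            continue
        mid = 0.5 * (z[sl_a][mask] + z[sl_b][mask])
        for a, b, m in zip(la[mask].ravel(), lb[mask].ravel(), mid.ravel()):
            key = (int(min(a, b)), int(max(a, b)))
            if key not in levels or m < levels[key]:
                levels[key] = float(m)
    return levels


def barrier_height(surface: QuasiPotentialSurface, basin_a: int, basin_b: int) -> float:
    """Ridge minimum on the a-b boundary minus attractor a's elevation.

    Asymmetric in (a, b): escaping a deep valley costs more than entering
    it.  If the two basins share no boundary,
    :class:`~epiland.errors.NoSharedBoundaryError` is raised naming the
    intermediate basin(s) adjacent to both.
    """
    elevs = surface.attractor_elevations
    for b in (basin_a, basin_b):
        if b not in elevs:
            raise ConfigurationError(
                f"basin {b} is not present on the surface (basins: {sorted(elevs)})"
            )
    if basin_a == basin_b:
        raise ConfigurationError("barrier requires two distinct basins")
    levels = _boundary_levels(surface)
    key = (min(basin_a, basin_b), max(basin_a, basin_b))
    if key not in levels:
        inter = sorted({
            c
            for (u, v) in levels
            for c in (u, v)
            if {u, v} & {basin_a} or {u, v} & {basin_b}
        } - {basin_a, basin_b})
        inter = [
            c for c in inter
            if (min(c, basin_a), max(c, basin_a)) in levels
            and (min(c, basin_b), max(c, basin_b)) in levels
        ]
        raise NoSharedBoundaryError(basin_a, basin_b, inter)
    # Interpolation noise can push the ridge a hair below a near-zero-depth
    # attractor; the barrier itself is non-negative by construction.
    return max(levels[key] - elevs[basin_a], 0.0)


def elevation_at(aligned: AlignedLandscape, point) -> float:
    """Elevation at ``point`` from the two nearest aligned trajectory samples.

    Linear (inverse-distance) interpolation between the two closest recorded
    trajectory points — the rule used to place stochastic cells on the
    surface.  Points outside the convex hull of the trajectory data return
    NaN (masked).
    """
    p = np.asarray(point, dtype=float)
    if aligned.triangulation.find_simplex(p) < 0:
        return float("nan")
    dist, idx = aligned.kdtree.query(p, k=2)
    e = aligned.elevations[idx]
    if dist[0] == 0.0:
        return float(e[0])
    w = 1.0 / dist
    return float((e * w).sum() / w.sum())
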