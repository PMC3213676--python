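"""Parameter sweeps tying the landscape and the stochastic populations together.

Two scripted experiments on the tristable circuit:

* a Hill-coefficient sweep — raising n_H steepens the regulatory sigmoids,
  which raises the ridges between basins and traps stochastic cells in their
  initial attractor;
* a basal-expression shift — raising one gene's basal rate remodels the
  landscape, deepening the attractor of that gene's lineage and destabilizing
  the opposite one, so cells "roll" toward the deepened valley.

Attractor aliases follow the lineage convention: A is the stable state most
dominated by gene y, B the one most dominated by gene x, and C (when a third
state exists) the progenitor-like state closest to the diagonal.  All sweep
points reuse the same master seed (common random numbers) so trends are not
confounded by sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .attractors import FixedPoint, find_fixed_points, stable_points as _stable_subset
from .circuits import CircuitParams, get_preset
from .errors import ConfigurationError, NoSharedBoundaryError
from .landscape import (
    GridSpec,
    align,
    barrier_height,
    build_trajectory_fan,
    interpolate_surface,
)
from .quasipotential import IntegratorConfig
from .ssa import occupancy, simulate_population

__all__ = ["SweepSpec", "attractor_aliases", "run_hill_sweep", "run_basal_shift"]

log = logging.getLogger(__name__)


def attractor_aliases(stable_pts: Sequence[FixedPoint]) -> Dict[int, str]:
    """Map basin labels to lineage aliases A (y-dominant), B (x-dominant), C.

    With two stable states only A and B are assigned; with three, the
    remaining (most diagonal) state is the progenitor C.
    """
    if not stable_pts:
        return {}
    pts = list(stable_pts)
    a = max(pts, key=lambda fp: fp.y - fp.x)
    b = max(pts, key=lambda fp: fp.x - fp.y)
    aliases = {}
    if a.label == b.label:  # single attractor
        aliases[a.label] = "A"
        return aliases
    aliases[a.label] = "A"
    aliases[b.label] = "B"
    rest = [fp for fp in pts if fp.label not in aliases]
    names = iter("CDEFG")
    for fp in sorted(rest, key=lambda fp: abs(fp.x - fp.y)):
        aliases[fp.label] = next(names)
    return aliases


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep configuration.

    ``values`` replace ``swept_field`` on ``base`` one at a time; every sweep
    point shares ``seed``, ``n_cells`` and ``t_end`` (common random numbers).
    Defaults are the scaled-down profile (200 cells to t = 1000); the
    paper-scale profile is n_cells=1000, t_end=10000.
    """

    base: CircuitParams = field(default_factory=lambda: get_preset("tristable"))
    swept_field: str = "n_H"
    values: Tuple[float, ...] = (2.0, 3.0, 4.0, 10.0)
    n_cells: int = 200
    t_end: float = 1000.0
    omega: float = 1.0
    seed: int = 0
    init_alias: str = "B"
    grid_n: int = 41
    surface_n: int = 201
    integrator: Optional[IntegratorConfig] = None

    def __post_init__(self):
        if not hasattr(self.base, self.swept_field):
            raise ConfigurationError(
                f"swept field {self.swept_field!r} is not a circuit parameter"
            )
        if not all(np.isfinite(v) for v in self.values):
            raise ConfigurationError("swept values must be finite")


def _landscape_summary(params: CircuitParams, spec: SweepSpec, seed: int):
    """Fixed points, aliases, aligned landscape and surface for one sweep point."""
    fps = find_fixed_points(params, seed=seed)
    stable = _stable_subset(fps)
    grid = GridSpec.for_params(params, n=spec.grid_n)
    fan = build_trajectory_fan(params, grid, spec.integrator, fixed_points=fps)
    aligned = align(fan)
    surface = interpolate_surface(aligned, nx=spec.surface_n, ny=spec.surface_n)
    return fps, stable, attractor_aliases(stable), aligned, surface


def _escape_barrier(surface, label: int) -> float:
    """Lowest barrier out of basin ``label`` (NaN if it borders no other basin)."""
    best = np.nan
    if label not in surface.attractor_elevations:
        return best
    for other in surface.attractor_elevations:
        if other == label:
            continue
        try:
            h = barrier_height(surface, label, other)
        except (NoSharedBoundaryError, ConfigurationError):
            continue
        if np.isnan(best) or h < best:
            best = h
    return best


def _sweep_point_rows(params, spec: SweepSpec, value: float) -> pd.DataFrame:
    fps, stable, aliases, aligned, surface = _landscape_summary(params, spec, spec.seed)
    by_alias = {v: k for k, v in aliases.items()}
    if spec.init_alias in by_alias:
        init_fp = next(fp for fp in stable if fp.label == by_alias[spec.init_alias])
        init = init_fp.location
    else:
        # Swept parameters can annihilate the requested attractor; fall back
        # to its location in the base circuit.
        base_stable = _stable_subset(find_fixed_points(spec.base, seed=spec.seed))
        base_alias = attractor_aliases(base_stable)
        base_by_alias = {v: k for k, v in base_alias.items()}
        init_fp = next(
            fp for fp in base_stable if fp.label == base_by_alias[spec.init_alias]
        )
        init = init_fp.location
    log.info(
        "sweep point %s=%g: %d stable states, init %s at (%.3f, %.3f), "
        "n_cells=%d t_end=%g omega=%g seed=%d",
        spec.swept_field, value, len(stable), spec.init_alias,
        init[0], init[1], spec.n_cells, spec.t_end, spec.omega, spec.seed,
    )
    pop = simulate_population(
        params, init, spec.n_cells, spec.t_end, omega=spec.omega,
        seed=spec.seed, stable_pts=stable,
    )
    occ = occupancy(pop)
    rows = []
    for fp in stable:
        rows.append({
            spec.swept_field: value,
            "attractor": aliases[fp.label],
            "label": fp.label,
            "x": fp.x,
            "y": fp.y,
            # A near-degenerate attractor can be unreachable on the fan grid
            # (no trajectory endpoint matches it); its elevation is then NaN.
            "elevation": surface.attractor_elevations.get(fp.label, np.nan),
            "barrier": _escape_barrier(surface, fp.label),
            "occupancy": float(occ[fp.label]),
        })
    rows.append({
        spec.swept_field: value,
        "attractor": "unassigned",
        "label": -1,
        "x": np.nan,
        "y": np.nan,
        "elevation": np.nan,
        "barrier": np.nan,
        "occupancy": float(occ[-1]),
    })
    return pd.DataFrame(rows)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Generic one-field sweep: one row per (value, attractor)."""
    frames = []
    for value in spec.values:
        params = spec.base.replace(**{spec.swept_field: value})
        try:
            frames.append(_sweep_point_rows(params, spec, value))
        except Exception as exc:
            raise ConfigurationError(
                f"sweep failed at {spec.swept_field} = {value}: {exc}"
            ) from exc
    return pd.concat(frames, ignore_index=True)


def run_hill_sweep(spec: Optional[SweepSpec] = None) -> pd.DataFrame:
    """Occupancy, barrier and elevation per attractor across Hill coefficients.

    Defaults reproduce the tristable study: n_H in {2, 3, 4, 10}, populations
    started at attractor B.
    """
    spec = spec or SweepSpec()
    if spec.swept_field != "n_H":
        raise ConfigurationError("run_hill_sweep expects swept_field 'n_H'")
    return run_sweep(spec)


def run_basal_shift(spec: Optional[SweepSpec] = None) -> pd.DataFrame:
    """Compare landscapes and occupancies as basal expression B_Y is raised.

    Defaults follow the remodeling study: tristable circuit at n_H = 10 with
    B_Y swept over {0, 4}, populations started at attractor B.  The returned
    table includes the per-condition elevation difference A - B
    (``delta_elevation_AB``).
    """
    if spec is None:
        spec = SweepSpec(
            base=get_preset("tristable").replace(n_H=10.0),
            swept_field="B_Y",
            values=(0.0, 4.0),
        )
    if spec.swept_field != "B_Y":
        raise ConfigurationError("run_basal_shift expects swept_field 'B_Y'")
    df = run_sweep(spec)
    deltas = {}
    for value, grp in df.groupby("B_Y"):
        by_alias = grp.set_index("attractor")["elevation"]
        if "A" in by_alias.index and "B" in by_alias.index:
            deltas[value] = float(by_alias["A"] - by_alias["B"])
        else:
            deltas[value] = np.nan
    df["delta_elevation_AB"] = df["B_Y"].map(deltas)
    return df
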