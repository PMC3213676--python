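"""Fixed points of a circuit: location, stability, and basin assignment.

Roots of the rate equations are found by a hybrid Newton method started from
a seeded random scatter of initial guesses, deduplicated by a merge radius,
and classified by the eigenvalues of the analytic Jacobian.  Stable fixed
points receive integer basin labels ordered lexicographically by (x, y) so
that labelling is reproducible; presentation aliases like A/B/C live in the
experiments layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize

from .circuits import CircuitParams, invariant_box, jacobian, rate
from .errors import ConfigurationError
from .quasipotential import IntegratorConfig, integrate

__all__ = [
    "FixedPoint",
    "UNASSIGNED",
    "find_fixed_points",
    "stable_points",
    "match_attractor",
    "assign_basin",
    "fixed_points_to_json",
]

#: Sentinel basin label for states whose trajectory could not be assigned.
UNASSIGNED = -1

#: Default merge radius for deduplicating roots (state-space distance).
MERGE_RADIUS = 1e-4

#: Eigenvalue real parts closer to zero than this are reported as degenerate.
EIG_THRESHOLD = 1e-8

#: Default radius for matching a converged trajectory endpoint to a stable point.
MATCH_RADIUS = 1e-3


@dataclass(frozen=True)
class FixedPoint:
    """A root of the rate equations with its linear stability."""

    x: float
    y: float
    eigenvalues: tuple
    kind: str  # "stable" | "saddle" | "unstable" | "degenerate"
    label: Optional[int] = None  # basin identifier, stable points only

    @property
    def location(self):
        return (self.x, self.y)

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "kind": self.kind,
            "label": self.label,
        }


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) <= EIG_THRESHOLD):
        return "degenerate"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    params: CircuitParams,
    search_box=None,
    n_starts: int = 300,
    seed: int = 0,
    merge_radius: float = MERGE_RADIUS,
    root_tol: float = 1e-9,
) -> List[FixedPoint]:
    """Locate and classify all fixed points inside ``search_box``.

    ``search_box`` defaults to a 10% margin around the forward-invariant box
    of the circuit.  Results are deterministic given ``seed`` and are
    deduplicated with ``merge_radius``.  Raises
    :class:`~epiland.errors.ConfigurationError` if no root is found.
    """
    if search_box is None:
        x_max, y_max = invariant_box(params, factor=1.1)
        search_box = (0.0, x_max, 0.0, y_max)
    x_lo, x_hi, y_lo, y_hi = search_box

    def fun_jac(z):
        x = max(z[0], 0.0)
        y = max(z[1], 0.0)
        f, g = rate((x, y), params)
        return np.array([f, g]), jacobian((x, y), params)

    rng = np.random.default_rng(seed)
    starts = np.column_stack([
        rng.uniform(x_lo, x_hi, n_starts),
        rng.uniform(y_lo, y_hi, n_starts),
    ])
    roots = []
    for z0 in starts:
        sol = optimize.root(fun_jac, z0, jac=True, method="hybr")
        if not sol.success:
            continue
        z = sol.x
        # Newton polish to machine precision so rates truly vanish at roots.
        for _ in range(5):
            F, J = fun_jac(z)
            if np.hypot(*F) == 0.0:
                break
            try:
                dz = np.linalg.solve(J, F)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(dz)):
                break
            z = z - dz
        x, y = z
        if x < -merge_radius or y < -merge_radius:
            continue
        x, y = max(x, 0.0), max(y, 0.0)
        f, g = rate((x, y), params)
        if np.hypot(f, g) > root_tol:
            continue
        if not (x_lo - merge_radius <= x <= x_hi + merge_radius
                and y_lo - merge_radius <= y <= y_hi + merge_radius):
            continue
        for rx, ry in roots:
            if np.hypot(x - rx, y - ry) < merge_radius:
                break
        else:
            roots.append((x, y))
    if not roots:
        raise ConfigurationError(
            "no fixed points found; try a larger n_starts or search_box"
        )

    points = []
    for x, y in roots:
        eigs = np.linalg.eigvals(jacobian((x, y), params))
        points.append((x, y, eigs, _classify(eigs)))
    # Stable labels ordered lexicographically by (x, y) for reproducibility.
    points.sort(key=lambda r: (r[0], r[1]))
    out = []
    label = 0
    for x, y, eigs, kind in points:
        lab = None
        if kind == "stable":
            lab = label
            label += 1
        out.append(FixedPoint(float(x), float(y), tuple(eigs), kind, lab))
    return out


def stable_points(fixed_points: Sequence[FixedPoint]) -> List[FixedPoint]:
    """The stable subset, in label order."""
    return sorted(
        (fp for fp in fixed_points if fp.kind == "stable"),
        key=lambda fp: fp.label,
    )


def match_attractor(
    state,
    stable_pts: Sequence[FixedPoint],
    match_radius: float = MATCH_RADIUS,
) -> int:
    """Label of the stable point within ``match_radius`` of ``state``, else UNASSIGNED."""
    x, y = state
    for fp in stable_pts:
        if np.hypot(x - fp.x, y - fp.y) <= match_radius:
            return fp.label
    return UNASSIGNED


def assign_basin(
    init,
    params: CircuitParams,
    stable_pts: Sequence[FixedPoint],
    cfg: Optional[IntegratorConfig] = None,
    match_radius: float = MATCH_RADIUS,
) -> int:
    """Basin label of the attractor reached from ``init``.

    Integrates the deterministic trajectory and matches its endpoint to a
    stable fixed point.  Returns :data:`UNASSIGNED` for non-converged
    trajectories or unmatched endpoints — never a silent guess.
    """
    if not stable_pts:
        raise ConfigurationError("assign_basin requires at least one stable point")
    traj = integrate(init, params, cfg)
    if not traj.converged:
        return UNASSIGNED
    return match_attractor(traj.final_state, stable_pts, match_radius)


def fixed_points_to_json(fixed_points: Sequence[FixedPoint], path) -> None:
    with open(path, "w") as fh:
        json.dump([fp.to_dict() for fp in fixed_points], fh, indent=2)
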