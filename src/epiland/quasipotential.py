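"""Path-integral quasi-potential along deterministic trajectories.

Along an Euler trajectory of the circuit, the quasi-potential V_q changes per
step by

    dV_q = -(f dx + g dy) = -(f^2 + g^2) dt <= 0,

where (f, g) are the rates and (dx, dy) = (f dt, g dt).  V_q is therefore
non-increasing along every trajectory and stationary exactly at fixed points:
it is a Lyapunov function of the circuit, and its accumulated drop is the
"elevation" coordinate from which the landscape modules build the surface.
The integrator is deliberately the plain explicit Euler scheme that defines
the quasi-potential increment — not a higher-order solver — with a fixed step
and a convergence stop on the per-step increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import STATUS_CONVERGED, STATUS_DIVERGED
from .circuits import CircuitParams, rate
from .errors import DomainError, IntegrationError, ParameterError

__all__ = ["IntegratorConfig", "Trajectory", "step", "integrate"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step Euler integration settings.

    Parameters
    ----------
    dt
        Time increment, fixed for a run (default 0.01 time units).
    v_tol
        Convergence tolerance on the per-step quasi-potential decrease
        |dV_q| (default 1e-12).
    rate_tol
        Secondary stop: the trajectory also counts as converged once
        ||(f, g)|| falls below this (default 1e-6), making "converged to a
        minimum" operational even for very small dt.
    max_steps
        Step budget (default 5e6).
    record_stride
        Store every k-th step (default 1).  V_q accumulation always uses
        every step regardless of recording.
    record_spacing
        If > 0, additionally decimate stored samples to this minimum
        Euclidean spacing in state space (first and final samples are always
        kept).
    divergence_norm
        Abort with an error if the state norm exceeds this bound.
    max_records
        Hard cap on stored samples (memory guard).
    """

    dt: float = 0.01
    v_tol: float = 1e-12
    rate_tol: float = 1e-6
    max_steps: int = 5_000_000
    record_stride: int = 1
    record_spacing: float = 0.0
    divergence_norm: float = 1e6
    max_records: int = 1_000_000

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.v_tol <= 0:
            raise ParameterError("v_tol must be > 0")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered (t, x, y, V_q) samples from one initial condition.

    V_q starts at 0 by convention and is non-increasing; ``drop`` is the
    total quasi-potential decrease accumulated over *every* step (not just
    the recorded ones).  ``elevation()`` returns the drop still remaining to
    the attractor at each recorded sample, so a converged trajectory
    terminates at elevation 0 before any basin offset is applied.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vq: np.ndarray
    converged: bool
    n_steps: int
    final_state: tuple
    vq_final: float
    basin: Optional[int] = None

    def __len__(self):
        return self.t.size

    @property
    def drop(self) -> float:
        """Total quasi-potential decrease |V_q(end) - V_q(0)| >= 0."""
        return -self.vq_final

    def elevation(self) -> np.ndarray:
        """Remaining drop to the attractor at each recorded sample (>= 0)."""
        return self.vq - self.vq_final

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "Vq": self.vq})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def step(state, params: CircuitParams, dt: float):
    """One Euler step and its quasi-potential increment.

    Returns ``((x + f dt, y + g dt), dV)`` with dV = -(f^2 + g^2) dt <= 0;
    dV is 0 exactly when the state is a fixed point.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    f, g = rate(state, params)
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(g))):
        raise IntegrationError(f"non-finite rates at state {state!r}")
    x, y = state
    new_state = (x + f * dt, y + g * dt)
    dv = -(f * f + g * g) * dt
    return new_state, dv


def integrate(init, params: CircuitParams, cfg: Optional[IntegratorConfig] = None) -> Trajectory:
    """Integrate from ``init`` until the quasi-potential converges to a minimum.

    Stops when the per-step decrease |dV_q| falls below ``cfg.v_tol`` (or the
    rate norm below ``cfg.rate_tol``), or at the step budget, in which case
    the trajectory is returned with ``converged=False``.  Divergence raises
    :class:`IntegrationError` naming the initial condition.
    """
    cfg = cfg or IntegratorConfig()
    x0, y0 = (float(v) for v in init)
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise DomainError("initial state must be finite")
    if x0 < 0 or y0 < 0:
        raise DomainError("initial concentrations must be non-negative")
    max_records = int(min(cfg.max_records,
                          cfg.max_steps // cfg.record_stride + 2))
    n_rec, ts, xs, ys, vs, status, n_steps, xe, ye, ve = _kernels.euler_path(
        params.to_array(), x0, y0, cfg.dt, cfg.v_tol, cfg.rate_tol,
        cfg.max_steps, cfg.record_stride, cfg.record_spacing,
        max_records, cfg.divergence_norm,
    )
    if status == STATUS_DIVERGED:
        raise IntegrationError(
            f"trajectory from ({x0}, {y0}) diverged "
            f"(state norm exceeded {cfg.divergence_norm:g} or rates non-finite)"
        )
    return Trajectory(
        t=ts[:n_rec].copy(), x=xs[:n_rec].copy(), y=ys[:n_rec].copy(),
        vq=vs[:n_rec].copy(), converged=(status == STATUS_CONVERGED),
        n_steps=int(n_steps), final_state=(float(xe), float(ye)),
        vq_final=float(ve),
    )
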