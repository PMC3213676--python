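"""Two-gene regulatory circuit models.

The circuits are mutual-inhibition ("toggle switch") motifs, optionally with
positive autoregulation, written as a two-variable dynamical system for the
dimensionless gene-product concentrations x and y:

    dx/dt = B_X + fold_XX * x^n / (K_DXX^n + x^n)
                + fold_YX * K_DYX^n / (K_DYX^n + y^n) - deg_X * x
    dy/dt = B_Y + fold_YY * y^n / (K_DYY^n + y^n)
                + fold_XY * K_DXY^n / (K_DXY^n + x^n) - deg_Y * y

i.e. basal expression plus sigmoidal (Hill) self-activation plus sigmoidal
cross-repression, with first-order decay.  The classic bistable toggle switch
is the special case fold_XX = fold_YY = 0; adding strong autoregulation
creates a third, "progenitor-like" stable state on the symmetry diagonal.
This is the standard model form for cross-antagonistic pairs of lineage
master regulators such as PU.1/GATA1.

Powers of zero are defined as 0 for any Hill exponent n > 0, so states on the
axes are regular points of the rate law.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Tuple, Union

import numpy as np

from ._kernels import N_PAR
from .errors import DomainError, ParameterError

__all__ = [
    "CircuitParams",
    "PRESETS",
    "get_preset",
    "rate",
    "jacobian",
    "gradient_condition_residual",
    "invariant_box",
]

StateLike = Union[Tuple[float, float], np.ndarray, Iterable[float]]

_FIELDS = (
    "B_X", "B_Y",
    "fold_XX", "fold_YY", "fold_YX", "fold_XY",
    "K_DXX", "K_DYY", "K_DYX", "K_DXY",
    "n_H", "deg_X", "deg_Y",
)


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of the two-gene circuit (all dimensionless).

    Attributes
    ----------
    B_X, B_Y
        Basal (constitutive) expression rates.
    fold_XX, fold_YY
        Rate constants of positive autoregulation of x and y.
    fold_YX, fold_XY
        Rate constants of the repression of x by y, and of y by x.
    K_DXX, K_DYY, K_DYX, K_DXY
        Effective affinity constants of the corresponding Hill terms.
    n_H
        Hill coefficient shared by all regulatory terms (>= 1; values > 1
        give ultrasensitive, sigmoidal regulation).
    deg_X, deg_Y
        First-order degradation rate constants (> 0).
    """

    B_X: float = 0.0
    B_Y: float = 0.0
    fold_XX: float = 0.0
    fold_YY: float = 0.0
    fold_YX: float = 0.0
    fold_XY: float = 0.0
    K_DXX: float = 1.0
    K_DYY: float = 1.0
    K_DYX: float = 1.0
    K_DXY: float = 1.0
    n_H: float = 1.0
    deg_X: float = 1.0
    deg_Y: float = 1.0

    def __post_init__(self):
        for name in _FIELDS:
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ParameterError(f"{name} must be finite, got {val!r}")
            if val < 0:
                raise ParameterError(f"{name} must be >= 0, got {val!r}")
            object.__setattr__(self, name, float(val))
        if self.deg_X <= 0 or self.deg_Y <= 0:
            raise ParameterError("degradation rate constants must be > 0")
        if self.n_H < 1:
            raise ParameterError(f"n_H must be >= 1, got {self.n_H}")
        for fold, kd in (
            ("fold_XX", "K_DXX"), ("fold_YY", "K_DYY"),
            ("fold_YX", "K_DYX"), ("fold_XY", "K_DXY"),
        ):
            if getattr(self, fold) > 0 and getattr(self, kd) == 0:
                raise ParameterError(f"{kd} = 0 with nonzero {fold}")

    # -- conversion helpers -------------------------------------------------
    def to_array(self) -> np.ndarray:
        """Flat float64 vector in the layout expected by the numba kernels."""
        out = np.array([getattr(self, f) for f in _FIELDS], dtype=np.float64)
        assert out.size == N_PAR
        return out

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in _FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        unknown = set(d) - set(_FIELDS)
        if unknown:
            raise ParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)

    def swapped(self) -> "CircuitParams":
        """Parameters with the roles of genes x and y exchanged."""
        return CircuitParams(
            B_X=self.B_Y, B_Y=self.B_X,
            fold_XX=self.fold_YY, fold_YY=self.fold_XX,
            fold_YX=self.fold_XY, fold_XY=self.fold_YX,
            K_DXX=self.K_DYY, K_DYY=self.K_DXX,
            K_DYX=self.K_DXY, K_DXY=self.K_DYX,
            n_H=self.n_H, deg_X=self.deg_Y, deg_Y=self.deg_X,
        )

    # -- flat key=value serialization --------------------------------------
    def to_file(self, path) -> None:
        lines = [f"{k} = {v!r}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "CircuitParams":
        d = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"malformed parameter line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            d[key] = float(val)
        return cls.from_dict(d)


#: Named parameter presets.  "bistable" is the plain toggle switch; the
#: "tristable" preset adds symmetric positive autoregulation strong enough to
#: stabilize a third state on the diagonal.
PRESETS = {
    "bistable": CircuitParams(
        B_X=0.2, B_Y=0.2,
        fold_XX=0.0, fold_YY=0.0, fold_YX=2.0, fold_XY=2.0,
        K_DXX=1.0, K_DYY=1.0, K_DYX=0.7, K_DXY=0.5,
        n_H=4.0, deg_X=1.0, deg_Y=1.0,
    ),
    "tristable": CircuitParams(
        B_X=0.0, B_Y=0.0,
        fold_XX=10.0, fold_YY=10.0, fold_YX=10.0, fold_XY=10.0,
        K_DXX=4.0, K_DYY=4.0, K_DYX=4.0, K_DXY=4.0,
        n_H=4.0, deg_X=1.0, deg_Y=1.0,
    ),
}


def get_preset(name: str) -> CircuitParams:
    """Return a named parameter preset ("bistable" or "tristable")."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _check_state(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("state must be finite")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("concentrations must be non-negative")
    return x, y


def _hill_act(v, K, n):
    vn = np.power(v, n)
    return vn / (K ** n + vn)


def _hill_rep(v, K, n):
    kn = K ** n
    return kn / (kn + np.power(v, n))


def rate(state: StateLike, params: CircuitParams):
    """Deterministic rates (dx/dt, dy/dt) at a state.

    Accepts scalar or array-valued coordinates (broadcast elementwise).
    """
    x, y = state
    x, y = _check_state(x, y)
    p = params
    f = p.B_X - p.deg_X * x
    if p.fold_XX > 0:
        f = f + p.fold_XX * _hill_act(x, p.K_DXX, p.n_H)
    if p.fold_YX > 0:
        f = f + p.fold_YX * _hill_rep(y, p.K_DYX, p.n_H)
    g = p.B_Y - p.deg_Y * y
    if p.fold_YY > 0:
        g = g + p.fold_YY * _hill_act(y, p.K_DYY, p.n_H)
    if p.fold_XY > 0:
        g = g + p.fold_XY * _hill_rep(x, p.K_DXY, p.n_H)
    return f, g


def _dhill_act(v, K, n):
    # d/dv [v^n / (K^n + v^n)] = n K^n v^(n-1) / (K^n + v^n)^2
    kn = K ** n
    vn1 = np.power(v, n - 1.0)
    return n * kn * vn1 / (kn + vn1 * v) ** 2


def jacobian(state: StateLike, params: CircuitParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the rate law at a (scalar) state.

    The off-diagonal entries are everywhere <= 0: both cross terms are
    repressive.
    """
    x, y = state
    x, y = _check_state(x, y)
    p = params
    dfdx = -p.deg_X
    if p.fold_XX > 0:
        dfdx = dfdx + p.fold_XX * _dhill_act(x, p.K_DXX, p.n_H)
    dfdy = 0.0
    if p.fold_YX > 0:
        dfdy = -p.fold_YX * _dhill_act(y, p.K_DYX, p.n_H)
    dgdy = -p.deg_Y
    if p.fold_YY > 0:
        dgdy = dgdy + p.fold_YY * _dhill_act(y, p.K_DYY, p.n_H)
    dgdx = 0.0
    if p.fold_XY > 0:
        dgdx = -p.fold_XY * _dhill_act(x, p.K_DXY, p.n_H)
    return np.array([[dfdx, dfdy], [dgdx, dgdy]], dtype=float)


def gradient_condition_residual(state: StateLike, params: CircuitParams) -> float:
    """Residual d(dx/dt)/dy - d(dy/dt)/dx of the gradient-system condition.

    A closed-form potential V with dx/dt = -dV/dx, dy/dt = -dV/dy exists only
    where this cross-partial symmetry holds; for mutually repressive circuits
    it is generically nonzero, which is what motivates the path-integral
    quasi-potential.
    """
    J = jacobian(state, params)
    return float(J[0, 1] - J[1, 0])


def invariant_box(params: CircuitParams, factor: float = 1.0):
    """Per-axis upper bounds of the forward-invariant box [0, (B + sum folds)/deg].

    Production is bounded by B + sum of fold constants, so each coordinate
    eventually falls below that bound divided by its degradation constant.
    """
    x_max = factor * (params.B_X + params.fold_XX + params.fold_YX) / params.deg_X
    y_max = factor * (params.B_Y + params.fold_YY + params.fold_XY) / params.deg_Y
    return x_max, y_max
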