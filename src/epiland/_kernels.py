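"""Numba kernels for the fixed-step Euler integrator and the SSA direct method.

The parameter vector layout used by every kernel is fixed by the index
constants below and produced by ``CircuitParams.to_array()``.  Hill terms are
guarded by their fold constants so that inactive terms (fold = 0) never touch
their affinity constants.
"""

import numpy as np
from numba import njit

# Indices into the flat parameter vector.
I_BX, I_BY = 0, 1
I_FXX, I_FYY, I_FYX, I_FXY = 2, 3, 4, 5
I_KXX, I_KYY, I_KYX, I_KXY = 6, 7, 8, 9
I_NH, I_DX, I_DY = 10, 11, 12

N_PAR = 13

# Euler kernel status codes.
STATUS_CONVERGED = 0
STATUS_MAX_STEPS = 1
STATUS_DIVERGED = 2


@njit(cache=True)
def production(par, x, y):
    """Production parts of the two rate laws at concentrations (x, y) >= 0."""
    n = par[I_NH]
    px = par[I_BX]
    if par[I_FXX] > 0.0:
        kn = par[I_KXX] ** n
        xn = x ** n
        px += par[I_FXX] * xn / (kn + xn)
    if par[I_FYX] > 0.0:
        kn = par[I_KYX] ** n
        px += par[I_FYX] * kn / (kn + y ** n)
    py = par[I_BY]
    if par[I_FYY] > 0.0:
        kn = par[I_KYY] ** n
        yn = y ** n
        py += par[I_FYY] * yn / (kn + yn)
    if par[I_FXY] > 0.0:
        kn = par[I_KXY] ** n
        py += par[I_FXY] * kn / (kn + x ** n)
    return px, py


@njit(cache=True)
def rates(par, x, y):
    """Full deterministic rates (dx/dt, dy/dt)."""
    px, py = production(par, x, y)
    return px - par[I_DX] * x, py - par[I_DY] * y


@njit(cache=True)
def euler_path(par, x0, y0, dt, v_tol, rate_tol, max_steps,
               record_stride, record_spacing, max_records, div_norm):
    """Fixed-step Euler integration with quasi-potential accumulation.

    At each step: f, g evaluated at the current state; the state advances by
    (f dt, g dt) and the quasi-potential by dV = -(f^2 + g^2) dt.  The walk
    stops when |dV| < v_tol or ||(f, g)|| < rate_tol (converged), at the step
    budget, or on divergence.  V_q accumulates every step; recording may be
    strided and/or decimated to a minimum spacing in state space.  The initial
    and terminal samples are always recorded.

    Returns (n_rec, t, x, y, v, status, n_steps, x_end, y_end, v_end).
    """
    ts = np.empty(max_records)
    xs = np.empty(max_records)
    ys = np.empty(max_records)
    vs = np.empty(max_records)
    x = x0
    y = y0
    v = 0.0
    t = 0.0
    ts[0] = 0.0
    xs[0] = x0
    ys[0] = y0
    vs[0] = 0.0
    n_rec = 1
    lx = x0
    ly = y0
    sp2 = record_spacing * record_spacing
    status = STATUS_MAX_STEPS
    step = 0
    while step < max_steps:
        f, g = rates(par, x, y)
        if not (np.isfinite(f) and np.isfinite(g)):
            status = STATUS_DIVERGED
            break
        r2 = f * f + g * g
        dv = r2 * dt  # magnitude of the (non-positive) increment
        if r2 <= rate_tol * rate_tol or dv < v_tol:
            status = STATUS_CONVERGED
            break
        x += f * dt
        y += g * dt
        v -= dv
        t += dt
        step += 1
        if x * x + y * y > div_norm * div_norm:
            status = STATUS_DIVERGED
            break
        if step % record_stride == 0:
            ddx = x - lx
            ddy = y - ly
            if sp2 <= 0.0 or ddx * ddx + ddy * ddy >= sp2:
                if n_rec < max_records:
                    ts[n_rec] = t
                    xs[n_rec] = x
                    ys[n_rec] = y
                    vs[n_rec] = v
                    n_rec += 1
                    lx = x
                    ly = y
    # Always include the terminal state.
    if ts[n_rec - 1] != t or n_rec == 1 and step > 0:
        if n_rec >= max_records:
            n_rec = max_records - 1
        ts[n_rec] = t
        xs[n_rec] = x
        ys[n_rec] = y
        vs[n_rec] = v
        n_rec += 1
    return n_rec, ts, xs, ys, vs, status, step, x, y, v


@njit(cache=True)
def ssa_path(par, omega, x0, y0, t_end, seed, sample_times):
    """Gillespie direct method for the two-gene circuit.

    Four channels: lumped production of each gene (propensity = omega times
    the deterministic production rate at concentrations counts/omega) and
    first-order degradation (propensity = deg * count).  Exponential waiting
    times from the total propensity; channel chosen proportionally.

    ``sample_times`` must be sorted; the state recorded for each sample time
    is the state immediately before the first jump past it.  Returns
    (x_end, y_end, t_reached, absorbed, sample_x, sample_y).
    """
    np.random.seed(seed)
    x = np.int64(x0)
    y = np.int64(y0)
    t = 0.0
    ns = sample_times.size
    sx = np.empty(ns, np.int64)
    sy = np.empty(ns, np.int64)
    si = 0
    absorbed = False
    while True:
        px, py = production(par, x / omega, y / omega)
        a1 = omega * px
        a2 = par[I_DX] * x
        a3 = omega * py
        a4 = par[I_DY] * y
        a0 = a1 + a2 + a3 + a4
        if a0 <= 0.0:
            absorbed = True
            break
        u = np.random.random()
        tau = -np.log(1.0 - u) / a0
        t_next = t + tau
        while si < ns and sample_times[si] < t_next:
            sx[si] = x
            sy[si] = y
            si += 1
        if t_next >= t_end:
            t = t_end
            break
        t = t_next
        r = np.random.random() * a0
        if r < a1:
            x += 1
        elif r < a1 + a2:
            x -= 1
        elif r < a1 + a2 + a3:
            y += 1
        else:
            y -= 1
    while si < ns:
        sx[si] = x
        sy[si] = y
        si += 1
    return x, y, t, absorbed, sx, sy
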