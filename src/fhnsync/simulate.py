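"""Fixed-step simulation of the coupled drive/slave FHN networks.

The integrator is deliberately a fixed-step scheme: classical four-stage
Runge-Kutta for the deterministic variants and Euler-Maruyama with additive
increments ``sqrt(2 D dt) z`` for the noisy ones.  Delayed gap junctions are
handled with a grid-aligned history buffer (constant pre-history equal to
the initial condition, linear interpolation between grid points), which is
what makes a common fixed grid across drive, slave, control and error
series possible.

Control convention
------------------
The two networks nominally both carry control inputs with ``u = u_x - u_y``
determined by the design; the drive is left unactuated (``u_x = 0``) and the
designed ``u`` is applied additively to the slave membrane equation.  The
half-error ``e = (drive - slave)/2`` therefore evolves with a ``-u/2``
control contribution, which is the convention pinned down by the dual-path
validation in :func:`integrate_error_system`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ControllerSchedule,
    DelayPair,
    NetworkConfig,
    cubic_term,
    variant_is_noisy,
)

#: Any state component beyond this magnitude aborts the run.
DIVERGENCE_LIMIT = 1e6


class SimulationDiverged(RuntimeError):
    """Raised when a state component exceeds :data:`DIVERGENCE_LIMIT`."""

    def __init__(self, t: float, max_abs: float):
        self.t = t
        self.max_abs = max_abs
        super().__init__(f"simulation diverged at t={t:.6g} (max |state| = {max_abs:.3g})")


@dataclass(frozen=True)
class ErrorState:
    """Half-difference synchronization errors ``e = (drive - slave)/2``.

    ``ex`` are the membrane errors, ``ey`` the recovery errors; in the
    delayed variants they are evaluated at the lagged time arguments
    ``t - tau1`` (drive) and ``t - tau2`` (slave).
    """

    ex: np.ndarray
    ey: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.ex, self.ey])


class HistoryBuffer:
    """Past states on the integration grid, with constant pre-history.

    ``lookup(t)`` is exact at grid points and linearly interpolated in
    between; for ``t <= 0`` it returns the initial state.  Lookups beyond
    the last stored step raise ``ValueError``.
    """

    def __init__(self, dim: int, dt: float, capacity: int, initial: np.ndarray):
        self.dt = dt
        self.data = np.empty((capacity + 1, dim))
        self.data[0] = initial
        self.filled = 0  # index of the last valid row

    def append(self, state: np.ndarray) -> None:
        self.filled += 1
        self.data[self.filled] = state

    def lookup(self, t: float) -> np.ndarray:
        if t <= 0.0:
            return self.data[0]
        idx = t / self.dt
        i0 = int(idx)
        frac = idx - i0
        if i0 > self.filled or (i0 == self.filled and frac > 1e-9):
            raise ValueError(
                f"history lookup at t={t:.6g} beyond stored horizon {self.filled * self.dt:.6g}"
            )
        if frac <= 1e-9:
            return self.data[i0]
        return self.data[i0] * (1.0 - frac) + self.data[i0 + 1] * frac


# ---------------------------------------------------------------------------
# Control laws


def control_nondelayed(err: ErrorState, t: float, cfg: NetworkConfig,
                       sched: ControllerSchedule) -> np.ndarray:
    """Adaptive error-feedback law for the non-delayed variants.

    Per neuron ``i``::

        u_i = 2 ex_i (g_i1 + (A/w) sin(w t) + b_i + c_i)
            - 2 ey_i (g_i2 - (A/w) cos(w t) - b_i - c_i)

    with ``g_i1, g_i2`` read from the coupling-matrix columns selected by
    ``sched.gain_columns`` (1-based; default columns 1 and 2).
    """
    if cfg.delays.is_delayed:
        raise ValueError("non-delayed control law called for a delayed configuration")
    w = cfg.ees.omega
    aw = cfg.ees.A / w
    j1, j2 = (c - 1 for c in sched.gain_columns)
    g1 = cfg.coupling.G[:, j1]
    g2 = cfg.coupling.G[:, j2]
    b = cfg.b_vec
    c = cfg.c_vec
    return (
        2.0 * err.ex * (g1 + aw * np.sin(w * t) + b + c)
        - 2.0 * err.ey * (g2 - aw * np.cos(w * t) - b - c)
    )


def control_delayed(err_lagged: ErrorState, cfg: NetworkConfig,
                    sched: ControllerSchedule) -> np.ndarray:
    """Lagged linear feedback law for the delayed variants.

    Per neuron ``i``: ``u_i = -g_i1 (b_i - c_i) ex_i - (b_i - c_i) ey_i``
    on the lagged errors.  Vanishes when ``b_i = c_i``.
    """
    if not cfg.delays.is_delayed:
        raise ValueError("delayed control law called for a non-delayed configuration")
    j1 = sched.gain_columns[0] - 1
    g1 = cfg.coupling.G[:, j1]
    bc = cfg.b_vec - cfg.c_vec
    return -g1 * bc * err_lagged.ex - bc * err_lagged.ey


def lag_error(drive_lookup, slave_lookup, t: float, delays: DelayPair) -> ErrorState:
    """Lagged half-errors ``(drive(t - tau1) - slave(t - tau2)) / 2``.

    ``drive_lookup``/``slave_lookup`` map a time to the length-``2n`` state
    of the respective network.  With ``tau1 = tau2 = 0`` this reduces to the
    instantaneous error.
    """
    xs = np.asarray(drive_lookup(t - delays.tau1), dtype=float)
    ys = np.asarray(slave_lookup(t - delays.tau2), dtype=float)
    n = xs.shape[0] // 2
    return ErrorState(ex=(xs[:n] - ys[:n]) / 2.0, ey=(xs[n:] - ys[n:]) / 2.0)


# ---------------------------------------------------------------------------
# Right-hand sides


def _network_rhs(state, t, cfg, coupling_membranes, u, noise_sample):
    n = cfg.n
    m = state[:n]
    rec = state[n:]
    dm = (
        cubic_term(m, cfg.r_vec)
        - rec
        + cfg.coupling.G @ coupling_membranes
        + cfg.ees.current(t)
        + cfg.disturbance_amplitudes * np.sin(cfg.disturbance_rates * t)
    )
    if u is not None:
        dm = dm + u
    if noise_sample is not None:
        dm = dm + noise_sample
    return np.concatenate([dm, cfg.b_vec * m - cfg.c_vec * rec])


def drive_rhs(state, t, cfg: NetworkConfig, hist: HistoryBuffer | None = None,
              noise_sample: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the drive network state (length ``2n``).

    ``hist`` must supply the drive's past joint state when the configuration
    is delayed; ``noise_sample`` is the white-noise value added to the
    membrane block in the noisy variants.  The drive carries no control.
    """
    if cfg.delays.is_delayed:
        if hist is None:
            raise ValueError("delayed configuration requires a history buffer")
        past = hist.lookup(t - cfg.delays.tau1)
        coupling_membranes = past[: cfg.n]
    else:
        coupling_membranes = state[: cfg.n]
    if variant_is_noisy(cfg.variant) and noise_sample is None:
        raise ValueError("noisy variant requires a noise sample")
    return _network_rhs(state, t, cfg, coupling_membranes, None, noise_sample)


def slave_rhs(state, t, cfg: NetworkConfig, hist: HistoryBuffer | None = None,
              noise_sample: np.ndarray | None = None,
              u: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the slave network state (length ``2n``).

    Identical structure to :func:`drive_rhs` with the slave delay ``tau2``;
    the applied control ``u`` enters the membrane equations only (additively)
    and the noise sample is the same realization as the drive's.
    """
    if cfg.delays.is_delayed:
        if hist is None:
            raise ValueError("delayed configuration requires a history buffer")
        past = hist.lookup(t - cfg.delays.tau2)
        coupling_membranes = past[: cfg.n]
    else:
        coupling_membranes = state[: cfg.n]
    if variant_is_noisy(cfg.variant) and noise_sample is None:
        raise ValueError("noisy variant requires a noise sample")
    return _network_rhs(state, t, cfg, coupling_membranes, u, noise_sample)


# ---------------------------------------------------------------------------
# Generic fixed steppers


def rk4_step(f, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    """One classical four-stage Runge-Kutta step of ``y' = f(t, y)``."""
    k1 = f(t, y)
    k2 = f(t + 0.5 * dt, y + 0.5 * dt * k1)
    k3 = f(t + 0.5 * dt, y + 0.5 * dt * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def euler_maruyama_step(f, t: float, y: np.ndarray, dt: float,
                        noise_increment: np.ndarray | None = None) -> np.ndarray:
    """One Euler-Maruyama step; with zero noise this is explicit Euler."""
    y1 = y + dt * f(t, y)
    if noise_increment is not None:
        y1 = y1 + noise_increment
    return y1


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class Trajectory:
    """Time-indexed result of one drive/slave run.

    ``drive``/``slave`` have shape ``(T, 2n)`` in the layout
    ``[membranes, recoveries]``; ``control`` ``(T, n)`` is the control
    applied to the slave membranes; ``errors`` ``(T, 2n)`` stacks the
    membrane and recovery half-errors (lagged ones for delayed variants).
    """

    times: np.ndarray
    drive: np.ndarray
    slave: np.ndarray
    control: np.ndarray
    errors: np.ndarray
    controller_active: np.ndarray
    dt: float
    method: str
    seed: int | None
    cfg: NetworkConfig
    sched: ControllerSchedule

    @property
    def n(self) -> int:
        return self.cfg.n

    def error_state(self, k: int) -> ErrorState:
        n = self.n
        return ErrorState(ex=self.errors[k, :n], ey=self.errors[k, n:])

    def drive_lookup(self, t: float) -> np.ndarray:
        return _interp_row(self.times, self.drive, t)

    def slave_lookup(self, t: float) -> np.ndarray:
        return _interp_row(self.times, self.slave, t)


def _interp_row(times: np.ndarray, data: np.ndarray, t: float) -> np.ndarray:
    if t <= times[0]:
        return data[0]
    if t >= times[-1]:
        return data[-1]
    idx = (t - times[0]) / (times[1] - times[0])
    i0 = int(idx)
    frac = idx - i0
    if frac <= 1e-12:
        return data[i0]
    return data[i0] * (1.0 - frac) + data[i0 + 1] * frac


def run_simulation(cfg: NetworkConfig, sched: ControllerSchedule, t_end: float,
                   dt: float = 0.005, seed: int | None = None,
                   method: str | None = None) -> Trajectory:
    """Integrate a drive/slave pair on a uniform grid.

    The control is the zero vector for ``t < sched.t_on`` and the scheduled
    law thereafter.  ``method`` is ``"rk4"`` (default for non-noisy
    configurations) or ``"euler"`` (Euler-Maruyama; required, and default,
    for noisy ones).  ``seed`` feeds the single per-run noise generator and
    defaults to ``cfg.noise.seed``; a run is reproducible from
    ``(cfg, sched, t_end, dt, seed, method)`` alone.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    noisy = variant_is_noisy(cfg.variant)
    if method is None:
        method = "euler" if noisy else "rk4"
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")
    if noisy and method != "euler":
        raise ValueError("noisy variants integrate with the Euler-Maruyama scheme")
    if sched.law == "delayed" and not cfg.delays.is_delayed:
        raise ValueError("delayed control law requires a delayed variant")
    if sched.law == "nondelayed" and cfg.delays.is_delayed:
        raise ValueError("non-delayed control law requires a non-delayed variant")
    delayed = cfg.delays.is_delayed
    for tau in (cfg.delays.tau1, cfg.delays.tau2):
        if 0.0 < tau < dt:
            raise ValueError(f"delay {tau} smaller than the step {dt} is not supported")

    n = cfg.n
    steps = int(round(t_end / dt))
    if steps < 1:
        raise ValueError("t_end must span at least one step")

    S = np.concatenate([cfg.drive_ic, cfg.effective_slave_ic()])
    hist = HistoryBuffer(4 * n, dt, steps, S) if delayed else None

    # flatten config onto locals for the hot loop
    G = cfg.coupling.G
    r, b, c = cfg.r_vec, cfg.b_vec, cfg.c_vec
    amp, rate = cfg.disturbance_amplitudes, cfg.disturbance_rates
    A, w = cfg.ees.A, cfg.ees.omega
    aw = A / w
    tau1, tau2 = cfg.delays.tau1, cfg.delays.tau2
    law, t_on = sched.law, sched.t_on
    j1, j2 = (col - 1 for col in sched.gain_columns)
    g1, g2 = G[:, j1], G[:, j2]
    bc = b - c

    def control_at(t, xm, xr, ym, yr):
        if law == "none" or t < t_on:
            return None
        if law == "nondelayed":
            ex = (xm - ym) / 2.0
            ey = (xr - yr) / 2.0
            return (2.0 * ex * (g1 + aw * np.sin(w * t) + b + c)
                    - 2.0 * ey * (g2 - aw * np.cos(w * t) - b - c))
        # delayed law: lagged errors from history
        xs = hist.lookup(t - tau1)
        ys = hist.lookup(t - tau2)
        ex = (xs[:n] - ys[2 * n:3 * n]) / 2.0
        ey = (xs[n:2 * n] - ys[3 * n:]) / 2.0
        return -g1 * bc * ex - bc * ey

    def joint_rhs(t, SS):
        xm, xr = SS[:n], SS[n:2 * n]
        ym, yr = SS[2 * n:3 * n], SS[3 * n:]
        if delayed:
            cx = G @ hist.lookup(t - tau1)[:n]
            cy = G @ hist.lookup(t - tau2)[2 * n:3 * n]
        else:
            cx = G @ xm
            cy = G @ ym
        I = aw * np.cos(w * t)
        d = amp * np.sin(rate * t)
        u = control_at(t, xm, xr, ym, yr)
        dym = cubic_term(ym, r) - yr + cy + I + d
        if u is not None:
            dym = dym + u
        return np.concatenate([
            cubic_term(xm, r) - xr + cx + I + d,
            b * xm - c * xr,
            dym,
            b * ym - c * yr,
        ])

    rng = None
    sigma = 0.0
    if noisy:
        if seed is None:
            seed = cfg.noise.seed
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(2.0 * cfg.noise.D * dt)

    states = np.empty((steps + 1, 4 * n))
    states[0] = S
    for k in range(steps):
        t = k * dt
        if method == "rk4":
            S = rk4_step(joint_rhs, t, S, dt)
        else:
            S = S + dt * joint_rhs(t, S)
            if noisy:
                z = rng.standard_normal(n)
                inc = sigma * z
                S[:n] += inc
                if cfg.noise.common:
                    S[2 * n:3 * n] += inc
                else:
                    S[2 * n:3 * n] += sigma * rng.standard_normal(n)
        max_abs = np.max(np.abs(S))
        if not np.isfinite(max_abs) or max_abs > DIVERGENCE_LIMIT:
            raise SimulationDiverged((k + 1) * dt, float(max_abs))
        states[k + 1] = S
        if delayed:
            hist.append(S)

    times = np.arange(steps + 1) * dt
    drive = states[:, :2 * n]
    slave = states[:, 2 * n:]

    # errors: instantaneous for non-delayed, lagged for delayed variants
    errors = np.empty((steps + 1, 2 * n))
    if not delayed:
        errors[:] = (drive - slave) / 2.0
    else:
        for k in range(steps + 1):
            xs = hist.lookup(max(times[k] - tau1, 0.0))
            ys = hist.lookup(max(times[k] - tau2, 0.0))
            errors[k, :n] = (xs[:n] - ys[2 * n:3 * n]) / 2.0
            errors[k, n:] = (xs[n:2 * n] - ys[3 * n:]) / 2.0

    control = np.zeros((steps + 1, n))
    active = np.zeros(steps + 1, dtype=bool)
    for k in range(steps + 1):
        t = times[k]
        if law != "none" and t >= t_on:
            active[k] = True
            u = control_at(t, drive[k, :n], drive[k, n:], slave[k, :n], slave[k, n:])
            if u is not None:
                control[k] = u

    return Trajectory(
        times=times, drive=drive, slave=slave, control=control, errors=errors,
        controller_active=active, dt=dt, method=method,
        seed=seed if noisy else None, cfg=cfg, sched=sched,
    )


# ---------------------------------------------------------------------------
# Error-system validation path


def error_system_rhs(err: ErrorState, t: float, shared_r: float,
                     cfg: NetworkConfig, u: np.ndarray, cd: np.ndarray,
                     sd: np.ndarray, strict: bool = True) -> ErrorState:
    """Right-hand side of the reduced synchronization-error system.

    ``e_x' = -(r/2) c_d + ((1+r)/2) s_d - e_x - e_y + G e_x + u`` and
    ``e_y' = b e_x - c e_y``, with ``c_d = x^3 - y^3`` and
    ``s_d = x^2 - y^2`` supplied from the state trajectories.  The reduction
    assumes a single shared cubic steepness ``r``; with ``strict`` a
    heterogeneous configuration is rejected.

    This is a validation path: integrating it alongside a direct simulation
    (with the matched control ``u = -u_applied/2``) must reproduce the
    directly computed error trajectory.
    """
    if strict and not np.allclose(cfg.r_vec, shared_r):
        raise ValueError("error system assumes a single shared r across neurons")
    dex = (
        -0.5 * shared_r * np.asarray(cd)
        + 0.5 * (1.0 + shared_r) * np.asarray(sd)
        - err.ex
        - err.ey
        + cfg.coupling.G @ err.ex
        + np.asarray(u)
    )
    dey = cfg.b_vec * err.ex - cfg.c_vec * err.ey
    return ErrorState(ex=dex, ey=dey)


def integrate_error_system(traj: Trajectory, shared_r: float | None = None,
                           t_end: float | None = None) -> np.ndarray:
    """Replay the reduced error system along a stored trajectory.

    The cubic and square state differences and the applied control are read
    (with linear interpolation) from ``traj``; the matched control entering
    the error system is ``-u_applied/2``.  Returns the ``(T, 2n)`` error
    series on the trajectory grid up to ``t_end``, for comparison with
    ``traj.errors``.  Requires a non-delayed configuration.
    """
    cfg = traj.cfg
    if cfg.delays.is_delayed:
        raise ValueError("error-system replay supports the non-delayed variants")
    if shared_r is None:
        shared_r = float(cfg.r_vec[0])
    n = cfg.n
    times = traj.times
    if t_end is not None:
        stop = int(np.searchsorted(times, t_end + 1e-12))
        times = times[:stop]
    dt = traj.dt
    G = cfg.coupling.G
    b, c = cfg.b_vec, cfg.c_vec

    def rhs(t, e):
        xs = _interp_row(traj.times, traj.drive, t)
        ys = _interp_row(traj.times, traj.slave, t)
        xm, ym = xs[:n], ys[:n]
        cd = xm**3 - ym**3
        sd = xm**2 - ym**2
        u = -0.5 * _interp_row(traj.times, traj.control, t)
        ex, ey = e[:n], e[n:]
        dex = (-0.5 * shared_r * cd + 0.5 * (1.0 + shared_r) * sd
               - ex - ey + G @ ex + u)
        return np.concatenate([dex, b * ex - c * ey])

    out = np.empty((len(times), 2 * n))
    e = traj.errors[0].copy()
    out[0] = e
    for k in range(len(times) - 1):
        e = rk4_step(rhs, times[k], e, dt)
        out[k + 1] = e
    return out
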