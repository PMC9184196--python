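"""Numerical Lyapunov-stability diagnostics for the synchronization errors.

The candidate function is the quadratic form ``V = (|e_x|^2 + |e_y|^2) / 2``.
Along a simulated run its decay (or failure to decay) is measured with
centered finite differences.  The sufficient-condition side of the analysis
is embodied by a block matrix ``P`` assembled from the error-dynamics bound;
``V' <= -E P E^T`` holds when ``P`` is positive definite.  Two
positive-definiteness tests are reported side by side:

* the leading-principal-minors test applied to ``P`` exactly as assembled
  (Sylvester's criterion, which is only conclusive for symmetric matrices),
* the mathematically binding test ``x^T P x > 0  <=>  (P + P^T)/2`` has
  positive eigenvalues.

``P`` is not symmetric here (its off-diagonal blocks differ), so the two
verdicts can disagree; both are recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .model import ControllerSchedule, NetworkConfig
from .simulate import ErrorState, Trajectory


def lyapunov_V(err: ErrorState) -> float:
    """``V = (|e_x|^2 + |e_y|^2) / 2``; positive definite in the error."""
    return 0.5 * (float(np.dot(err.ex, err.ex)) + float(np.dot(err.ey, err.ey)))


def V_series(traj: Trajectory) -> np.ndarray:
    """``V`` evaluated at every stored time."""
    return 0.5 * np.einsum("ij,ij->i", traj.errors, traj.errors)


def vdot_series(traj: Trajectory):
    """Centered finite differences of ``V`` along the trajectory.

    Returns ``(times, vdot)`` of length ``T - 2`` (interior points only).
    """
    if len(traj.times) < 3:
        raise ValueError("need at least three trajectory points")
    V = V_series(traj)
    dt = traj.dt
    vdot = (V[2:] - V[:-2]) / (2.0 * dt)
    return traj.times[1:-1], vdot


# ---------------------------------------------------------------------------
# P matrices


def _scalar_terms(cfg: NetworkConfig, sched: ControllerSchedule, neuron_index: int):
    i = neuron_index - 1
    if not 0 <= i < cfg.n:
        raise ValueError(f"neuron_index must be in 1..{cfg.n}")
    j1, j2 = (col - 1 for col in sched.gain_columns)
    g1 = float(cfg.coupling.G[i, j1])
    g2 = float(cfg.coupling.G[i, j2])
    b = float(cfg.b_vec[i])
    c = float(cfg.c_vec[i])
    return g1, g2, b, c


def build_P_nondelayed(t: float, cfg: NetworkConfig, sched: ControllerSchedule,
                       shared_r: float | None = None, neuron_index: int = 1,
                       q_factors: bool = False, q1: float = 0.0,
                       q2: float = 0.0) -> np.ndarray:
    """Time-dependent ``2n x 2n`` stability matrix of the non-delayed bound.

    Blocks (scalars broadcast onto identity blocks, ``a = A/w``)::

        P11 = [1/(2r) - (1+r)/2 + 1 - 2 g_i1 - 2 a sin(wt) - 2 b - 2 c] I - 2 G
        P12 = [1 + 2 g_i2 - 2 a cos(wt) - 2 b - 2 c] I
        P21 = -b I          P22 = c I

    ``neuron_index`` (1-based) selects which row supplies ``g_i1, g_i2`` and
    the scalars ``b, c``; ``shared_r`` defaults to the first neuron's ``r``
    (the error-system reduction uses a single ``r``).  With ``q_factors``
    the first two terms are weighted by the trajectory bounds ``q2``/``q1``
    (``1/(2r) q2 - (1+r)/2 q1``), the variant consistent with the bound the
    blocks were derived from; the default builds the matrix exactly in its
    plain printed form.
    """
    if cfg.delays.is_delayed:
        raise ValueError("non-delayed stability matrix requested for a delayed configuration")
    if shared_r is None:
        shared_r = float(cfg.r_vec[0])
    n = cfg.n
    g1, g2, b, c = _scalar_terms(cfg, sched, neuron_index)
    w = cfg.ees.omega
    aw = cfg.ees.A / w
    I = np.eye(n)
    if q_factors:
        lead = (1.0 / (2.0 * shared_r)) * q2 - 0.5 * (1.0 + shared_r) * q1
    else:
        lead = 1.0 / (2.0 * shared_r) - 0.5 * (1.0 + shared_r)
    p11 = (lead + 1.0 - 2.0 * g1 - 2.0 * aw * np.sin(w * t)
           - 2.0 * b - 2.0 * c) * I - 2.0 * cfg.coupling.G
    p12 = (1.0 + 2.0 * g2 - 2.0 * aw * np.cos(w * t) - 2.0 * b - 2.0 * c) * I
    return np.block([[p11, p12], [-b * I, c * I]])


def build_P_delayed(cfg: NetworkConfig, sched: ControllerSchedule,
                    shared_r: float | None = None, q1: float = 0.0,
                    q2: float = 0.0, neuron_index: int = 1) -> np.ndarray:
    """Time-independent ``2n x 2n`` stability matrix of the delayed bound.

    Blocks::

        P11 = [q2/(2r) - (1+r) q1/2 + 1 + g_i1 b - g_i1 c] I - G
        P12 = [1 + b - c] I
        P21 = -b I          P22 = c I

    ``q1``/``q2`` are the trajectory bounds on ``|x| + |y|`` and on the
    cubic-difference factor (see :func:`estimate_bounds_q`).
    """
    if not cfg.delays.is_delayed:
        raise ValueError("delayed stability matrix requested for a non-delayed configuration")
    if q1 < 0 or q2 < 0:
        raise ValueError("q bounds must be non-negative")
    if shared_r is None:
        shared_r = float(cfg.r_vec[0])
    n = cfg.n
    g1, _, b, c = _scalar_terms(cfg, sched, neuron_index)
    I = np.eye(n)
    p11 = ((1.0 / (2.0 * shared_r)) * q2 - 0.5 * (1.0 + shared_r) * q1
           + 1.0 + g1 * b - g1 * c) * I - cfg.coupling.G
    p12 = (1.0 + b - c) * I
    return np.block([[p11, p12], [-b * I, c * I]])


def estimate_bounds_q(traj: Trajectory, margin: float = 0.0):
    """Trajectory bounds used in the delayed stability matrix.

    ``q1 = (1+margin) max_i (max_t |x_i| + max_t |y_i|)`` bounds
    ``|x_i| + |y_i|``; ``q2 = (1+margin) max_{i,t} (x^2 + |x||y| + y^2)``
    bounds the factor in ``|x^3 - y^3| <= q2 |x - y|``.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    n = traj.n
    xm = traj.drive[:, :n]
    ym = traj.slave[:, :n]
    q1 = float(np.max(np.abs(xm).max(axis=0) + np.abs(ym).max(axis=0)))
    q2 = float(np.max(xm**2 + np.abs(xm) * np.abs(ym) + ym**2))
    return (1.0 + margin) * q1, (1.0 + margin) * q2


# ---------------------------------------------------------------------------
# Positive-definiteness tests


def leading_principal_minors(M: np.ndarray) -> np.ndarray:
    """Determinants of the top-left ``k x k`` submatrices, ``k = 1..m``."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    return np.array([np.linalg.det(M[:k, :k]) for k in range(1, M.shape[0] + 1)])


def pd_verdict(M: np.ndarray):
    """Two positive-definiteness verdicts: raw minors, and symmetric part.

    ``pd_by_minors`` applies Sylvester's criterion to ``M`` as given (the
    test is conclusive only for symmetric matrices).
    ``pd_by_eigen_symmetric_part`` checks all eigenvalues of
    ``(M + M^T)/2``, which is equivalent to ``x^T M x > 0`` for all
    ``x != 0``.  On symmetric input the two always agree.
    """
    minors = leading_principal_minors(M)
    pd_minors = bool(np.all(minors > 0))
    sym = 0.5 * (np.asarray(M) + np.asarray(M).T)
    eigs = np.linalg.eigvalsh(sym)
    return pd_minors, bool(np.all(eigs > 0))


@dataclass
class StabilityReport:
    """P matrix, its minors, PD verdicts and the trajectory bounds."""

    P: np.ndarray
    minors: np.ndarray
    pd_by_minors: bool
    pd_by_eigen_symmetric_part: bool
    q1: float | None
    q2: float | None
    t_evaluated: object  # a time, or "sweep"
    min_eig_over_sweep: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["P"] = [[float(v) for v in row] for row in self.P]
        d["minors"] = [float(v) for v in self.minors]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pd_sweep_over_period(cfg: NetworkConfig, sched: ControllerSchedule,
                         shared_r: float | None = None,
                         n_samples: int = 64, neuron_index: int = 1,
                         t0: float = 0.0) -> StabilityReport:
    """Evaluate the non-delayed ``P`` across one EES period.

    Samples ``n_samples`` times spanning ``[t0, t0 + 1/f)``, records the
    per-sample minors verdict and the minimum symmetric-part eigenvalue over
    the sweep.  The stored matrix/minors belong to the worst (smallest
    minimum eigenvalue) sample.  Verdicts are reported, not asserted.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    period = 1.0 / cfg.ees.f
    ts = t0 + period * np.arange(n_samples) / n_samples
    min_eig = np.inf
    worst = None
    pd_minors_all = True
    pd_eig_all = True
    for t in ts:
        P = build_P_nondelayed(t, cfg, sched, shared_r, neuron_index)
        pm, pe = pd_verdict(P)
        pd_minors_all &= pm
        pd_eig_all &= pe
        e = float(np.linalg.eigvalsh(0.5 * (P + P.T))[0])
        if e < min_eig:
            min_eig = e
            worst = (float(t), P)
    t_worst, P_worst = worst
    return StabilityReport(
        P=P_worst,
        minors=leading_principal_minors(P_worst),
        pd_by_minors=pd_minors_all,
        pd_by_eigen_symmetric_part=pd_eig_all,
        q1=None,
        q2=None,
        t_evaluated="sweep" if n_samples > 1 else t_worst,
        min_eig_over_sweep=min_eig,
    )


def delayed_stability_report(cfg: NetworkConfig, sched: ControllerSchedule,
                             traj: Trajectory, margin: float = 0.0,
                             shared_r: float | None = None,
                             neuron_index: int = 1) -> StabilityReport:
    """Full delayed pipeline: trajectory bounds, then ``P`` and verdicts."""
    q1, q2 = estimate_bounds_q(traj, margin=margin)
    P = build_P_delayed(cfg, sched, shared_r, q1, q2, neuron_index)
    pm, pe = pd_verdict(P)
    return StabilityReport(
        P=P,
        minors=leading_principal_minors(P),
        pd_by_minors=pm,
        pd_by_eigen_symmetric_part=pe,
        q1=q1,
        q2=q2,
        t_evaluated=None,
        min_eig_over_sweep=float(np.linalg.eigvalsh(0.5 * (P + P.T))[0]),
    )
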