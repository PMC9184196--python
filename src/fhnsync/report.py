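"""Synchronization metrics, exports and figures."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import config_to_dict
from .simulate import Trajectory

#: "Converged to zero" operationalized: max-norm error below this ...
DEFAULT_TOL = 1e-3
#: ... sustained for this many time units.
DEFAULT_HOLD = 10.0


def sync_error_norm(traj: Trajectory, norm: str = "max") -> np.ndarray:
    """Per-time norm over all ``2n`` error components (``"max"`` or ``"l2"``)."""
    if norm == "max":
        return np.abs(traj.errors).max(axis=1)
    if norm == "l2":
        return np.sqrt((traj.errors**2).sum(axis=1))
    raise ValueError(f"unknown norm {norm!r}")


@dataclass(frozen=True)
class ConvergenceResult:
    """Outcome of the sustained-threshold convergence test."""

    converged: bool
    t_converge: float | None
    sup_error_after: float
    tol: float
    hold: float


def convergence_time(traj: Trajectory, tol: float = DEFAULT_TOL,
                     hold: float = DEFAULT_HOLD) -> ConvergenceResult:
    """First ``t >= t_on`` with max-norm error below ``tol`` on ``[t, t+hold]``.

    ``sup_error_after`` is the supremum of the max-norm error from that time
    to the end of the run (``inf`` when never converged).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if hold < 0:
        raise ValueError("hold must be non-negative")
    times = traj.times
    if times[-1] - traj.sched.t_on < hold:
        raise ValueError("holding duration exceeds the horizon after t_on")
    m = sync_error_norm(traj, "max")
    k0 = int(np.searchsorted(times, traj.sched.t_on))
    nhold = int(round(hold / traj.dt))
    below = m < tol
    for k in range(k0, len(times) - nhold):
        if below[k : k + nhold + 1].all():
            return ConvergenceResult(
                converged=True,
                t_converge=float(times[k]),
                sup_error_after=float(m[k:].max()),
                tol=tol,
                hold=hold,
            )
    return ConvergenceResult(False, None, float("inf"), tol, hold)


def phase_plane_pairs(traj: Trajectory, neuron: int, block: str = "membrane"):
    """Paired (drive, slave) series for one neuron's phase-plane diagram.

    ``neuron`` is 1-based; ``block`` selects ``"membrane"`` or
    ``"recovery"``.  When the networks are synchronized the point cloud
    collapses onto the identity diagonal.
    """
    n = traj.n
    if not 1 <= neuron <= n:
        raise ValueError(f"neuron must be in 1..{n}")
    off = 0 if block == "membrane" else n
    if block not in ("membrane", "recovery"):
        raise ValueError(f"unknown block {block!r}")
    j = off + neuron - 1
    return traj.drive[:, j], traj.slave[:, j]


# ---------------------------------------------------------------------------
# Export


_STATE_NAMES = ("membrane", "recovery")


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format view: time, network, neuron (1-based), state, value."""
    n = traj.n
    frames = []
    for network, data in (("drive", traj.drive), ("slave", traj.slave)):
        for block, name in enumerate(_STATE_NAMES):
            for i in range(n):
                frames.append(pd.DataFrame({
                    "time": traj.times,
                    "network": network,
                    "neuron": i + 1,
                    "state": name,
                    "value": data[:, block * n + i],
                }))
    for block, name in enumerate(("error_membrane", "error_recovery")):
        for i in range(n):
            frames.append(pd.DataFrame({
                "time": traj.times,
                "network": "error",
                "neuron": i + 1,
                "state": name,
                "value": traj.errors[:, block * n + i],
            }))
    for i in range(n):
        frames.append(pd.DataFrame({
            "time": traj.times,
            "network": "control",
            "neuron": i + 1,
            "state": "control",
            "value": traj.control[:, i],
        }))
    return pd.concat(frames, ignore_index=True)


def export_run(traj: Trajectory, path, stability=None, hdf5: bool = False) -> dict:
    """Write a run to ``path``: trajectory CSV, metadata JSON, optional extras.

    Values are printed with 17 significant digits, so re-reading reproduces
    the series exactly.  Returns the mapping of written files.  ``stability``
    is an optional :class:`~fhnsync.lyapunov.StabilityReport`; with ``hdf5``
    the full arrays are additionally stored in a compact HDF5 container.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    path.mkdir(parents=True, exist_ok=True)
    written = {}

    csv_path = path / "trajectory.csv"
    trajectory_frame(traj).to_csv(csv_path, index=False, float_format="%.17g")
    written["trajectory"] = csv_path

    meta = {
        "config": config_to_dict(traj.cfg, traj.sched),
        "seed": traj.seed,
        "dt": traj.dt,
        "method": traj.method,
        "t_end": float(traj.times[-1]),
    }
    meta_path = path / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    written["metadata"] = meta_path

    if stability is not None:
        sp = path / "stability.json"
        stability.to_json(sp)
        written["stability"] = sp

    if hdf5:
        import h5py

        hp = path / "trajectory.h5"
        with h5py.File(hp, "w") as h5:
            for name in ("times", "drive", "slave", "control", "errors"):
                h5.create_dataset(name, data=getattr(traj, name))
            h5.create_dataset("controller_active",
                              data=traj.controller_active.astype(np.uint8))
            h5.attrs["metadata"] = json.dumps(meta)
        written["hdf5"] = hp
    return written


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read back a long-format trajectory CSV, bit-exactly."""
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Figures


def _panel_grid(n):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 2.8), squeeze=False)
    return plt, fig, axes[0]


def plot_errors(traj: Trajectory, uncontrolled: Trajectory | None = None,
                path=None, block: str = "membrane"):
    """Per-neuron error time-series panels; one panel per neuron.

    The controlled run is drawn in red, an optional uncontrolled twin in
    blue, with a vertical marker at the controller activation time.
    Returns the figure.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    n = traj.n
    off = 0 if block == "membrane" else n
    plt, fig, axes = _panel_grid(n)
    for i, ax in enumerate(axes):
        if uncontrolled is not None:
            ax.plot(uncontrolled.times, uncontrolled.errors[:, off + i],
                    color="tab:blue", lw=0.7, label="without control")
        ax.plot(traj.times, traj.errors[:, off + i],
                color="tab:red", lw=0.7, label="with control")
        if traj.sched.law != "none":
            ax.axvline(traj.sched.t_on, color="k", ls=":", lw=0.8)
        ax.set_title(f"$e_{{{'x' if block == 'membrane' else 'y'}_{{{i+1}1}}}}$")
        ax.set_xlabel("t")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_phase(traj: Trajectory, uncontrolled: Trajectory | None = None,
               path=None, block: str = "membrane"):
    """Per-neuron drive-vs-slave phase-plane panels.

    Synchronized segments collapse onto the identity diagonal.  Returns the
    figure.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    n = traj.n
    plt, fig, axes = _panel_grid(n)
    for i, ax in enumerate(axes):
        if uncontrolled is not None:
            dx, sx = phase_plane_pairs(uncontrolled, i + 1, block)
            ax.plot(dx, sx, color="tab:blue", lw=0.5, label="without control")
        dx, sx = phase_plane_pairs(traj, i + 1, block)
        ax.plot(dx, sx, color="tab:red", lw=0.5, label="with control")
        sub = "1" if block == "membrane" else "2"
        ax.set_xlabel(f"$x_{{{i+1}{sub}}}$")
        ax.set_ylabel(f"$y_{{{i+1}{sub}}}$")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
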