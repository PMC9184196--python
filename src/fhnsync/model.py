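"""Model ingredients for coupled FitzHugh-Nagumo (FHN) drive/slave networks.

Each neuron is a two-variable FHN unit: a membrane potential ``x`` with the
cubic nonlinearity ``x(x-1)(1-r x)`` and a linear recovery variable driven by
``b x - c w``.  Every neuron receives the same external electrical
stimulation (EES) current ``(A/w) cos(w t)`` with ``w = 2 pi f``, a small
sinusoidal ionic-gate disturbance, and diffusive gap-junction input from the
other neurons of its own network.  A drive network and a structurally
identical slave network form a master/slave pair; the slave carries the
control input that is supposed to synchronize it to the drive.

Four variants are distinguished by whether the gap-junction terms are
delayed and whether a common additive Gaussian noise acts on the membranes:

* ``nondelayed_nonnoisy`` / ``nondelayed_noisy``
* ``delayed_nonnoisy`` / ``delayed_noisy``

In the delayed variants the drive coupling is evaluated at ``t - tau1`` and
the slave coupling at ``t - tau2``; synchronization is then judged on the
lagged half-errors ``(x(t-tau1) - y(t-tau2))/2`` (lag synchronization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coupling import CouplingMatrix

VARIANTS = (
    "nondelayed_nonnoisy",
    "nondelayed_noisy",
    "delayed_nonnoisy",
    "delayed_noisy",
)

CONTROL_LAWS = ("nondelayed", "delayed", "none")


def variant_is_delayed(variant: str) -> bool:
    return variant.startswith("delayed")


def variant_is_noisy(variant: str) -> bool:
    return variant.endswith("_noisy")


def cubic_term(x, r):
    """FHN membrane nonlinearity ``x (x - 1) (1 - r x)``.

    Vanishes at ``x`` in ``{0, 1, 1/r}``; ``r > 0`` sets the position of the
    third root and thereby the steepness of the cubic.
    """
    return x * (x - 1.0) * (1.0 - r * x)


@dataclass(frozen=True)
class FHNNeuronParams:
    """Positive per-neuron parameters: cubic steepness ``r``, recovery gain
    ``b`` and recovery decay ``c``."""

    r: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("r", "b", "c"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")


@dataclass(frozen=True)
class EESDrive:
    """External electrical stimulation ``I(t) = (A / w) cos(w t)``.

    ``w = 2 pi f`` is always derived from the frequency ``f``; it is never an
    independent field, which rules out inconsistent ``A/w`` factors.  The
    same stimulation acts on every neuron of both networks.
    """

    A: float
    f: float

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.f

    def current(self, t):
        if self.f == 0:
            raise ValueError("EES frequency must be nonzero")
        w = self.omega
        return (self.A / w) * np.cos(w * np.asarray(t, dtype=float))


def ees_current(ees: EESDrive, t):
    """Evaluate the EES current; bounded by ``A/w`` and ``1/f``-periodic."""
    return ees.current(t)


@dataclass(frozen=True)
class IonicDisturbance:
    """Deterministic ionic-gate disturbance ``d(t) = amplitude sin(rate t)``."""

    amplitude: float
    rate: float

    def value(self, t):
        return self.amplitude * np.sin(self.rate * np.asarray(t, dtype=float))


def disturbance_value(d: IonicDisturbance, t):
    return d.value(t)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian membrane noise of intensity ``D``.

    The discretized increments have variance ``2 D dt`` (white noise with
    correlation ``2 D delta(t - t')``).  With ``common=True`` (the default)
    the drive and slave membranes receive the *same* realization, so the
    noise cancels exactly in the drive-slave difference.
    """

    D: float
    seed: int = 0
    common: bool = True

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"noise intensity D must be non-negative, got {self.D}")


@dataclass(frozen=True)
class DelayPair:
    """Gap-junction delays: ``tau1`` for the drive, ``tau2`` for the slave.

    ``(0, 0)`` selects the non-delayed model.  Unequal delays make the
    synchronization target a *lag*: the slave should track the drive shifted
    by ``tau1 - tau2``.
    """

    tau1: float = 0.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be non-negative")

    @property
    def is_delayed(self) -> bool:
        return self.tau1 > 0 or self.tau2 > 0

    @property
    def max_delay(self) -> float:
        return max(self.tau1, self.tau2)


@dataclass(frozen=True)
class NetworkConfig:
    """Full specification of one drive/slave experiment.

    ``drive_ic`` and ``slave_ic`` are length-``2n`` state vectors laid out as
    ``[membrane_1..membrane_n, recovery_1..recovery_n]``.
    ``slave_ic_perturbation`` is an additive offset applied to each slave
    membrane initial condition; it exists because with exactly identical
    initial conditions the uncontrolled non-delayed drive and slave are the
    same trajectory and the error is identically zero.
    """

    n: int
    params: tuple  # of FHNNeuronParams
    ees: EESDrive
    disturbances: tuple  # of IonicDisturbance
    coupling: CouplingMatrix
    delays: DelayPair = DelayPair()
    noise: NoiseSpec | None = None
    drive_ic: np.ndarray = None
    slave_ic: np.ndarray = None
    slave_ic_perturbation: float = 0.0
    variant: str = "nondelayed_nonnoisy"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        n = self.n
        object.__setattr__(self, "params", tuple(self.params))
        object.__setattr__(self, "disturbances", tuple(self.disturbances))
        if len(self.params) != n:
            raise ValueError(f"need {n} neuron parameter sets, got {len(self.params)}")
        if len(self.disturbances) != n:
            raise ValueError(f"need {n} disturbances, got {len(self.disturbances)}")
        if self.coupling.n != n:
            raise ValueError(f"coupling matrix is {self.coupling.n}x{self.coupling.n}, expected {n}x{n}")
        for name in ("drive_ic", "slave_ic"):
            ic = np.asarray(getattr(self, name), dtype=float)
            if ic.shape != (2 * n,):
                raise ValueError(f"{name} must have shape ({2*n},), got {ic.shape}")
            object.__setattr__(self, name, ic)
        if self.slave_ic_perturbation < 0:
            raise ValueError("slave_ic_perturbation must be non-negative")
        if variant_is_delayed(self.variant) != self.delays.is_delayed:
            raise ValueError(
                f"variant {self.variant!r} inconsistent with delays {self.delays}"
            )
        if variant_is_noisy(self.variant) != (self.noise is not None):
            raise ValueError(
                f"variant {self.variant!r} inconsistent with noise={self.noise!r}"
            )

    # Per-neuron parameter vectors, used throughout the numerics.
    @property
    def r_vec(self) -> np.ndarray:
        return np.array([p.r for p in self.params])

    @property
    def b_vec(self) -> np.ndarray:
        return np.array([p.b for p in self.params])

    @property
    def c_vec(self) -> np.ndarray:
        return np.array([p.c for p in self.params])

    @property
    def disturbance_amplitudes(self) -> np.ndarray:
        return np.array([d.amplitude for d in self.disturbances])

    @property
    def disturbance_rates(self) -> np.ndarray:
        return np.array([d.rate for d in self.disturbances])

    def effective_slave_ic(self) -> np.ndarray:
        """Slave initial condition with the membrane perturbation applied."""
        ic = self.slave_ic.copy()
        ic[: self.n] += self.slave_ic_perturbation
        return ic


@dataclass(frozen=True)
class ControllerSchedule:
    """Which control law acts on the slave, and from when.

    ``law`` is one of ``"nondelayed"`` (the trigonometric error-feedback law
    for the non-delayed variants), ``"delayed"`` (the lagged linear feedback
    law for the delayed variants) or ``"none"``.  The control is the zero
    vector for ``t < t_on``.  ``gain_columns`` are the 1-based columns of the
    coupling matrix supplying the per-neuron gains ``g_i1``, ``g_i2`` of the
    non-delayed law.
    """

    law: str = "none"
    t_on: float = 0.0
    gain_columns: tuple = (1, 2)

    def __post_init__(self) -> None:
        if self.law not in CONTROL_LAWS:
            raise ValueError(f"unknown control law {self.law!r}; expected one of {CONTROL_LAWS}")
        if self.t_on < 0:
            raise ValueError("t_on must be non-negative")
        if len(self.gain_columns) != 2:
            raise ValueError("gain_columns must be a pair of 1-based column indices")

    def active(self, t: float) -> bool:
        return self.law != "none" and t >= self.t_on
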