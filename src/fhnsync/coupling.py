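"""Gap-junction coupling matrices.

A gap-junction matrix ``G`` couples the membrane potentials of the neurons in
one network through the diffusive term ``(G @ membrane)_i``.  Its entries obey

* ``g_ij >= 0`` for ``i != j`` (electrical junctions are non-negative; a zero
  entry means the pair is not connected),
* ``g_ii = -sum_{j != i} g_ij`` (each diagonal entry balances its row).

The zero-row-sum structure (the negative of a weighted graph Laplacian) is the
conservation property the simulator relies on: when all membrane potentials
are equal the coupling term vanishes identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default validation tolerance.  The bundled five-neuron matrix is printed to
#: five significant figures, so its row sums cancel only to ~1e-7.
DEFAULT_TOL = 5e-7

#: Tolerance for matrices constructed exactly from their off-diagonal part.
EXACT_TOL = 1e-12


@dataclass(frozen=True)
class CouplingMatrix:
    """An ``n x n`` gap-junction matrix with zero row sums."""

    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError(f"coupling matrix must be square, got shape {G.shape}")
        object.__setattr__(self, "G", G)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def validate(self, tol: float = DEFAULT_TOL) -> "ValidationReport":
        return validate_coupling(self.G, tol=tol)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a matrix against the gap-junction constraints."""

    valid: bool
    max_row_sum_abs: float
    violations: tuple = field(default_factory=tuple)


def validate_coupling(G: np.ndarray, tol: float = DEFAULT_TOL) -> ValidationReport:
    """Check the sign and row-sum constraints of a gap-junction matrix.

    Three conditions are verified: off-diagonal entries are non-negative
    (entries of unconnected pairs are zero, which non-negativity subsumes),
    and each diagonal entry equals the negative sum of its off-diagonal row,
    i.e. every row sums to zero within ``tol``.

    Parameters
    ----------
    G
        Square matrix to check.
    tol
        Absolute tolerance on the row sums.  The default accommodates
        matrices printed to five significant figures.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"coupling matrix must be square, got shape {G.shape}")
    n = G.shape[0]
    violations = []
    for i in range(n):
        for j in range(n):
            if i != j and G[i, j] < 0:
                violations.append((i + 1, j + 1, "negative off-diagonal"))
    row_sums = G.sum(axis=1)
    max_row_sum_abs = float(np.max(np.abs(row_sums))) if n else 0.0
    for i in range(n):
        if abs(row_sums[i]) > tol:
            violations.append((i + 1, i + 1, "row sum exceeds tolerance"))
    return ValidationReport(
        valid=not violations,
        max_row_sum_abs=max_row_sum_abs,
        violations=tuple(violations),
    )


def coupling_from_offdiagonal(W: np.ndarray) -> CouplingMatrix:
    """Build a valid coupling matrix from non-negative off-diagonal weights.

    The diagonal of ``W`` must be zero; the returned matrix has the same
    off-diagonal entries and diagonal ``-row_sum(W)``, so it validates at the
    exact tolerance by construction.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    if np.any(W < 0):
        raise ValueError("off-diagonal gap-junction weights must be non-negative")
    G = W.copy()
    np.fill_diagonal(G, -W.sum(axis=1))
    return CouplingMatrix(G)


def random_coupling(
    n: int, density: float = 1.0, scale: float = 1e-3, seed: int = 0
) -> CouplingMatrix:
    """Generate a random symmetric gap-junction matrix.

    Each unordered pair is connected with probability ``density``; connected
    weights are uniform on ``(0, scale]``.  Gap junctions are bidirectional,
    hence the symmetric support.  Reproducible from ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                # uniform on (0, scale]: flip the half-open side of random()
                w = scale * (1.0 - rng.random())
                W[i, j] = W[j, i] = w
    return coupling_from_offdiagonal(W)


# Five-neuron gap-junction matrix of the reference benchmark, printed to five
# significant figures.  Row sums cancel only to ~1e-7, hence DEFAULT_TOL.
_REFERENCE_G = np.array(
    [
        [-1.0735e-03, 3.6412e-04, 4.0396e-04, 2.0640e-05, 2.8481e-04],
        [3.6412e-04, -1.5070e-03, 8.3269e-04, 1.6223e-04, 1.4797e-04],
        [4.0396e-04, 8.3269e-04, -2.2451e-03, 8.1832e-04, 1.9013e-04],
        [2.0640e-05, 1.6223e-04, 8.1832e-04, -1.6371e-03, 6.3596e-04],
        [2.8481e-04, 1.4797e-04, 1.9013e-04, 6.3596e-04, -1.2589e-03],
    ]
)


def reference_coupling() -> CouplingMatrix:
    """The 5x5 gap-junction matrix of the bundled five-neuron benchmark."""
    return CouplingMatrix(_REFERENCE_G.copy())


def read_coupling_csv(path) -> CouplingMatrix:
    """Read an ``n x n`` numeric grid from CSV."""
    G = np.loadtxt(path, delimiter=",", ndmin=2)
    return CouplingMatrix(G)


def write_coupling_csv(cm: CouplingMatrix, path) -> None:
    """Write the matrix as a plain CSV numeric grid (full precision)."""
    np.savetxt(path, cm.G, delimiter=",", fmt="%.17g")
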