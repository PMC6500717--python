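"""Stage-structured projection-matrix data model, validation and eigen-analysis.

A population matrix model (PMM) is a square nonnegative matrix ``L`` whose
columns are life stages in ascending order.  Row 1 holds per-stage
fertilities (average female offspring per breeding female per time unit);
every other nonzero entry is a transition probability: the diagonal is
stasis (survive and remain in the stage), the sub-diagonal is growth
(survive and advance).  Multiplying ``L`` by a stage-abundance vector
projects the female population one discrete time unit forward:

    n_T = L^T n_0

For a primitive ``L`` the Perron-Frobenius theorem guarantees a unique real
positive dominant eigenvalue ``lambda_1`` (the asymptotic growth rate) with a
strictly positive right eigenvector; normalized to sum 1 that eigenvector is
the stable stage proportions (SSP), i.e. the stable stage distribution (SSD)
standardized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ConvergenceError,
    DimensionMismatchError,
    ImprimitiveError,
    MatrixValidationError,
    NegativeEntryError,
    NonSquareError,
    StageCountError,
    SurvivalBudgetError,
    TransitionBoundError,
)

MIN_STAGES = 2
MAX_STAGES = 5

#: tolerance on the per-column survival budget (stasis + growth <= 1)
SURVIVAL_TOL = 1e-9


@dataclass(frozen=True)
class StageMatrix:
    """A validated m-stage projection matrix (2 <= m <= 5).

    Construct through :func:`validate_stage_matrix`; direct construction
    skips validation and is reserved for internal use on already-checked
    arrays.
    """

    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        a.setflags(write=False)
        object.__setattr__(self, "entries", a)

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def fertilities(self) -> np.ndarray:
        """Top row: average female offspring per breeding female per unit."""
        return self.entries[0]

    @property
    def transitions(self) -> np.ndarray:
        """Rows 2..m: survival transition probabilities."""
        return self.entries[1:]

    def with_entry(self, row: int, col: int, value: float) -> "StageMatrix":
        """Return a revalidated copy with one entry (0-based) replaced."""
        raw = np.array(self.entries, dtype=float)
        raw[row, col] = value
        return validate_stage_matrix(raw)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.entries, dtype=dtype)


@dataclass(frozen=True)
class PopulationVector:
    """Per-stage female abundances at a single time, stage order as columns."""

    abundances: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.abundances, dtype=float))
        if a.ndim != 1:
            raise DimensionMismatchError(
                f"population vector must be 1-D, got shape {a.shape}"
            )
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            raise DimensionMismatchError(
                "population vector entries must be finite and >= 0"
            )
        a.setflags(write=False)
        object.__setattr__(self, "abundances", a)

    @property
    def m(self) -> int:
        return self.abundances.shape[0]

    @property
    def total(self) -> float:
        return float(self.abundances.sum())

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.abundances, dtype=dtype)


@dataclass(frozen=True)
class EigenSummary:
    """Dominant eigenvalue and stable stage proportions of a StageMatrix."""

    lambda1: float
    ssp: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.ssp, dtype=float)
        a.setflags(write=False)
        object.__setattr__(self, "ssp", a)

    @property
    def m(self) -> int:
        return self.ssp.shape[0]

    def to_dict(self) -> dict:
        return {
            "lambda1": float(self.lambda1),
            "ssp": [float(v) for v in self.ssp],
            "m": self.m,
        }


def _as_matrix_array(raw) -> np.ndarray:
    if isinstance(raw, StageMatrix):
        return np.asarray(raw.entries, dtype=float)
    a = np.asarray(raw, dtype=float)
    return a


def validate_stage_matrix(raw) -> StageMatrix:
    """Validate a raw m x m array as a projection matrix.

    Checks, in order: squareness; stage count within 2-5; finite
    nonnegative entries; transition entries (rows 2..m) bounded by 1; each
    column's total survival (all transition entries of the column) bounded
    by 1; primitivity.  Raises a :class:`MatrixValidationError` subclass
    naming the first violated rule.
    """
    a = _as_matrix_array(raw)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NonSquareError(f"matrix must be square, got shape {a.shape}")
    m = a.shape[0]
    if not (MIN_STAGES <= m <= MAX_STAGES):
        raise StageCountError(
            f"stage count must be between {MIN_STAGES} and {MAX_STAGES}, got {m}"
        )
    if not np.all(np.isfinite(a)):
        raise MatrixValidationError("matrix entries must be finite numbers")
    if np.any(a < 0):
        i, j = np.argwhere(a < 0)[0]
        raise NegativeEntryError(
            f"entry ({i + 1},{j + 1}) = {a[i, j]} is negative"
        )
    transitions = a[1:]
    if np.any(transitions > 1.0 + SURVIVAL_TOL):
        i, j = np.argwhere(transitions > 1.0 + SURVIVAL_TOL)[0]
        raise TransitionBoundError(
            f"transition ({i + 2},{j + 1}) = {transitions[i, j]} exceeds 1"
        )
    col_survival = transitions.sum(axis=0)
    if np.any(col_survival > 1.0 + SURVIVAL_TOL):
        j = int(np.argmax(col_survival))
        raise SurvivalBudgetError(
            f"column {j + 1} total survival {col_survival[j]:.6g} exceeds 1"
        )
    if not is_primitive(a):
        raise ImprimitiveError(
            "matrix is not primitive: no power of its zero pattern is "
            "strictly positive (check for isolated stages, zero fertilities "
            "or purely cyclic structure)"
        )
    return StageMatrix(a)


def is_primitive(M) -> bool:
    """Whether a nonnegative square matrix is primitive.

    Uses the Wielandt bound: an m x m nonnegative matrix is primitive iff
    M^(m^2 - 2m + 2) is entrywise positive.  Only the zero pattern matters,
    so the power is taken over the boolean adjacency pattern (entries are
    compared to 0 exactly: users enter literal zeros).
    """
    a = _as_matrix_array(M)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NonSquareError(f"matrix must be square, got shape {a.shape}")
    m = a.shape[0]
    pattern = (a > 0).astype(np.int64)
    k = m * m - 2 * m + 2
    power = np.eye(m, dtype=np.int64)
    base = pattern
    e = k
    while e > 0:  # boolean matrix power by squaring, clipped to {0,1}
        if e & 1:
            power = np.clip(power @ base, 0, 1)
        base = np.clip(base @ base, 0, 1)
        e >>= 1
    return bool(np.all(power > 0))


def eigen_summary(M: StageMatrix) -> EigenSummary:
    """Dominant eigenvalue and stable stage proportions of a primitive PMM.

    ``lambda1`` is the unique largest-modulus eigenvalue, real and positive
    by Perron-Frobenius; ``ssp`` is the associated right eigenvector,
    sign-corrected to be entrywise positive and normalized to sum 1.
    """
    a = _as_matrix_array(M)
    try:
        eigvals, eigvecs = np.linalg.eig(a)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"eigensolver failed: {exc}") from exc
    idx = int(np.argmax(np.abs(eigvals)))
    lam = eigvals[idx]
    if abs(lam.imag) > 1e-12 * max(1.0, abs(lam.real)) or lam.real <= 0:
        raise ConvergenceError(
            f"dominant eigenvalue {lam} is not real positive; "
            "matrix is numerically degenerate"
        )
    vec = eigvecs[:, idx].real
    if vec.sum() < 0:
        vec = -vec
    if np.any(vec <= 0):
        raise ConvergenceError(
            "dominant eigenvector is not strictly positive; "
            "matrix is numerically degenerate"
        )
    ssp = vec / vec.sum()
    return EigenSummary(lambda1=float(lam.real), ssp=ssp)


def project(
    M: StageMatrix, n0, T: int
) -> np.ndarray:
    """Deterministic projection ``n_t = L^t n_0`` for t = 0..T.

    Parameters
    ----------
    M
        Validated stage matrix.
    n0
        Length-m initial abundances (PopulationVector or array-like).
    T
        Nonnegative number of discrete time units.

    Returns
    -------
    ndarray of shape (T+1, m); row t is the stage-abundance vector at time
    t, row 0 is ``n0`` unchanged.
    """
    a = _as_matrix_array(M)
    v = np.asarray(
        n0.abundances if isinstance(n0, PopulationVector) else n0, dtype=float
    )
    if v.shape != (a.shape[0],):
        raise DimensionMismatchError(
            f"release vector has length {v.shape}, matrix has {a.shape[0]} stages"
        )
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    out = np.empty((T + 1, a.shape[0]))
    out[0] = v
    for t in range(1, T + 1):
        out[t] = a @ out[t - 1]
    return out


def power_iteration(M, iterations: int = 200) -> tuple[float, np.ndarray]:
    """Estimate (lambda1, ssp) by repeated multiplication from a uniform start.

    Independent of :func:`eigen_summary`; intended as a cross-check.
    """
    a = _as_matrix_array(M)
    v = np.full(a.shape[0], 1.0 / a.shape[0])
    lam = 1.0
    for _ in range(iterations):
        w = a @ v
        lam = w.sum()
        v = w / lam
    return float(lam), v
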