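"""Candidate-model generation and ranking.

Alternative projection matrices with the same life-history structure
(identical zero/nonzero pattern) and similar vital-rate magnitudes (each
nonzero entry perturbed within +/- 0.5, clamped to the legal range) are
sampled, scored by the total release abundance they require for a shared
management goal, and presented with the user's model first followed by the
x - 1 most efficient alternates in ascending order of total release.
Larger growth rates need smaller releases, so the ranking doubles as an
efficiency ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import StageMatrix, eigen_summary, is_primitive, validate_stage_matrix
from .errors import (
    InsufficientPoolError,
    MatrixValidationError,
    SamplingExhaustedError,
)
from .planner import ManagementGoal, release_abundances

#: half-width of the vital-rate perturbation box
RATE_DELTA = 0.5

#: rejection-sampling retry cap per draw
RETRY_CAP = 1000

#: default pool size ("thousands" of simulated models)
DEFAULT_POOL_SIZE = 2000


@dataclass(frozen=True)
class CandidateRow:
    """One matrix model unraveled row-wise, with its score for the goal."""

    flat_entries: np.ndarray = field(repr=False)
    lambda1: float
    total_release: float

    def __post_init__(self) -> None:
        a = np.asarray(self.flat_entries, dtype=float)
        a.setflags(write=False)
        object.__setattr__(self, "flat_entries", a)

    @property
    def m(self) -> int:
        return int(round(self.flat_entries.shape[0] ** 0.5))

    def matrix(self) -> StageMatrix:
        return validate_stage_matrix(self.flat_entries.reshape(self.m, self.m))


@dataclass(frozen=True)
class CandidatePool:
    """User model (always first) plus alternates sorted by total release."""

    user_row: CandidateRow
    alternates: tuple[CandidateRow, ...]
    goal: ManagementGoal
    seed: Optional[int] = None

    @property
    def rows(self) -> tuple[CandidateRow, ...]:
        return (self.user_row, *self.alternates)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the row-wise unraveling: a11..amm, lambda1, total."""
        m = self.user_row.m
        cols = [f"a{i + 1}{j + 1}" for i in range(m) for j in range(m)]
        data = [
            [*row.flat_entries, row.lambda1, row.total_release]
            for row in self.rows
        ]
        return pd.DataFrame(data, columns=[*cols, "lambda1", "total_release"])


def _perturbation_bounds(user: StageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise uniform-sampling bounds for the +/- 0.5 box.

    Fertilities clamp below at 0; transitions clamp to [0, 1].  Zero
    entries stay zero (identical life-history structure).
    """
    a = np.asarray(user)
    lo = np.maximum(a - RATE_DELTA, 0.0)
    hi = a + RATE_DELTA
    hi[1:] = np.minimum(hi[1:], 1.0)
    zero = a == 0
    lo[zero] = 0.0
    hi[zero] = 0.0
    return lo, hi


def sample_similar_matrix(
    user: StageMatrix, rng: np.random.Generator
) -> StageMatrix:
    """Draw one valid matrix from the clamped +/- 0.5 box around ``user``.

    Each nonzero entry is uniform within its clamped interval; the zero
    pattern is preserved exactly.  Draws violating the survival budget or
    primitivity are rejected and redrawn, up to ``RETRY_CAP`` attempts.
    """
    lo, hi = _perturbation_bounds(user)
    for _ in range(RETRY_CAP):
        draw = rng.uniform(lo, hi)
        draw[np.asarray(user) == 0] = 0.0
        try:
            return validate_stage_matrix(draw)
        except MatrixValidationError:
            continue
    raise SamplingExhaustedError(
        f"no valid matrix found in {RETRY_CAP} draws around the user matrix; "
        "the +/- 0.5 neighborhood may be infeasible"
    )


def _score(matrix: StageMatrix, goal: ManagementGoal) -> tuple[float, float]:
    plan = release_abundances(matrix, goal)
    return plan.eigen.lambda1, plan.total_release


def build_pool(
    user: StageMatrix,
    goal: ManagementGoal,
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: Optional[int] = None,
    freeze_mask: Optional[np.ndarray] = None,
) -> CandidatePool:
    """Generate and rank a candidate pool for a shared management goal.

    ``pool_size`` similar matrices are sampled (reproducibly under
    ``seed``), each is scored by the total release its own plan requires,
    and the ``goal.x - 1`` smallest-total models become the alternates,
    sorted ascending by total release (ties broken by higher lambda1, then
    generation order).  The user's own row is always first and is never
    sorted among the alternates.

    ``freeze_mask`` (optional boolean m x m array) pins entries to the
    user's values during sampling, e.g. to hold fertilities at biologically
    fixed magnitudes while perturbing survivals only.
    """
    n_alternates = goal.x - 1
    if pool_size < n_alternates:
        raise InsufficientPoolError(
            f"pool size {pool_size} cannot supply {n_alternates} alternates"
        )
    user_lambda, user_total = _score(user, goal)
    user_row = CandidateRow(
        flat_entries=np.asarray(user).ravel(),
        lambda1=user_lambda,
        total_release=user_total,
    )
    alternates: list[CandidateRow] = []
    if n_alternates > 0:
        rng = np.random.default_rng(seed)
        scored: list[tuple[float, float, int, CandidateRow]] = []
        for idx in range(pool_size):
            matrix = sample_similar_matrix(user, rng)
            if freeze_mask is not None:
                frozen = np.array(matrix.entries)
                frozen[freeze_mask] = np.asarray(user)[freeze_mask]
                matrix = validate_stage_matrix(frozen)
            lam, total = _score(matrix, goal)
            row = CandidateRow(
                flat_entries=np.asarray(matrix).ravel(),
                lambda1=lam,
                total_release=total,
            )
            scored.append((total, -lam, idx, row))
        scored.sort(key=lambda item: item[:3])
        if len(scored) < n_alternates:
            raise InsufficientPoolError(
                f"only {len(scored)} valid candidates for {n_alternates} slots"
            )
        alternates = [item[3] for item in scored[:n_alternates]]
    return CandidatePool(
        user_row=user_row,
        alternates=tuple(alternates),
        goal=goal,
        seed=seed,
    )
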