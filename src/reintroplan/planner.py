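"""SSD-aligned release planning.

Given a projection matrix and a management goal (a timeline of T discrete
time units and a desired number B of breeding females at time T), the
planner builds the target vector ``n_T`` on the stable-stage ray so that
its breeding-stage abundances sum to B, then inverts the projection through
the dominant eigenvalue:

    n_0 = n_T / lambda_1^T

Because both ``n_0`` and ``n_T`` lie on the SSD ray, the whole schedule is
scalar growth along that ray: the abundances at time t are
``n_0 * lambda_1^t``, with stage proportions fixed at the SSP.  "Breeding
female" means a female in a stage with strictly positive fertility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import EigenSummary, PopulationVector, StageMatrix, eigen_summary
from .errors import GoalError, NoBreedingStageError, NonPositiveTotalError


@dataclass(frozen=True)
class ManagementGoal:
    """Management goal: timeline, breeding-female target, candidate count.

    Parameters
    ----------
    T
        Desired number of discrete time units (>= 1).  Units carry no
        calendar semantics; "7 years" is 7 units.
    B
        Desired abundance of breeding females at time T (> 0).
    x
        Desired number of candidate models to compare (>= 1); the user's
        own model always counts as the first.
    """

    T: int
    B: float
    x: int = 1

    def __post_init__(self) -> None:
        if int(self.T) != self.T or self.T < 1:
            raise GoalError(f"T must be a positive integer, got {self.T}")
        if not self.B > 0:
            raise GoalError(f"B must be > 0, got {self.B}")
        if int(self.x) != self.x or self.x < 1:
            raise GoalError(f"x must be a positive integer, got {self.x}")
        object.__setattr__(self, "T", int(self.T))
        object.__setattr__(self, "B", float(self.B))
        object.__setattr__(self, "x", int(self.x))


@dataclass(frozen=True)
class ReleasePlan:
    """A stable-stage-aligned release plan for one matrix and goal.

    ``schedule`` is a (T+1) x m table; row t holds the per-stage abundances
    at time t, every row proportional to the SSP.  ``n_0`` (row 0) is what
    must be released; ``n_T`` (row T) meets the goal.  Abundances are
    continuous; integerization happens only at display.
    """

    matrix: StageMatrix
    goal: ManagementGoal
    eigen: EigenSummary
    n_T: PopulationVector
    n_0: PopulationVector
    schedule: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.schedule, dtype=float)
        s.setflags(write=False)
        object.__setattr__(self, "schedule", s)

    @property
    def total_release(self) -> float:
        return self.n_0.total

    def schedule_frame(self) -> pd.DataFrame:
        """Schedule as a DataFrame with columns time, stage_1..stage_m."""
        m = self.matrix.m
        frame = pd.DataFrame(
            self.schedule, columns=[f"stage_{i + 1}" for i in range(m)]
        )
        frame.insert(0, "time", np.arange(self.goal.T + 1))
        return frame

    def to_dict(self) -> dict:
        return {
            "lambda1": float(self.eigen.lambda1),
            "ssp": [float(v) for v in self.eigen.ssp],
            "n_T": [float(v) for v in self.n_T.abundances],
            "n_0": [float(v) for v in self.n_0.abundances],
            "total_release": float(self.total_release),
            "schedule": [
                [int(t), *(float(v) for v in row)]
                for t, row in enumerate(self.schedule)
            ],
        }


def breeding_stage_indices(M: StageMatrix) -> frozenset[int]:
    """Stages whose fertility is strictly positive, as 1-based indices."""
    fert = M.fertilities
    stages = frozenset(int(i) + 1 for i in np.flatnonzero(fert > 0))
    if not stages:
        raise NoBreedingStageError("all fertilities are zero")
    return stages


def _breeding_mask(M: StageMatrix) -> np.ndarray:
    mask = np.asarray(M.fertilities) > 0
    if not mask.any():
        raise NoBreedingStageError("all fertilities are zero")
    return mask


def ssd_target_vector(M: StageMatrix, B: float) -> PopulationVector:
    """Target vector on the SSD ray whose breeding-stage total equals B.

    ``n_T = (B / sum of breeding-stage SSP) * ssp``: the B desired breeding
    females are partitioned among the breeding stages in SSP proportion, and
    the non-breeding stages carry the abundances the stable distribution
    requires alongside them.
    """
    if not B > 0:
        raise GoalError(f"B must be > 0, got {B}")
    summary = eigen_summary(M)
    mask = _breeding_mask(M)
    scale = B / float(summary.ssp[mask].sum())
    return PopulationVector(scale * summary.ssp)


def release_abundances(M: StageMatrix, goal: ManagementGoal) -> ReleasePlan:
    """Compute the SSD-aligned release plan for a matrix and goal.

    ``n_0 = n_T / lambda_1^T``; the schedule row at time t is
    ``n_0 * lambda_1^t`` (scalar growth on the SSD ray, equal to repeated
    matrix multiplication for vectors on that ray).
    """
    summary = eigen_summary(M)
    n_T = ssd_target_vector(M, goal.B)
    lam = summary.lambda1
    n0_arr = np.asarray(n_T) / lam ** goal.T
    growth = lam ** np.arange(goal.T + 1)
    schedule = growth[:, None] * n0_arr[None, :]
    return ReleasePlan(
        matrix=M,
        goal=goal,
        eigen=summary,
        n_T=n_T,
        n_0=PopulationVector(n0_arr),
        schedule=schedule,
    )


def scale_plan(plan: ReleasePlan, new_total: float) -> ReleasePlan:
    """Rescale a plan so the total release equals ``new_total``.

    Stage proportions are unchanged (any scaling of an SSD release stays on
    the SSD ray); the goal's B is recomputed to the breeding-stage total the
    rescaled plan reaches at time T, so it no longer equals the user's
    original B.
    """
    if not new_total > 0:
        raise NonPositiveTotalError(f"new total must be > 0, got {new_total}")
    factor = new_total / plan.total_release
    mask = _breeding_mask(plan.matrix)
    new_nT = np.asarray(plan.n_T) * factor
    new_goal = replace(plan.goal, B=float(new_nT[mask].sum()))
    return ReleasePlan(
        matrix=plan.matrix,
        goal=new_goal,
        eigen=plan.eigen,
        n_T=PopulationVector(new_nT),
        n_0=PopulationVector(np.asarray(plan.n_0) * factor),
        schedule=plan.schedule * factor,
    )
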