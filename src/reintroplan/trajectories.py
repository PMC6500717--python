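"""Deterministic trajectories for releases in and out of the stable stage
distribution.

A release on the SSD ray keeps fixed stage proportions and grows by exactly
lambda_1 each step.  Any other release excites the subdominant eigenmodes
and produces transient dynamics: the total abundance dips below
(attenuation) or rises above (amplification) the lambda_1-scaled launch
total before the stage proportions converge back to the SSP.  This module
computes both trajectories for side-by-side comparison; it reports them and
flags each step, it does not adjudicate which is desirable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import PopulationVector, StageMatrix, eigen_summary, project
from .errors import AllZeroReleaseError, DimensionMismatchError
from .planner import ManagementGoal, _breeding_mask, release_abundances

#: relative tolerance for calling a step attenuating/amplifying
FLAG_TOL = 1e-9


@dataclass(frozen=True)
class TrajectoryComparison:
    """Stable vs transient abundance tables for a shared goal and timeline.

    ``stable`` is the SSD-aligned schedule toward the goal; ``transient``
    projects the user's release vector through the matrix.  ``flags[t]``
    classifies the transient total at time t against the launch total
    scaled by lambda_1^t: "attenuating" below, "amplifying" above,
    "stable" within tolerance.
    """

    stable: np.ndarray = field(repr=False)
    transient: np.ndarray = field(repr=False)
    release_total: float
    lambda1: float
    flags: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("stable", "transient"):
            a = np.asarray(getattr(self, name), dtype=float)
            a.setflags(write=False)
            object.__setattr__(self, name, a)

    @property
    def T(self) -> int:
        return self.stable.shape[0] - 1

    @property
    def m(self) -> int:
        return self.stable.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: time, stage, stable and transient abundances."""
        times = np.repeat(np.arange(self.T + 1), self.m)
        stages = np.tile(np.arange(1, self.m + 1), self.T + 1)
        return pd.DataFrame(
            {
                "time": times,
                "stage": stages,
                "stable_abundance": self.stable.ravel(),
                "transient_abundance": self.transient.ravel(),
            }
        )


def _classify(total: float, reference: float) -> str:
    scale = max(abs(reference), 1.0)
    if total < reference - FLAG_TOL * scale:
        return "attenuating"
    if total > reference + FLAG_TOL * scale:
        return "amplifying"
    return "stable"


def compare_release(
    M: StageMatrix, goal: ManagementGoal, user_n0
) -> TrajectoryComparison:
    """Compare an arbitrary release against the SSD-aligned plan.

    The stable table is the planner's schedule for ``goal``; the transient
    table projects ``user_n0`` for T steps.  Identical shapes make the two
    directly overlayable, one line per stage.
    """
    v = np.asarray(
        user_n0.abundances if isinstance(user_n0, PopulationVector) else user_n0,
        dtype=float,
    )
    if v.shape != (M.m,):
        raise DimensionMismatchError(
            f"release vector has shape {v.shape}, matrix has {M.m} stages"
        )
    if np.any(v < 0):
        raise AllZeroReleaseError("release abundances must be >= 0")
    if not np.any(v > 0):
        raise AllZeroReleaseError("release vector is all zero")
    plan = release_abundances(M, goal)
    transient = project(M, v, goal.T)
    lam = plan.eigen.lambda1
    launch_total = float(v.sum())
    totals = transient.sum(axis=1)
    flags = tuple(
        _classify(float(totals[t]), launch_total * lam ** t)
        for t in range(goal.T + 1)
    )
    return TrajectoryComparison(
        stable=plan.schedule,
        transient=transient,
        release_total=launch_total,
        lambda1=lam,
        flags=flags,
    )


def time_to_goal(
    M: StageMatrix, n0, B: float, horizon: int
) -> Optional[int]:
    """Earliest time t <= horizon at which breeding-stage total reaches B.

    Returns the smallest t with the summed abundance over breeding stages
    (positive-fertility stages) >= B, or None if the goal is not met within
    the horizon.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    mask = _breeding_mask(M)
    traj = project(M, n0, horizon)
    breeding_totals = traj[:, mask].sum(axis=1)
    hits = np.flatnonzero(breeding_totals >= B)
    return int(hits[0]) if hits.size else None


def plot_comparison(
    comparison: TrajectoryComparison, path: str, title: Optional[str] = None
) -> None:
    """Write a PNG overlaying stable (solid) and transient (dotted) lines.

    One line per stage; requires matplotlib (the ``plot`` extra).
    Side-effect only: nothing about the comparison is recomputed here.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = np.arange(comparison.T + 1)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for stage in range(comparison.m):
        color = colors[stage % len(colors)]
        ax.plot(
            times, comparison.stable[:, stage], "-", color=color,
            label=f"stage {stage + 1} (stable)",
        )
        ax.plot(
            times, comparison.transient[:, stage], ":", color=color,
            label=f"stage {stage + 1} (release)",
        )
    ax.set_xlabel("time units")
    ax.set_ylabel("female abundance")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
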