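"""Seeded generator of valid random life histories for tests and demos.

Emulates a library of simulated stage-structured models: Lefkovitch-pattern
matrices (top-row fertilities, sub-diagonal growth, diagonal stasis) with
per-column survival within budget, guaranteed primitive, reproducible per
seed.  It does not attempt taxon-realistic vital rates — magnitudes default
to the ungulate-like ranges of the worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StageMatrix, validate_stage_matrix
from .errors import MatrixValidationError, SamplingExhaustedError

RETRY_CAP = 1000


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one random life history.

    fertility_range: uniform range for per-stage fertilities (female
    offspring per breeding female per time unit); default [0, 2] spans
    ungulate-like magnitudes.  survival_budget: upper bound on each
    column's total survival probability (stasis + growth).
    max_damping_ratio: ceiling on |lambda2|/lambda1; draws above it are
    rejected.  Iteroparous life cycles with reproduction spread over
    several adult stages mix quickly (the ungulate worked example sits
    near 0.12), and a bounded ratio guarantees transients decay within a
    few tens of time units rather than lingering indefinitely.
    """

    m: int
    seed: int
    fertility_range: tuple[float, float] = (0.0, 2.0)
    survival_budget: float = 1.0
    max_damping_ratio: float = 0.65

    def __post_init__(self) -> None:
        if not 2 <= self.m <= 5:
            raise ValueError(f"m must be in 2..5, got {self.m}")
        lo, hi = self.fertility_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad fertility range {self.fertility_range}")
        if not 0 < self.survival_budget <= 1:
            raise ValueError(
                f"survival budget must be in (0, 1], got {self.survival_budget}"
            )
        if not 0 < self.max_damping_ratio < 1:
            raise ValueError(
                f"damping-ratio ceiling must be in (0, 1), "
                f"got {self.max_damping_ratio}"
            )


def random_life_history(spec: FixtureSpec) -> StageMatrix:
    """Draw one valid Lefkovitch matrix.

    Stage 1 never breeds (juveniles); stages 2..m draw fertilities uniform
    in ``fertility_range`` bounded away from zero so the matrix stays
    irreducible.  Each column's survival is a uniform draw below the
    budget, split between stasis (diagonal) and growth (sub-diagonal); the
    final stage keeps all survival as stasis, whose self-loop makes the
    life cycle aperiodic.  Draws that are invalid or more weakly damped
    than ``max_damping_ratio`` are rejected up to a retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.fertility_range
    # keep fertilities strictly positive: a zero top-right entry would cut
    # the adult->newborn arc and break irreducibility
    fert_lo = max(lo, 1e-3 * max(hi, 1.0))
    for _ in range(RETRY_CAP):
        a = np.zeros((spec.m, spec.m))
        a[0, 1:] = rng.uniform(fert_lo, hi, size=spec.m - 1)
        for col in range(spec.m):
            survival = rng.uniform(0.2, 1.0) * spec.survival_budget
            if col < spec.m - 1:
                growth_share = rng.uniform(0.3, 1.0)
                a[col + 1, col] = survival * growth_share
                if col > 0:  # stage-1 stasis stays 0: newborns must advance
                    a[col, col] = survival * (1.0 - growth_share)
            else:
                a[col, col] = survival
        try:
            matrix = validate_stage_matrix(a)
        except MatrixValidationError:
            continue
        mods = np.sort(np.abs(np.linalg.eigvals(a)))[::-1]
        if mods[1] <= spec.max_damping_ratio * mods[0]:
            return matrix
    raise SamplingExhaustedError(
        f"no valid life history in {RETRY_CAP} draws for spec {spec}"
    )


def random_release_vector(
    m: int, seed: int, total: float = 50.0
) -> np.ndarray:
    """A nonnegative random release vector summing to ``total``."""
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(m))
    return total * weights
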