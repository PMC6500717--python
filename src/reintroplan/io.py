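"""File formats and run configuration.

Matrix CSV: m rows x m columns of plain decimals, no header, row 1 =
fertilities.  Machine outputs carry 12 significant digits so a write/read
round trip reproduces entries; display-truncated values live in separate
``*_display`` fields and never feed back into computation.  CSV dialect is
comma-separated, "." decimal point, LF newlines.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import EigenSummary, StageMatrix, validate_stage_matrix
from .display import format_sig, format_truncated, truncate, truncate_int
from .errors import MatrixValidationError
from .planner import ManagementGoal, ReleasePlan

PathLike = Union[str, Path]

SIG_DIGITS = 12
FLOAT_FORMAT = f"%.{SIG_DIGITS}g"


@dataclass(frozen=True)
class RunConfig:
    """Resolved inputs of one CLI run, serializable for provenance."""

    matrix_path: str
    T: Optional[int] = None
    B: Optional[float] = None
    x: Optional[int] = None
    pool_size: Optional[int] = None
    seed: Optional[int] = None
    out_dir: Optional[str] = None
    display_decimals: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def file_sha256(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_matrix_csv(path: PathLike) -> StageMatrix:
    """Read and validate a headerless m x m matrix CSV."""
    rows: list[list[float]] = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            parsed = []
            for colno, cell in enumerate(row, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError as exc:
                    raise MatrixValidationError(
                        f"{path}: line {lineno}, column {colno}: "
                        f"cannot parse {cell!r} as a number"
                    ) from exc
            rows.append(parsed)
    if not rows:
        raise MatrixValidationError(f"{path}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise MatrixValidationError(
            f"{path}: ragged rows (widths {sorted(widths)})"
        )
    return validate_stage_matrix(np.array(rows))


def write_matrix_csv(matrix: StageMatrix, path: PathLike) -> None:
    with open(path, "w", newline="\n") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        for row in np.asarray(matrix):
            writer.writerow([format_sig(v, SIG_DIGITS) for v in row])


def eigen_summary_dict(summary: EigenSummary, decimals: int = 3) -> dict:
    """JSON-ready eigen summary with truncated display companions."""
    return {
        **summary.to_dict(),
        "lambda1_display": format_truncated(summary.lambda1, decimals),
        "ssp_percent_display": [
            truncate_int(100 * v) for v in summary.ssp
        ],
    }


def write_eigen_json(summary: EigenSummary, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(eigen_summary_dict(summary), indent=2) + "\n"
    )


def plan_dict(plan: ReleasePlan) -> dict:
    """JSON-ready release plan: full precision plus truncated displays."""
    return {
        **plan.to_dict(),
        "lambda1_display": format_truncated(plan.eigen.lambda1, 3),
        "n_T_display": [truncate_int(v) for v in plan.n_T.abundances],
        "n_0_display": [truncate_int(v) for v in plan.n_0.abundances],
        "total_release_display": truncate_int(plan.total_release),
    }


def write_plan_json(plan: ReleasePlan, path: PathLike) -> None:
    Path(path).write_text(json.dumps(plan_dict(plan), indent=2) + "\n")


def write_schedule_csv(plan: ReleasePlan, path: PathLike) -> None:
    frame = plan.schedule_frame()
    frame.to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def write_candidates_csv(pool, path: PathLike) -> None:
    pool.to_frame().to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def write_comparison_csv(comparison, path: PathLike) -> None:
    comparison.to_long_frame().to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def load_config_file(path: PathLike) -> dict:
    """Read a flat key=value (or YAML-subset) config file.

    Lines are ``key: value`` or ``key = value``; blank lines and ``#``
    comments are ignored.  Values are parsed as int, then float, then kept
    as strings.  Flags on the command line override file values.
    """
    result: dict = {}
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}: cannot parse config line {raw_line!r}")
        key = key.strip()
        value = value.strip()
        for cast in (int, float):
            try:
                result[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            result[key] = value
    return result
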