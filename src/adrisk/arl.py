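"""Failure-mode RPN matrix and Acceptable Risk Levels (ARL).

The FMECA panel rates five preparation-process failure modes —
packaging/handling, reconstitution, dilution, pharmaceutical form and
waste disposal — on an ordinal 1–5 risk-priority-number (RPN) scale
combining severity, expected frequency and avoidability, for each of
the eight drug hazard groups under manual and automated preparation.
The ARL for a (group, mode) cell is the sum of its five failure-mode
RPNs and ranges from 5 (all ones) to 25 (all fives); it is the
tolerable baseline that measured risk levels are compared against.

ARLs are always derived from the matrix, never stored independently, so
the two can never disagree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

from .catalog import ADGroup
from .errors import ConfigError, IncompleteMatrixError

__all__ = [
    "FailureMode",
    "PrepMode",
    "RPNMatrix",
    "compute_arl",
    "build_default_matrix",
    "load_matrix",
    "arl_profile",
    "RPN_MIN",
    "RPN_MAX",
]

RPN_MIN = 1
RPN_MAX = 5


class FailureMode(enum.Enum):
    """The five preparation failure modes, in table row order."""

    PACKAGING_HANDLING = "packaging_handling"
    RECONSTITUTION = "reconstitution"
    DILUTION = "dilution"
    PHARMACEUTICAL_FORM = "pharmaceutical_form"
    WASTE_DISPOSAL = "waste_disposal"


class PrepMode(enum.Enum):
    """Preparation mode: manual (biological safety cabinet, two
    technicians) or automated (compounding robot)."""

    MANUAL = "manual"
    AUTOMATED = "automated"


Cell = tuple[ADGroup, PrepMode, FailureMode]


def _validate_score(score: int, cell: Cell) -> int:
    if not isinstance(score, int) or isinstance(score, bool):
        raise ConfigError(f"RPN at {_cell_path(cell)} must be an integer, got {score!r}")
    if not RPN_MIN <= score <= RPN_MAX:
        raise ConfigError(
            f"RPN at {_cell_path(cell)} out of range [{RPN_MIN}, {RPN_MAX}]: {score}"
        )
    return score


def _cell_path(cell: Cell) -> str:
    group, mode, fm = cell
    return f"{group.value}.{mode.value}.{fm.value}"


@dataclass(frozen=True)
class RPNMatrix:
    """Complete failure-mode score matrix: 8 groups x 2 modes x 5 modes of
    failure = 80 cells, each an integer in [1, 5]."""

    scores: Mapping[Cell, int]

    def __post_init__(self) -> None:
        for group in ADGroup:
            for mode in PrepMode:
                for fm in FailureMode:
                    cell = (group, mode, fm)
                    if cell not in self.scores:
                        raise IncompleteMatrixError(
                            f"RPN matrix missing cell {_cell_path(cell)}"
                        )
                    _validate_score(self.scores[cell], cell)

    def score(self, group: ADGroup, mode: PrepMode, failure_mode: FailureMode) -> int:
        return self.scores[(group, mode, failure_mode)]


# Default panel ratings; five values per (group, mode) in FailureMode order.
_DEFAULT_SCORES: dict[tuple[ADGroup, PrepMode], tuple[int, int, int, int, int]] = {
    (ADGroup.POWDER, PrepMode.MANUAL): (4, 5, 3, 2, 3),
    (ADGroup.POWDER, PrepMode.AUTOMATED): (4, 4, 2, 2, 3),
    (ADGroup.LIQUID, PrepMode.MANUAL): (2, 1, 4, 3, 3),
    (ADGroup.LIQUID, PrepMode.AUTOMATED): (2, 1, 4, 2, 3),
    (ADGroup.CORROSIVE, PrepMode.MANUAL): (4, 2, 2, 3, 5),
    (ADGroup.CORROSIVE, PrepMode.AUTOMATED): (4, 1, 1, 3, 3),
    (ADGroup.ONE_CONCENTRATION, PrepMode.MANUAL): (3, 4, 4, 3, 3),
    (ADGroup.ONE_CONCENTRATION, PrepMode.AUTOMATED): (3, 4, 4, 2, 2),
    (ADGroup.UNSTABLE, PrepMode.MANUAL): (3, 3, 3, 3, 4),
    (ADGroup.UNSTABLE, PrepMode.AUTOMATED): (3, 2, 2, 3, 4),
    (ADGroup.NO_HOLDER_CASING, PrepMode.MANUAL): (5, 3, 3, 2, 5),
    (ADGroup.NO_HOLDER_CASING, PrepMode.AUTOMATED): (5, 2, 2, 2, 5),
    (ADGroup.HIGH_AVG_CONCENTRATION, PrepMode.MANUAL): (3, 4, 4, 4, 2),
    (ADGroup.HIGH_AVG_CONCENTRATION, PrepMode.AUTOMATED): (3, 3, 2, 4, 2),
    (ADGroup.POORLY_SOLUBLE, PrepMode.MANUAL): (3, 4, 4, 3, 2),
    (ADGroup.POORLY_SOLUBLE, PrepMode.AUTOMATED): (3, 3, 3, 3, 2),
}


def build_default_matrix() -> RPNMatrix:
    """The packaged default matrix: the consensus ratings of the
    multidisciplinary FMECA panel (three pharmacists, a risk manager and
    three monitoring technicians) for all 80 cells."""
    scores: dict[Cell, int] = {}
    for (group, mode), row in _DEFAULT_SCORES.items():
        for fm, score in zip(FailureMode, row):
            scores[(group, mode, fm)] = score
    return RPNMatrix(scores)


def compute_arl(matrix: RPNMatrix, group: ADGroup, mode: PrepMode) -> int:
    """Acceptable Risk Level: the sum of the five failure-mode RPNs for
    one (group, preparation-mode) cell; always in [5, 25]."""
    return sum(matrix.score(group, mode, fm) for fm in FailureMode)


def arl_profile(matrix: RPNMatrix) -> dict[tuple[ADGroup, PrepMode], int]:
    """ARLs for all 16 (group, mode) cells."""
    return {
        (group, mode): compute_arl(matrix, group, mode)
        for group in ADGroup
        for mode in PrepMode
    }


def load_matrix(config: Mapping | None) -> RPNMatrix:
    """Build a matrix from a config mapping, merged cell-wise over defaults.

    ``config`` has the shape ``{group: {mode: {failure_mode: score}}}``
    using the enum value tokens; any subset of cells may be supplied and
    the rest inherit the default matrix.  Out-of-range scores and
    unknown tokens are rejected with the offending cell path.
    """
    scores = dict(build_default_matrix().scores)
    if not config:
        return RPNMatrix(scores)
    for group_key, modes in config.items():
        try:
            group = ADGroup(group_key)
        except ValueError:
            raise ConfigError(f"rpn_matrix: unknown AD group {group_key!r}")
        for mode_key, cells in modes.items():
            try:
                mode = PrepMode(mode_key)
            except ValueError:
                raise ConfigError(
                    f"rpn_matrix.{group.value}: unknown preparation mode {mode_key!r}"
                )
            for fm_key, score in cells.items():
                try:
                    fm = FailureMode(fm_key)
                except ValueError:
                    raise ConfigError(
                        f"rpn_matrix.{group.value}.{mode.value}: "
                        f"unknown failure mode {fm_key!r}"
                    )
                cell = (group, mode, fm)
                scores[cell] = _validate_score(score, cell)
    return RPNMatrix(scores)
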