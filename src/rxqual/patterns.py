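"""Ward-level change-pattern classification of criterion trajectories.

For each criterion, every ward contributes a trajectory (its criteria-Fscore
before and after the intervention).  Trajectories across wards are then
classified into one of four qualitative patterns by whether their starting
points, end points and gradient directions are the "same" under a small
tolerance:

* **A** — different starting points, end points, and gradient direction;
* **B** — different starting and end points but same gradient direction;
* **C** — different starting points but same end points and direction;
* **D** — same starting points, end points, and direction.

"Same" for starts/ends means the pairwise spread across wards is within a
tolerance (default 2 percentage points); a trajectory is "flat" when its
pre→post change is within the flat tolerance (default 1 point).  Flat
trajectories mixed with a single direction count as that direction; flat
mixed with both rising and falling counts as differing directions.  The
tolerances are configurable — larger tolerances can only coarsen the
classification toward pattern D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .criteria import AssessmentResult, CriterionOutcome
from .prescriptions import PatientRecord, Prescription, TimePoint

__all__ = [
    "ChangePattern",
    "WardTrajectory",
    "ward_criteria_fscores",
    "classify_change_pattern",
    "classify_all_criteria",
    "DEFAULT_SAME_TOLERANCE",
    "DEFAULT_FLAT_TOLERANCE",
]

DEFAULT_SAME_TOLERANCE = 0.02   # proportion scale = 2 percentage points
DEFAULT_FLAT_TOLERANCE = 0.01


class ChangePattern(str, Enum):
    A = "different_starts_ends_directions"
    B = "different_starts_ends_same_direction"
    C = "different_starts_same_ends_direction"
    D = "same_starts_ends_direction"


@dataclass(frozen=True)
class WardTrajectory:
    ward_id: int
    criterion: int
    fscore_pre: float
    fscore_post: float

    def direction(self, flat_tolerance: float = DEFAULT_FLAT_TOLERANCE) -> str:
        delta = self.fscore_post - self.fscore_pre
        if abs(delta) <= flat_tolerance:
            return "flat"
        return "up" if delta > 0 else "down"


def ward_criteria_fscores(
    results: Sequence[AssessmentResult],
    prescriptions: Sequence[Prescription],
    patients: Sequence[PatientRecord],
    criterion: int,
) -> list[WardTrajectory]:
    """Per-ward pre/post criteria-Fscores for one criterion.

    Wards where the criterion is never applicable at either time point are
    excluded (as a criterion applicable on almost no orders cannot be traced
    on every ward).  Returns an empty list with a warning if the criterion
    applies nowhere.
    """
    if not 1 <= criterion <= 20:
        raise ValueError("criterion must be in 1..20")
    pat_index = {p.patient_id: p for p in patients}
    rx_index = {p.prescription_id: p for p in prescriptions}
    # counts[ward][tp] = [met, applicable]
    counts: dict[int, dict[TimePoint, list[int]]] = {}
    for r in results:
        rx = rx_index[r.prescription_id]
        pat = pat_index[rx.patient_id]
        outcome = r.outcomes[criterion - 1]
        if outcome is CriterionOutcome.NOT_APPLICABLE:
            continue
        cell = counts.setdefault(pat.ward_id, {}).setdefault(pat.time_point, [0, 0])
        cell[1] += 1
        if outcome is CriterionOutcome.MET:
            cell[0] += 1
    trajectories = []
    for ward_id in sorted(counts):
        by_tp = counts[ward_id]
        if TimePoint.PRE not in by_tp or TimePoint.POST not in by_tp:
            continue
        trajectories.append(
            WardTrajectory(
                ward_id=ward_id,
                criterion=criterion,
                fscore_pre=by_tp[TimePoint.PRE][0] / by_tp[TimePoint.PRE][1],
                fscore_post=by_tp[TimePoint.POST][0] / by_tp[TimePoint.POST][1],
            )
        )
    if not trajectories:
        warnings.warn(f"criterion #{criterion} applicable on no ward at both time points")
    return trajectories


def _same(values: Sequence[float], tolerance: float) -> bool:
    return max(values) - min(values) <= tolerance


def classify_change_pattern(
    trajectories: Sequence[WardTrajectory],
    tolerance: float = DEFAULT_SAME_TOLERANCE,
    flat_tolerance: float = DEFAULT_FLAT_TOLERANCE,
) -> ChangePattern:
    """Classify a set of ward trajectories into pattern A, B, C or D."""
    if not trajectories:
        raise ValueError("no trajectories to classify")
    starts = [t.fscore_pre for t in trajectories]
    ends = [t.fscore_post for t in trajectories]
    dirs = {t.direction(flat_tolerance) for t in trajectories}
    same_direction = len(dirs - {"flat"}) <= 1
    if not same_direction:
        return ChangePattern.A
    same_starts = _same(starts, tolerance)
    same_ends = _same(ends, tolerance)
    if same_starts and same_ends:
        return ChangePattern.D
    if same_ends:
        return ChangePattern.C
    return ChangePattern.B


def classify_all_criteria(
    results: Sequence[AssessmentResult],
    prescriptions: Sequence[Prescription],
    patients: Sequence[PatientRecord],
    tolerance: float = DEFAULT_SAME_TOLERANCE,
    flat_tolerance: float = DEFAULT_FLAT_TOLERANCE,
) -> dict[int, tuple[ChangePattern | None, list[WardTrajectory]]]:
    """Pattern and trajectories for every criterion (None where undefined)."""
    out = {}
    for c in range(1, 21):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = ward_criteria_fscores(results, prescriptions, patients, c)
        out[c] = (
            classify_change_pattern(traj, tolerance, flat_tolerance) if traj else None,
            traj,
        )
    return out
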