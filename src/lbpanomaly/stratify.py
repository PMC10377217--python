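"""Per-subject reconstruction fit and percentile subgrouping.

Each subject's reconstructed feature vector is compared with the actual
one through a single linear regression — target regressed on output —
whose correlation coefficient R (signed Pearson) scores how well the
subject conforms to the population structure the network learned.  The
cohort is then split at the 25th and 75th percentiles of the R
distribution: group 1 (R strictly below P25, the altered-profile group),
group 2 (P25..P75 inclusive) and group 3 (R strictly above P75).  A
binary change flag marks group 1 as "changed" (2) and everyone else as
"no change" (1).

Percentiles use linear interpolation of order statistics (index
``q*(n-1)``), the numpy default; group membership near the cut points
depends on this choice, so it is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from lbpanomaly.errors import ValidationError

__all__ = ["SubjectFit", "GroupAssignment", "subject_fit", "fit_all",
           "stratify", "pooled_fit"]


@dataclass(frozen=True)
class SubjectFit:
    """Fit of one subject's reconstruction: R plus the regression line."""

    id: int
    r: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class GroupAssignment:
    """Subgroup label (1/2/3) and binary change flag (2 = altered)."""

    id: int
    group: int
    change_flag: int


def subject_fit(target_row: Sequence[float], output_row: Sequence[float],
                subject_id: int = 0) -> SubjectFit:
    """Regress a subject's target vector on the reconstructed one.

    Returns the signed Pearson correlation R and the OLS slope/intercept
    of target-on-output.  A constant output vector is degenerate: R and
    slope are set to 0 and the intercept to the target mean.
    """
    t = np.asarray(target_row, dtype=float)
    y = np.asarray(output_row, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 3:
        raise ValidationError("need matched 1-D vectors of length >= 3")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in fit vectors")
    sy = y.std()
    st = t.std()
    if sy == 0.0:
        return SubjectFit(id=subject_id, r=0.0, slope=0.0,
                          intercept=float(t.mean()))
    cov = float(np.mean((t - t.mean()) * (y - y.mean())))
    slope = cov / (sy * sy)
    intercept = float(t.mean() - slope * y.mean())
    r = 0.0 if st == 0.0 else cov / (st * sy)
    return SubjectFit(id=subject_id, r=float(r), slope=float(slope),
                      intercept=intercept)


def fit_all(targets: np.ndarray, outputs: np.ndarray,
            ids: Sequence[int] | None = None) -> list[SubjectFit]:
    """Apply :func:`subject_fit` row-wise over a cohort."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValidationError("targets and outputs must share a shape")
    if ids is None:
        ids = range(1, targets.shape[0] + 1)
    return [subject_fit(t, o, subject_id=int(i))
            for i, t, o in zip(ids, targets, outputs)]


def stratify(fits: Sequence[SubjectFit], p_low: float = 25.0,
             p_high: float = 75.0) -> list[GroupAssignment]:
    """Assign percentile subgroups from the R distribution.

    Strict inequalities define the outer groups; values equal to either
    percentile fall in group 2.
    """
    if len(fits) < 4:
        raise ValidationError("need at least 4 subjects to stratify")
    if not 0.0 <= p_low < p_high <= 100.0:
        raise ValidationError("need 0 <= p_low < p_high <= 100")
    r = np.array([f.r for f in fits], dtype=float)
    lo, hi = np.percentile(r, [p_low, p_high])  # linear interpolation
    out = []
    for f in fits:
        if f.r < lo:
            group = 1
        elif f.r > hi:
            group = 3
        else:
            group = 2
        out.append(GroupAssignment(id=f.id, group=group,
                                   change_flag=2 if group == 1 else 1))
    return out


def pooled_fit(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Pearson correlation over all flattened (subject, feature) pairs."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValidationError("targets and outputs must share a shape")
    t, y = targets.ravel(), outputs.ravel()
    if t.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(t, y)[0, 1])


def fits_to_frame(fits: Sequence[SubjectFit],
                  groups: Sequence[GroupAssignment]) -> pd.DataFrame:
    """Combine fits and assignments into the output table."""
    by_id = {g.id: g for g in groups}
    rows = [{"id": f.id, "R": f.r, "slope": f.slope,
             "intercept": f.intercept, "group": by_id[f.id].group,
             "change_flag": by_id[f.id].change_flag} for f in fits]
    return pd.DataFrame(rows)
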