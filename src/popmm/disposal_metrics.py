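"""Partitioning net glucose disposal into insulin-dependent and
non-insulin-dependent routes.

In the minimal model the instantaneous fractional glucose disappearance rate
is GEZI + X(t): the GEZI part acts regardless of insulin, the X(t) part is
insulin-mediated.  Two summaries follow:

* basal state: fraction = GEZI / (GEZI + SI*Ibasal), since X settles at
  SI*Ibasal under basal insulin;
* over an IVGTT of duration T: GD_NID = integral of GEZI*G(t) dt and
  GD_ID = integral of X(t)*G(t) dt, with fraction GD_NID/(GD_NID+GD_ID).

Dynamic fractions are conventionally computed for standard-IVGTT subjects
(exogenous insulin in IM-IVGTT would distort the partition); pass
``include_im=True`` to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import _core
from .minimal_model import MMParams, SubjectData, TestType


@dataclass(frozen=True)
class DisposalResult:
    GD_NID: float        # mmol/L * min
    GD_ID: float         # mmol/L * min
    fraction_NID: float  # in [0, 1]
    T_end: float         # min

    def __post_init__(self):
        if self.GD_NID < 0 or self.GD_ID < 0:
            raise ValueError("disposal integrals must be non-negative")


def basal_noninsulin_fraction(GEZI: float, SI: float, Ibasal: float) -> float:
    """GEZI / (GEZI + SI*Ibasal), the basal-state non-insulin fraction."""
    if GEZI <= 0:
        raise ValueError("GEZI must be positive")
    if SI < 0 or Ibasal < 0:
        raise ValueError("SI and Ibasal must be non-negative")
    return GEZI / (GEZI + SI * Ibasal)


def disposal_integrals(params: MMParams, subject: SubjectData,
                       grid_step: float = 0.1) -> DisposalResult:
    """Trapezoidal GD_NID and GD_ID over [0, T], T = last observation time."""
    T = float(subject.obs_times[-1])
    grid = np.arange(0.0, T + 0.5 * grid_step, grid_step)
    grid[-1] = T
    G, X = _core.simulate_mm_gx(
        params.GEZI, params.SI, params.p2, params.V, subject.dose,
        subject.Gbasal, subject.Ibasal, subject.forcing.times,
        subject.forcing.concentrations, grid, grid_step)
    if not np.all(np.isfinite(G)):
        raise RuntimeError(f"simulation failed for subject {subject.subject_id}")
    gd_nid = float(np.trapezoid(params.GEZI * G, grid))
    gd_id = float(np.trapezoid(X * G, grid))
    return DisposalResult(GD_NID=gd_nid, GD_ID=gd_id,
                          fraction_NID=gd_nid / (gd_nid + gd_id), T_end=T)


def cohort_disposal(subjects: Sequence[SubjectData],
                    params_by_subject: Mapping[str, MMParams],
                    grid_step: float = 0.1,
                    include_im: bool = False):
    """Per-subject disposal table for a cohort.

    ``params_by_subject`` maps subject ids to individual parameter values
    (typically conditional-mean estimates from a fit).  IM-IVGTT subjects
    are excluded unless ``include_im`` is set.
    """
    import pandas as pd

    rows = []
    for s in subjects:
        if s.test_type == TestType.IM_IVGTT and not include_im:
            continue
        res = disposal_integrals(params_by_subject[s.subject_id], s, grid_step)
        rows.append({"subject_id": s.subject_id,
                     "cohort": s.covariates.get("cohort", "NA"),
                     "GD_NID": res.GD_NID, "GD_ID": res.GD_ID,
                     "fraction_NID": res.fraction_NID, "T_end": res.T_end})
    return pd.DataFrame(rows)


def cohort_fraction_summary(fractions_by_group: Mapping[str, Sequence[float]]):
    """Mean +/- SD (percent), min, max and n of the NID fraction per group."""
    out = {}
    for group, values in fractions_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            raise ValueError(f"group {group!r} needs at least 2 subjects")
        out[group] = {
            "mean_percent": float(100.0 * v.mean()),
            "sd_percent": float(100.0 * v.std(ddof=1)),
            "min_percent": float(100.0 * v.min()),
            "max_percent": float(100.0 * v.max()),
            "n": int(v.size),
        }
    return out


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have n <= 10 and no cross-group ties;
    tie-corrected normal approximation otherwise.  Completely tied data give
    p = 1 with a warning.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("each group needs at least 4 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied across both groups; p = 1")
        return 0.0, 1.0
    ties = np.intersect1d(a, b).size > 0
    method = "exact" if (a.size <= 10 and b.size <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
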