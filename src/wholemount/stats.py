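"""Group-level statistics for density studies.

Treatment studies (ovariectomy, retinoids, diet-induced obesity, ...) compare
small groups of specimens on the eight density measures.  This module keeps
those comparisons deliberately simple and explicit: per-group mean with both
SD and SEM (published tables rarely say which "±" they print, so both are
always reported), percent change of a treated group against its control,
a two-sample t test (Welch by default — equal variances are not assumed for
n of 5–9 animals), and the log–log regression of epithelial volume (ΣOD)
against epithelial area that justifies using the cheaper area measure as a
proxy for volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "summarize_group",
    "percent_reduction",
    "two_group_test",
    "loglog_area_volume_r2",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    se: float


def summarize_group(values) -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and SEM of one group.

    A single observation yields SD = SE = 0 rather than NaN so that tables
    render; n must be at least 1.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(n=int(arr.size), mean=mean, sd=sd, se=sd / np.sqrt(arr.size))


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to control.

    ``100 * (control - treated) / control``; negative values mean the
    treated group increased. The control mean must be positive.
    """
    if not (control_mean > 0):
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return 100.0 * (control_mean - treated_mean) / control_mean


def two_group_test(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test; Welch by default.

    Returns ``(t, p)``.  Set ``equal_var=True`` for the pooled-variance
    (Student) variant.  Each group needs n ≥ 2.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.size == b.size and np.array_equal(a, b):
        return 0.0, 1.0  # identical samples: no evidence, degenerate SE aside
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def loglog_area_volume_r2(areas, volumes) -> float:
    """r² of the OLS regression of log10(volume) on log10(area).

    Both inputs must be strictly positive (log-transform) with n ≥ 3.
    Returns the squared Pearson correlation of the log-transformed data,
    which for simple OLS equals the coefficient of determination.
    """
    areas = np.asarray(areas, dtype=np.float64)
    volumes = np.asarray(volumes, dtype=np.float64)
    if areas.shape != volumes.shape or areas.size < 3:
        raise ValueError("need matched area/volume vectors with n >= 3")
    if (areas <= 0).any() or (volumes <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    res = sps.linregress(np.log10(areas), np.log10(volumes))
    return float(res.rvalue**2)
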