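"""Gated linear regressions and group quantile (box-plot) summaries.

Correlations in this analysis are fit as straight lines ``y = y0 + a*x``
on subsets of the data selected by a "gate" — e.g. fold changes below
10-fold, fold changes up to 40-fold, or ATPase rates below 50 pmol/min —
because the descriptor/efficiency relationships hold only for the weaker
terminators.  r² > 0.3 is treated as the significance convention for these
data.

Box summaries use linear-interpolation percentiles; group contrasts are
reported as the percent reduction of the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError, ValidationError

#: Named gates and the predicate each applies to the gating variable.
GATES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "all": lambda x: np.ones_like(x, dtype=bool),
    "fc_lt_10": lambda x: x < 10.0,
    "fc_gt_10": lambda x: x > 10.0,
    "fc_le_40": lambda x: x <= 40.0,
    "atpase_lt_50": lambda x: x < 50.0,
}

#: r-squared above which a correlation is called significant in these data.
R2_SIGNIFICANCE = 0.3


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of y = y0 + a*x with the subset rule that produced it."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    gate: str = "all"

    @property
    def significant(self) -> bool:
        return self.r2 > R2_SIGNIFICANCE


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary with 10th/90th-percentile whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_values: tuple[float, ...]


def linear_fit(
    x: Sequence[float], y: Sequence[float], gate: str = "all"
) -> RegressionResult:
    """Ordinary least squares of y on x with r² and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise InsufficientDataError(f"need >= 2 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
        gate=gate,
    )


def gated_correlation(
    pairs: Sequence[tuple[float, float]],
    gate: str | float = "all",
    min_points: int = 3,
) -> RegressionResult:
    """Apply a named gate (or an upper x threshold) before a linear fit.

    Named gates: ``all``, ``fc_lt_10``, ``fc_gt_10``, ``fc_le_40``,
    ``atpase_lt_50``; a numeric gate keeps points with ``x < gate``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (x, y) tuples")
    x, y = arr[:, 0], arr[:, 1]
    if isinstance(gate, str):
        if gate not in GATES:
            raise ValidationError(f"unknown gate {gate!r}; options: {sorted(GATES)}")
        mask = GATES[gate](x)
        gate_name = gate
    else:
        mask = x < float(gate)
        gate_name = f"x_lt_{gate:g}"
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"gate {gate_name!r} leaves {int(mask.sum())} points "
            f"(< {min_points} required)"
        )
    return linear_fit(x[mask], y[mask], gate=gate_name)


def box_summary(
    values: Sequence[float],
    whisker_percentiles: tuple[float, float] = (10.0, 90.0),
) -> BoxSummary:
    """Quartiles by linear interpolation, with configurable whiskers.

    Points beyond the whisker percentiles are flagged as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty group")
    lo, hi = whisker_percentiles
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    wlo, whi = np.percentile(v, [lo, hi], method="linear")
    outliers = tuple(float(t) for t in np.sort(v[(v < wlo) | (v > whi)]))
    return BoxSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(wlo),
        whisker_high=float(whi),
        outlier_values=outliers,
    )


def group_box_summary(
    dep_values: Sequence[float],
    indep_values: Sequence[float],
    descriptor_name: str = "",
    whisker_percentiles: tuple[float, float] = (10.0, 90.0),
) -> tuple[BoxSummary, BoxSummary, float]:
    """Box summaries for two groups plus the percent median reduction.

    ``median_reduction = 100 * (median_indep - median_dep) / median_indep``:
    how much lower the dependent group's median descriptor value is than the
    independent group's.
    """
    dep = box_summary(dep_values, whisker_percentiles)
    indep = box_summary(indep_values, whisker_percentiles)
    if indep.median == 0:
        raise ValidationError(
            f"{descriptor_name or 'descriptor'}: independent-group median is 0; "
            "percent reduction undefined"
        )
    reduction = 100.0 * (indep.median - dep.median) / indep.median
    return dep, indep, reduction
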