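"""Validation statistics: bias vs target, one-sample t-test, linearity.

The validation concept prepares sample and reference from a single stock
solution so that the true content ratio w_X/w_Z is exactly 1; deviations
of the measured ratios from this target separate the instrumental and
preparative contributions to the uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .quantities import SingularDesignError, ValidationError
from .msa import fit_addition


@dataclass(frozen=True)
class TTestResult:
    t: float
    t_crit: float
    dof: int
    passed: bool


def target_ttest(
    values: Sequence[float],
    target: float = 1.0,
    alpha: float = 0.975,
    dof_override: Optional[int] = None,
) -> TTestResult:
    """One-sample t-test of the mean against a target value.

    t = (mean - target) / (sd / sqrt n), compared two-sidedly against the
    Student-t quantile ``alpha`` with n - 1 degrees of freedom (a
    different convention can be imposed via ``dof_override``).  A zero sd
    with mean off target is reported as infinite t and a fail.
    """
    n = len(values)
    if n < 2:
        raise ValidationError("t-test needs at least 2 values")
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    dof = dof_override if dof_override is not None else n - 1
    t_crit = float(stats.t.ppf(alpha, dof))
    if sd == 0:
        t = 0.0 if mean == target else math.inf
        return TTestResult(t=t, t_crit=t_crit, dof=dof, passed=mean == target)
    t = (mean - target) / (sd / math.sqrt(n))
    return TTestResult(t=t, t_crit=t_crit, dof=dof, passed=abs(t) < t_crit)


@dataclass(frozen=True)
class BiasReport:
    """Bias and uncertainty components of a replicated target-value design.

    ``u_inst`` is the pooled within-group standard deviation (repeat
    measurement of one blend set: instrument only); ``u_inst_prep`` is the
    standard deviation of the group means (repeat preparation plus
    measurement).  ``u_prep`` is the between-group component with the
    within-group part removed; a negative estimate is truncated to zero
    and flagged.
    """

    bias: float
    u_inst: float
    u_inst_prep: Optional[float]
    u_prep: Optional[float]
    truncated: bool
    n_groups: int


def bias_report(groups: Sequence[Sequence[float]], target: float = 1.0) -> BiasReport:
    """Decompose repeated target-value measurements into bias, u(inst) and
    u(inst)+u(prep).

    Parameters
    ----------
    groups : list of lists
        Each inner list holds the repeat measurements of one preparation
        (one set of blends); groups are independent preparations.
    """
    if not groups or any(len(g) == 0 for g in groups):
        raise ValidationError("bias report needs non-empty groups")
    all_values = [v for g in groups for v in g]
    bias = sum(all_values) / len(all_values) - target
    # pooled within-group variance
    ss_within = 0.0
    dof_within = 0
    for g in groups:
        gm = sum(g) / len(g)
        ss_within += sum((v - gm) ** 2 for v in g)
        dof_within += len(g) - 1
    u_inst = math.sqrt(ss_within / dof_within) if dof_within > 0 else 0.0
    if len(groups) < 2:
        return BiasReport(
            bias=bias, u_inst=u_inst, u_inst_prep=None, u_prep=None,
            truncated=False, n_groups=len(groups),
        )
    means = [sum(g) / len(g) for g in groups]
    grand = sum(means) / len(means)
    u_inst_prep = math.sqrt(sum((m - grand) ** 2 for m in means) / (len(means) - 1))
    n_bar = sum(len(g) for g in groups) / len(groups)
    var_prep = u_inst_prep**2 - u_inst**2 / n_bar
    truncated = var_prep < 0
    u_prep = 0.0 if truncated else math.sqrt(var_prep)
    return BiasReport(
        bias=bias, u_inst=u_inst, u_inst_prep=u_inst_prep, u_prep=u_prep,
        truncated=truncated, n_groups=len(groups),
    )


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    passed: bool
    origin_consistent: bool  # |intercept| < 3 * se(intercept)


def linearity(
    mass_ratios: Sequence[float],
    area_ratios: Sequence[float],
    r2_min: float = 0.999,
) -> LinearityResult:
    """Linear-response check: OLS of area ratio vs mass ratio.

    Passing requires r^2 > ``r2_min``.  The intercept is reported and
    checked for consistency with the expected line through the origin
    (|a0| < 3 se) but never forced to zero.
    """
    if len(mass_ratios) != len(area_ratios):
        raise ValidationError("mass_ratios and area_ratios must have equal length")
    if len(mass_ratios) < 3:
        raise ValidationError("linearity check needs at least 3 points")
    if len(set(mass_ratios)) < 2:
        raise SingularDesignError("all mass ratios identical")
    fit = fit_addition(list(zip(mass_ratios, area_ratios)))
    origin = abs(fit.a0) < 3 * fit.se_a0 if fit.se_a0 > 0 else fit.a0 == 0
    return LinearityResult(
        slope=fit.a1,
        intercept=fit.a0,
        se_slope=fit.se_a1,
        se_intercept=fit.se_a0,
        r2=fit.r2,
        passed=fit.r2 > r2_min,
        origin_consistent=origin,
    )
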