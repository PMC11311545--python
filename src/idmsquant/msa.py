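"""Matched standard-addition IDMS (MSA-IDMS).

Each blend i mixes sample x (mass m_x,i), labeled spike y (m_y,i) and —
for ternary blends — reference solution z (m_z,i) of known mass fraction
w_Z.  Writing the blend's isotopologue amount ratio in the inverted
convention R_b,i = f_inst*A2/A1, the no-overlap series linearizes to

    y_i = (m_y,i/m_x,i) * (1/R_b,i) = a1 * x_i + a0,   x_i = m_z,i/m_x,i,

so with the stored A1/A2 ratio convention y_i = (m_y,i/m_x,i) * r_obs,i.
An unweighted least-squares fit of the points gives slope a1 and
intercept a0, and the analyte content of the sample follows as

    w_X = (a0/a1) * w_Z.

The instrumental bias f_inst scales a0 and a1 equally and cancels in
their ratio; molar-mass and amount-fraction factors cancel the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .quantities import (
    AdditionSeries,
    DomainError,
    IsotopicConstants,
    RegressionResult,
    SingularDesignError,
    UncertainQuantity,
    ValidationError,
)

#: Advisory threshold on the relative spread of the blend ratios; a matched
#: series keeps the signal ratios constant, so a larger spread is flagged.
MATCHING_RSD_LIMIT = 0.02


def linearize(series: AdditionSeries) -> list[tuple[float, float]]:
    """Linearized (x_i, y_i) points of an addition series under the
    no-overlap simplification.

    x_i = m_z,i/m_x,i (0 for the binary blend) and
    y_i = (m_y,i/m_x,i) * r_obs,i with r_obs the stored A1/A2 ratio.
    """
    return linearize_values(
        [(b.m_x.value, b.m_y.value, b.m_z.value, b.r_obs.value) for b in series.blends]
    )


def linearize_values(
    rows: Iterable[tuple[float, float, float, float]],
) -> list[tuple[float, float]]:
    """Linearization on raw (m_x, m_y, m_z, r_obs) values (used per MC draw)."""
    points = []
    for m_x, m_y, m_z, r in rows:
        if r <= 0:
            raise DomainError(f"signal ratio must be > 0, got {r}")
        if m_x <= 0:
            raise DomainError(f"sample mass must be > 0, got {m_x}")
        points.append((m_z / m_x, (m_y / m_x) * r))
    return points


def linearize_general(series: AdditionSeries) -> list[tuple[float, float]]:
    """Linearized points of the general form allowing spectral overlap
    between sample and spike isotopologues.

    With amount fractions x_x1, x_x2 (sample) and x_y1, x_y2 (spike) and
    the inverted ratio R_b,i = 1/r_obs,i,

        y_i = (m_y,i/m_x,i) * (x_y2 - R_b,i*x_y1) / (R_b,i*x_x1 - x_x2).

    Reduces exactly to :func:`linearize` when x_y1 = x_x2 = 0 and
    x_x1 = x_y2 = 1.
    """
    iso = series.isotopic_constants or IsotopicConstants()
    points = []
    for b in series.blends:
        r = b.r_obs.value
        if r <= 0:
            raise DomainError(f"signal ratio must be > 0, got {r}")
        R_b = 1.0 / r  # inverted A2/A1 convention
        denom = R_b * iso.x_x1 - iso.x_x2
        if denom <= 0:
            raise DomainError(
                f"spike/sample overlap inconsistent with ratio in blend "
                f"{b.blend_id!r}: R_b*x_x1 - x_x2 = {denom}"
            )
        y = (b.m_y.value / b.m_x.value) * (iso.x_y2 - R_b * iso.x_y1) / denom
        points.append((b.m_z.value / b.m_x.value, y))
    return points


def fit_addition(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """Ordinary (unweighted) least-squares fit of the linearized points.

    Standard errors come from the residual variance with n - 2 degrees of
    freedom; with exactly two points the errors are reported as 0.
    """
    n = len(points)
    if n < 2:
        raise ValidationError("regression needs at least 2 points")
    a0, a1 = _ols_coefficients(points)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    residuals = [y - (a0 + a1 * x) for x, y in points]
    ss_res = sum(r * r for r in residuals)
    ss_tot = sum((y - ybar) ** 2 for y in ys)
    s2 = ss_res / (n - 2) if n > 2 else 0.0
    se_a1 = math.sqrt(s2 / sxx)
    se_a0 = math.sqrt(s2 * (1.0 / n + xbar * xbar / sxx))
    cov = -s2 * xbar / sxx
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(
        a0=a0,
        a1=a1,
        se_a0=se_a0,
        se_a1=se_a1,
        cov_a0a1=cov,
        r2=r2,
        residuals=tuple(residuals),
        points=tuple((float(x), float(y)) for x, y in points),
    )


def _ols_coefficients(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Closed-form intercept and slope; cheap enough to re-fit per MC draw."""
    n = len(points)
    xbar = sum(p[0] for p in points) / n
    ybar = sum(p[1] for p in points) / n
    sxx = 0.0
    sxy = 0.0
    for x, y in points:
        dx = x - xbar
        sxx += dx * dx
        sxy += dx * (y - ybar)
    if sxx == 0.0:
        raise SingularDesignError("all x values identical; slope undefined")
    a1 = sxy / sxx
    return ybar - a1 * xbar, a1


def msa_mass_fraction(fit: RegressionResult, w_Z: UncertainQuantity) -> float:
    """Analyte mass fraction w_X = (a0/a1) * w_Z of the sample.

    Molar-mass and amount-fraction factors are common to slope and
    intercept and cancel in the ratio, so isotopic constants never enter.
    """
    return fit.ratio * w_Z.value


def quantify(
    series: AdditionSeries,
    exclude: Sequence[str] = (),
) -> tuple[RegressionResult, float]:
    """Linearize, fit and recover w_X in one call.

    Parameters
    ----------
    exclude : sequence of blend ids
        Blends to leave out of the fit (manual outlier exclusion); the
        caller reports both included and excluded fits where relevant.
    """
    if exclude:
        keep = [b for b in series.blends if b.blend_id not in exclude]
        series = AdditionSeries(keep, series.w_Z, series.isotopic_constants)
    fit = fit_addition(linearize(series))
    return fit, msa_mass_fraction(fit, series.w_Z)


@dataclass(frozen=True)
class SeriesMatchingReport:
    """Spread of the observed blend ratios across a matched series."""

    mean: float
    sd: float
    rsd: float
    flagged: bool  # rsd above the advisory matching limit
    n: int


def matching_report(
    series: AdditionSeries,
    rsd_limit: float = MATCHING_RSD_LIMIT,
) -> SeriesMatchingReport:
    """Mean, sample sd (n-1) and RSD of r_obs across the blends.

    A matched series keeps the ratios nearly constant; RSD above
    ``rsd_limit`` is flagged but never blocks computation.
    """
    values = [b.r_obs.value for b in series.blends]
    if len(values) < 2:
        raise ValidationError("matching report needs at least 2 blends")
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    rsd = sd / mean
    return SeriesMatchingReport(
        mean=mean, sd=sd, rsd=rsd, flagged=rsd > rsd_limit, n=len(values)
    )
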