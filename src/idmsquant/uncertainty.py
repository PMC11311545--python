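"""First-order (GUM) propagation and Monte Carlo simulation.

Two complementary budget styles are provided:

* :func:`gum_budget` — sensitivity coefficients c_i = df/dx_i by central
  finite difference, combined as u_c^2 = sum (c_i * u_i,eff)^2.  The
  effective uncertainty folds the standard-error-of-the-mean factor
  1/sqrt(n_repeats) when ``repeat_scaling`` is on.
* :func:`relative_budget` — the simplified tabulated style common in
  IDMS budget tables: every input is assigned a unit relative
  sensitivity, so its variance contribution is (u_i/x_i)^2 / n_repeats
  and the printed "c_i" column reads 1.00, 0.58 (= 1/sqrt 3) or 0.71
  (= 1/sqrt 2).  This reproduces published standard-addition budget
  tables that do not differentiate the nested-regression model.

:func:`monte_carlo` draws every input independently from a Gaussian at
its *stated* standard uncertainty (no repeat scaling by default — the
stated u of a summarised ratio already characterises the quantity that
enters the model) and re-evaluates the full model per draw, including
any nested regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .emd import emd_formula
from .msa import _ols_coefficients, linearize_values
from .quantities import (
    AdditionSeries,
    BudgetRow,
    EMDBlendPair,
    MCSResult,
    PropagationError,
    UncertainQuantity,
    UncertaintyBudget,
    ValidationError,
)

#: Relative step for central finite differences; all models are smooth
#: and well-scaled, so a fixed relative step is adequate.
FD_RELATIVE_STEP = 1e-6

#: Default coverage factor for expanded uncertainties (~95% confidence).
DEFAULT_K = 2.0

#: Fraction of rejected draws above which an MCS result is flagged.
REJECTION_WARNING_FRACTION = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """A deterministic measurement model over uncertain inputs.

    ``function`` maps a value vector (one float per input, in order) to a
    tuple of scalar outputs named by ``output_names``.
    """

    input_names: tuple[str, ...]
    inputs: tuple[UncertainQuantity, ...]
    function: Callable[[Sequence[float]], tuple[float, ...]]
    output_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.input_names) != len(self.inputs):
            raise ValidationError("input_names and inputs must have equal length")

    def at_mean(self) -> tuple[float, ...]:
        return tuple(self.function([q.value for q in self.inputs]))


def effective_u(q: UncertainQuantity, repeat_scaling: bool) -> float:
    """Standard uncertainty entering the propagation, optionally scaled to
    a standard error of the mean."""
    return q.u / math.sqrt(q.n_repeats) if repeat_scaling else q.u


def gum_budget(
    model: ModelSpec,
    k: float = DEFAULT_K,
    repeat_scaling: bool = True,
) -> dict[str, UncertaintyBudget]:
    """First-order uncertainty budget per model output.

    Sensitivities are central finite differences with step
    ``max(|x_i|, 1) * 1e-6``.  Inputs with zero uncertainty contribute a
    zero row (their index is 0 and excluded from the sum-to-one check
    only trivially).
    """
    values = [q.value for q in model.inputs]
    try:
        f0 = model.function(values)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise PropagationError(f"model not evaluable at the mean vector: {exc}") from exc
    n_out = len(f0)
    sens = np.zeros((len(values), n_out))
    for i, x in enumerate(values):
        h = max(abs(x), 1.0) * FD_RELATIVE_STEP
        hi, lo = list(values), list(values)
        hi[i] = x + h
        lo[i] = x - h
        try:
            f_hi = model.function(hi)
            f_lo = model.function(lo)
        except Exception as exc:  # noqa: BLE001
            raise PropagationError(
                f"model not evaluable when perturbing input {model.input_names[i]!r}: {exc}"
            ) from exc
        for j in range(n_out):
            if not (math.isfinite(f_hi[j]) and math.isfinite(f_lo[j])):
                raise PropagationError(
                    f"non-finite model output when perturbing input "
                    f"{model.input_names[i]!r}"
                )
            sens[i, j] = (f_hi[j] - f_lo[j]) / (2 * h)
    budgets: dict[str, UncertaintyBudget] = {}
    u_eff = np.array([effective_u(q, repeat_scaling) for q in model.inputs])
    for j, out_name in enumerate(model.output_names):
        contrib = (sens[:, j] * u_eff) ** 2
        uc2 = float(contrib.sum())
        u_c = math.sqrt(uc2)
        rows = tuple(
            BudgetRow(
                name=model.input_names[i],
                value=values[i],
                u=model.inputs[i].u,
                u_eff=float(u_eff[i]),
                c=float(sens[i, j]),
                contribution=float(contrib[i]),
                index=float(contrib[i] / uc2) if uc2 > 0 else 0.0,
            )
            for i in range(len(values))
        )
        budgets[out_name] = UncertaintyBudget(
            output_name=out_name,
            output_value=float(f0[j]),
            rows=rows,
            u_c=u_c,
            k=k,
        )
    return budgets


def relative_budget(
    named_inputs: Sequence[tuple[str, UncertainQuantity]],
) -> pd.DataFrame:
    """Simplified tabulated budget with unit relative sensitivities.

    Each input with a nonzero value contributes (u/x)^2 / n_repeats to the
    relative combined variance; the ``c_i`` column carries the
    1/sqrt(n_repeats) factor as published budget tables do.  Inputs with a
    zero value (e.g. the binary blend's reference mass) get a dash-like
    zero row.

    Returns a DataFrame with the columns of the published tables:
    ``Mean``, ``u``, ``c_i``, ``c_i^2*u_r^2`` and ``Index``.
    """
    rows = []
    for name, q in named_inputs:
        if q.value == 0 or q.u == 0:
            rows.append((name, q.value, q.u, math.nan, 0.0))
            continue
        c = 1.0 / math.sqrt(q.n_repeats)
        u_r = q.u / abs(q.value)
        rows.append((name, q.value, q.u, c, (c * u_r) ** 2))
    total = sum(r[4] for r in rows)
    df = pd.DataFrame(rows, columns=["Measurand", "Mean", "u", "c_i", "c_i^2*u_r^2"])
    df["Index"] = df["c_i^2*u_r^2"] / total if total > 0 else 0.0
    return df.set_index("Measurand")


def monte_carlo(
    model: ModelSpec,
    n_draws: int = 10_000,
    seed: int = 0,
    retain_samples: bool = False,
    repeat_scaling: bool = False,
) -> dict[str, MCSResult]:
    """Monte Carlo evaluation of a model with independent Gaussian inputs.

    Each input is drawn Gaussian(value, u); the model is re-evaluated per
    draw (a nested regression is re-fit per draw).  Draws on which the
    model fails or returns a non-finite output are rejected and counted;
    more than 1% rejections flags the result.  Fully reproducible for a
    fixed ``seed``.

    The summary reports the mean, sd (n-1), median and the empirical 2.5
    and 97.5 percentiles with the linear-interpolation quantile
    convention.
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    u_eff = [effective_u(q, repeat_scaling) for q in model.inputs]
    draws = np.empty((len(model.inputs), n_draws))
    for i, (q, u) in enumerate(zip(model.inputs, u_eff)):
        draws[i] = rng.normal(q.value, u, n_draws) if u > 0 else q.value
    n_out = len(model.output_names)
    out = np.empty((n_out, n_draws))
    n_rejected = 0
    kept = 0
    func = model.function
    for d in range(n_draws):
        try:
            res = func(draws[:, d])
        except Exception:  # noqa: BLE001 - any model failure rejects the draw
            n_rejected += 1
            continue
        ok = True
        for j in range(n_out):
            if not math.isfinite(res[j]):
                ok = False
                break
        if not ok:
            n_rejected += 1
            continue
        for j in range(n_out):
            out[j, kept] = res[j]
        kept += 1
    if kept == 0:
        raise PropagationError("every Monte Carlo draw was rejected")
    warn = n_rejected > REJECTION_WARNING_FRACTION * n_draws
    if warn:
        warnings.warn(
            f"{n_rejected}/{n_draws} Monte Carlo draws rejected", stacklevel=2
        )
    results: dict[str, MCSResult] = {}
    for j, name in enumerate(model.output_names):
        samples = out[j, :kept]
        p = np.percentile(samples, [2.5, 50.0, 97.5])
        results[name] = MCSResult(
            output_name=name,
            n_draws=n_draws,
            seed=seed,
            mean=float(samples.mean()),
            sd=float(samples.std(ddof=1)) if kept > 1 else 0.0,
            median=float(p[1]),
            percentiles={2.5: float(p[0]), 50.0: float(p[1]), 97.5: float(p[2])},
            n_rejected=n_rejected,
            rejection_warning=warn,
            samples=tuple(float(s) for s in samples) if retain_samples else None,
        )
    return results


def emd_model(pair: EMDBlendPair) -> ModelSpec:
    """The double-IDMS expression as a measurement model with seven inputs."""

    def function(v: Sequence[float]) -> tuple[float, ...]:
        return (emd_formula(v[0], v[1], v[2], v[3], v[4], v[5], v[6]),)

    return ModelSpec(
        input_names=("m_X", "m_Y", "m_Zc", "m_Yc", "R_B", "R_Bc", "w_Zc"),
        inputs=(pair.m_X, pair.m_Y, pair.m_Zc, pair.m_Yc, pair.R_B, pair.R_Bc, pair.w_Zc),
        function=function,
        output_names=("w_X",),
    )


def msa_model(series: AdditionSeries) -> ModelSpec:
    """The nested standard-addition model: every blend mass, every observed
    ratio and w_Z as inputs; linearize -> OLS fit -> w_X per evaluation.

    Outputs are ``a0``, ``a1``, ``a0_over_a1`` and ``w_X``.
    """
    names: list[str] = []
    inputs: list[UncertainQuantity] = []
    for b in series.blends:
        names += [f"m_x,{b.blend_id}", f"m_y,{b.blend_id}", f"m_z,{b.blend_id}", f"R_b,{b.blend_id}"]
        inputs += [b.m_x, b.m_y, b.m_z, b.r_obs]
    names.append("w_Z")
    inputs.append(series.w_Z)
    n_blends = len(series.blends)

    def function(v: Sequence[float]) -> tuple[float, ...]:
        rows = [
            (v[4 * i], v[4 * i + 1], v[4 * i + 2], v[4 * i + 3])
            for i in range(n_blends)
        ]
        a0, a1 = _ols_coefficients(linearize_values(rows))
        ratio = a0 / a1
        return (a0, a1, ratio, ratio * v[4 * n_blends])

    return ModelSpec(
        input_names=tuple(names),
        inputs=tuple(inputs),
        function=function,
        output_names=("a0", "a1", "a0_over_a1", "w_X"),
    )
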