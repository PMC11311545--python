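# Methods

This note records the models implemented in `idmsquant`, the conventions
and defaults they rest on, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Measurement models

**Units.** Masses are mg, mass fractions mg/kg, signal ratios
dimensionless. Every measured input is an `UncertainQuantity`: a value, a
standard uncertainty `u` in the same units, and the number of repeat
observations `n_repeats` that the value summarises.

**Signal-ratio convention.** All stored ratios are A1/A2 — analyte signal
over labeled-spike signal. The standard-addition derivation is written in
terms of the inverted ratio R_b = f_inst·A2/A1; that inversion lives
entirely inside the linearization step, so the ordinate of the linearized
series is simply `y_i = (m_y,i/m_x,i) · r_obs,i` with the stored
convention. This is the single convention that reproduces the published
worked-example fits from the tabulated masses and ratios; it is enforced
by regression tests.

**EMD-IDMS.** `w_X = w_Zc·(m_Y/m_X)·(m_Zc/m_Yc)·(R_B/R_Bc)`, evaluated in
exactly this grouping (no algebraic rearrangement) so that independent
term-by-term transcriptions agree bitwise. QC: each blend ratio should lie
in the matching window [0.95, 1.15]; the ratio of ratios is reported with
its deviation from unity but is not gated, since only the individual
ratios carry a stated window. QC failures set flags, never exceptions.
Bracketed sequences are paired non-overlapping (B, Bc), (B, Bc), …; an odd
trailing measurement is dropped with a logged warning because real
sequences end unevenly.

**MSA-IDMS.** The binary blend enters the fit as an ordinary x = 0 point;
the intercept is estimated, not pinned. The regression is unweighted
ordinary least squares with a free intercept — the only estimator that
reproduces the published fit coefficients from the tabulated data — with
standard errors from the residual variance at n − 2 degrees of freedom.
The general (overlap) linearization
`y_i = (m_y/m_x)·(x_y2 − R_b·x_y1)/(R_b·x_x1 − x_x2)` is provided for
spikes or samples with isotopic cross-contamination and reduces exactly to
the simplified form when x_y1 = x_x2 = 0 and x_x1 = x_y2 = 1. Molar-mass
and amount-fraction factors cancel in a0/a1, so they never affect w_X.
Outlier handling is manual: an exclusion list by blend id, with both the
included and excluded fits reported. A matched series should keep its
blend ratios nearly constant; a relative spread above 2 % is flagged
(advisory only).

## Uncertainty evaluation

**GUM budgets** use central finite differences with relative step 1e-6
(step `max(|x|,1)·1e-6`); all models are smooth and well scaled, so a
fixed relative step suffices. With `repeat_scaling` on (the default), the
effective uncertainty of an input is `u/sqrt(n_repeats)` — the
standard-error-of-the-mean factor that published budget tables fold into
their c_i column as 0.58 (= 1/√3) or 0.71 (= 1/√2). Contribution indices
are `(c_i·u_i,eff)²/u_c²` and sum to one.

**Tabulated relative budgets** (`relative_budget`) reproduce the
simplified budget style common in standard-addition tables: every input is
assigned a *unit relative sensitivity*, so its contribution is
`(u/x)²/n_repeats` regardless of the model structure. This is a
documentation/comparison artifact, not a first-order propagation: for the
nested-regression model the true derivative-based indices differ
substantially (the dominant ratio input carries an even larger share under
exact sensitivities). Both styles are exposed so either can be compared
against published tables.

**Monte Carlo** draws every input independently from a Gaussian at its
*stated* standard uncertainty — no repeat scaling by default — and
re-evaluates the full model per draw, re-fitting the nested regression
each time. The unscaled default is deliberate: the published Monte Carlo
summaries of the worked examples (regression-coefficient means and
standard deviations, coverage intervals of the target-value series) are
reproduced exactly with the tabulated u values used as-is, and not when
the 1/√N factor is applied; the budget tables, by contrast, do fold 1/√N
into their c_i. Both engines therefore expose the flag with opposite
defaults. Summaries report mean, sd (n − 1), median and the empirical
2.5/97.5 percentiles with the linear-interpolation quantile convention
(the behavior of common spreadsheet percentile functions). Draws on which
the model fails (e.g. a non-positive drawn ratio, or a degenerate fit) are
rejected and counted rather than clipped — clipping would distort exactly
the distribution tails the method exists to expose; more than 1 %
rejections flags the result. Input distributions are Gaussian and
uncorrelated throughout; adaptive stopping and non-Gaussian inputs are out
of scope.

One internal inconsistency of the worked examples is worth recording: for
the matrix-sample model, the published regression-coefficient marginals
(a0 ≈ 2.053 ± 0.036, a1 ≈ 1.620 ± 0.210) are mutually incompatible with
the published 2.5/97.5 percentiles of the propagated content
(9.4/19.4 mg/kg) — no joint Gaussian input convention yields both, since
sd(a0/a1) is bounded by the coefficient marginals. `idmsquant` matches the
coefficient marginals and the solution-series coverage intervals; its
content percentiles for that model are accordingly tighter
(≈ 9.9/17.6 mg/kg at the same median 12.8 mg/kg) while preserving the
documented right skew (mean > median). No noise-inflation factor is
applied to force the wider printed interval.

## Validation statistics

The validation design prepares sample and reference from one stock so the
true content ratio is exactly 1. `target_ttest` compares measured ratios
against this target with a two-sided Student-t criterion at the 0.975
quantile and n − 1 degrees of freedom (for n = 8 values the critical value
is 2.36; `dof_override` accommodates other conventions). `bias_report`
separates the pooled within-group sd (instrument repeatability, u(inst))
from the sd of group means (instrument + preparation); the pure
preparation component subtracts the within part and truncates negative
estimates to zero with a flag. `linearity` fits area ratio against mass
ratio with a free intercept, passes at r² > 0.999, and checks
through-origin consistency as |intercept| < 3·se rather than forcing it.

## Synthetic experiments

The generator emulates: gravimetric noise (default 0.1 % relative on every
mass, matching the fixture tables' u(m)/m), Gaussian signal-ratio noise
(default 2.5 % relative, inside the 2–3 % repeatability range typical of
these two analytes), a multiplicative instrument bias f_inst (default 1)
and linear drift per injection (default 0). The ideal blend ratio is
`f_inst·(m_x·w_X + m_z·w_Z)/(m_y·w_Y)`, the exact inversion of the
linearized model, so the noiseless pipeline round-trips w_X to machine
precision and f_inst cancels in a0/a1. The default blend design is one
~500 mg sample + ~100 mg spike binary blend and reference additions of
50/100/150 mg. The effective spike mass fraction w_Y defaults to the value
that matches the binary blend's ratio to 1.

Drift is linear in injection order — the simulator's model of a
qualitative effect, not a measured one. Under this model a longer series
accumulates more drift at the high-addition end, so the *mean* bias of the
recovered content grows slowly with the number of blends while the
replicate-to-replicate *dispersion* shrinks; the drift study asserts
monotone |bias| in drift magnitude and reduced dispersion with more
blends. Ratio repeats are averaged, with the repeat sample sd recorded as
the stored uncertainty.

What passing synthetic tests show: the estimators are consistent, the bias
cancellations are exact, and the Monte Carlo intervals have roughly
nominal coverage under the stated noise model. What they do not show:
robustness to matrix effects, chromatographic interferences, non-Gaussian
ratio noise, or correlated weighing errors — none of which the generator
models.

## Numerical choices and edge cases

- OLS is solved in closed form from centered sums (numerically adequate
  for the small, well-scaled designs here; verified against
  normal-equations and statsmodels oracles to 1e-8 or better). An
  all-identical-x design raises a singular-design error.
- A standard with w_Zc = 0 (a blank) is allowed and propagates to
  w_X = 0; masses and ratios must be strictly positive.
- Percentile convention: linear interpolation between order statistics.
- The per-blend ratio repeat counts of the shipped fixtures (N = 3 for the
  solution series, N = 2 for the PT series, including its w_Z) mirror the
  published budget tables.
- Problem sizes: 10⁶ draws for the double-IDMS Monte Carlo (scalar model),
  10⁴ for the nested-regression models — the sizes at which the published
  summaries were produced; both run in seconds.

## Known limitations

- No weighted, Deming or errors-in-variables regression; ratio
  uncertainties enter through the budgets and Monte Carlo, not the fit.
- No correlations between inputs anywhere in the propagation.
- Single-point (one-blend) IDMS is not implemented.
- The CLI reads ratio-level blend tables only; chromatograms and peak
  integration are upstream of this package.
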