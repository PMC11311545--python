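"""Domain types shared by all quantification and uncertainty modules.

Units are fixed by convention throughout the package: masses in mg, mass
fractions in mg/kg, isotopologue signal ratios dimensionless.  Every
measured input is carried as an :class:`UncertainQuantity` — a value with
a standard uncertainty and the number of repeat observations it summarises.

Signal-ratio convention
-----------------------
``r_obs`` is always stored as A1/A2: the signal area of the analyte with
natural isotopic composition (A1) over that of the isotopically labeled
spike (A2).  The inverted ratio f_inst*A2/A1 that appears in the
standard-addition derivation exists only inside the linearization step
(:mod:`idmsquant.msa`), never in stored data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class IdmsError(Exception):
    """Base class for all idmsquant errors."""


class ValidationError(IdmsError, ValueError):
    """Invalid domain object or input data."""


class DomainError(IdmsError, ValueError):
    """Mathematically invalid input to a computation (e.g. r_obs <= 0)."""


class ConfigError(IdmsError, ValueError):
    """Invalid configuration (e.g. inverted QC window bounds)."""


class SequencingError(IdmsError, ValueError):
    """Bracketed measurement sequence violates the B/Bc alternation."""


class SingularDesignError(IdmsError, ValueError):
    """Regression design matrix is singular (all x identical)."""


class PropagationError(IdmsError, ValueError):
    """Model not evaluable during uncertainty propagation."""


class BlendTableError(IdmsError, ValueError):
    """Blend-table file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class UncertainQuantity:
    """A measured value with standard uncertainty.

    Parameters
    ----------
    value : float
        The best estimate (mg, mg/kg or dimensionless depending on context).
    u : float
        Standard uncertainty in the same units, >= 0.
    n_repeats : int
        Number of repeat observations the value summarises (1 for a single
        determination).  Budget routines may fold a 1/sqrt(n_repeats)
        standard-error-of-the-mean factor into the effective uncertainty.
    """

    value: float
    u: float = 0.0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(f"value must be finite, got {self.value}")
        if not (math.isfinite(self.u) and self.u >= 0):
            raise ValidationError(f"standard uncertainty must be >= 0, got {self.u}")
        if self.n_repeats < 1 or int(self.n_repeats) != self.n_repeats:
            raise ValidationError(f"n_repeats must be a positive integer, got {self.n_repeats}")

    @property
    def relative_u(self) -> float:
        """u / |value|; undefined for a zero value."""
        return relative_u(self)


def relative_u(q: UncertainQuantity) -> float:
    """Relative standard uncertainty u/|value| of a quantity.

    Raises
    ------
    DomainError
        If ``q.value`` is zero, where the relative uncertainty is undefined.
    """
    if q.value == 0:
        raise DomainError("relative uncertainty undefined for zero value")
    return q.u / abs(q.value)


def _require_positive(name: str, q: UncertainQuantity) -> None:
    if q.value <= 0:
        raise ValidationError(f"{name} must be > 0, got {q.value}")


@dataclass(frozen=True)
class EMDBlendPair:
    """Sample-blend / calibration-blend bracket of an exact-matching
    double-IDMS experiment.

    The sample blend B mixes sample X (mass ``m_X``) with spike Y
    (``m_Y``); the calibration blend Bc mixes primary standard Z
    (``m_Zc``, known mass fraction ``w_Zc``) with spike Y (``m_Yc``).
    ``R_B`` and ``R_Bc`` are the observed A1/A2 signal ratios of the two
    blends.
    """

    m_X: UncertainQuantity
    m_Y: UncertainQuantity
    m_Zc: UncertainQuantity
    m_Yc: UncertainQuantity
    R_B: UncertainQuantity
    R_Bc: UncertainQuantity
    w_Zc: UncertainQuantity

    def __post_init__(self) -> None:
        for name in ("m_X", "m_Y", "m_Zc", "m_Yc", "R_B", "R_Bc"):
            _require_positive(name, getattr(self, name))
        # w_Zc = 0 is permitted: a blank standard propagates to w_X = 0.
        if self.w_Zc.value < 0:
            raise ValidationError(f"w_Zc must be >= 0, got {self.w_Zc.value}")


@dataclass(frozen=True)
class AdditionBlend:
    """One gravimetric blend of a standard-addition series.

    Binary blends (sample + spike) have ``m_z`` exactly 0; ternary blends
    add a mass ``m_z`` of the reference solution.
    """

    blend_id: str
    m_x: UncertainQuantity
    m_y: UncertainQuantity
    m_z: UncertainQuantity
    r_obs: UncertainQuantity

    def __post_init__(self) -> None:
        _require_positive("m_x", self.m_x)
        _require_positive("m_y", self.m_y)
        if self.m_z.value < 0:
            raise ValidationError(f"m_z must be >= 0, got {self.m_z.value}")
        _require_positive("r_obs", self.r_obs)

    @property
    def is_binary(self) -> bool:
        return self.m_z.value == 0


@dataclass(frozen=True)
class IsotopicConstants:
    """Molar masses and amount fractions for the general (overlapping)
    standard-addition form.

    Defaults encode the no-overlap simplification: the spike contains no
    target analyte (``x_y1 = 0``) and the sample contains no spike
    isotopologue (``x_x2 = 0``).
    """

    M_x: float = 1.0
    M_y: float = 1.0
    x_x1: float = 1.0
    x_x2: float = 0.0
    x_y1: float = 0.0
    x_y2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("x_x1", "x_x2", "x_y1", "x_y2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"amount fraction {name} must be in [0, 1], got {v}")
        if self.M_x <= 0 or self.M_y <= 0:
            raise ValidationError("molar masses must be > 0")


@dataclass(frozen=True)
class AdditionSeries:
    """A matched standard-addition series: one (or more) binary blend plus
    ternary blends with increasing reference additions, and the reference
    mass fraction ``w_Z``."""

    blends: tuple[AdditionBlend, ...]
    w_Z: UncertainQuantity
    isotopic_constants: Optional[IsotopicConstants] = None

    def __init__(
        self,
        blends: Sequence[AdditionBlend],
        w_Z: UncertainQuantity,
        isotopic_constants: Optional[IsotopicConstants] = None,
    ) -> None:
        object.__setattr__(self, "blends", tuple(blends))
        object.__setattr__(self, "w_Z", w_Z)
        object.__setattr__(self, "isotopic_constants", isotopic_constants)
        self.__post_init__()

    def __post_init__(self) -> None:
        if len(self.blends) < 2:
            raise ValidationError("an addition series needs at least 2 blends")
        if not any(b.is_binary for b in self.blends):
            raise ValidationError("an addition series needs at least one binary blend")
        if not any(not b.is_binary for b in self.blends):
            raise ValidationError("an addition series needs at least one ternary blend")
        xs = {b.m_z.value / b.m_x.value for b in self.blends}
        if len(xs) < 2:
            raise ValidationError("at least 2 distinct x = m_z/m_x values are required")
        if self.w_Z.value <= 0:
            raise ValidationError("w_Z must be > 0")


@dataclass(frozen=True)
class RegressionResult:
    """Unweighted least-squares line fit y = a0 + a1*x with standard
    errors from the residual variance (n - 2 degrees of freedom)."""

    a0: float
    a1: float
    se_a0: float
    se_a1: float
    cov_a0a1: float
    r2: float
    residuals: tuple[float, ...]
    points: tuple[tuple[float, float], ...]

    @property
    def ratio(self) -> float:
        """Intercept-to-slope ratio a0/a1 — the recovered w_X/w_Z."""
        if self.a1 == 0:
            raise DomainError("a1 = 0: no signal from the standard additions")
        return self.a0 / self.a1


@dataclass(frozen=True)
class BudgetRow:
    """One input's line in a GUM uncertainty budget."""

    name: str
    value: float
    u: float
    u_eff: float
    c: float
    contribution: float  # (c * u_eff)^2
    index: float  # contribution / u_c^2


@dataclass(frozen=True)
class UncertaintyBudget:
    """First-order (GUM) uncertainty budget for one model output."""

    output_name: str
    output_value: float
    rows: tuple[BudgetRow, ...]
    u_c: float
    k: float

    @property
    def U(self) -> float:
        """Expanded uncertainty k * u_c."""
        return self.k * self.u_c


@dataclass(frozen=True)
class MCSResult:
    """Summary of a Monte-Carlo-simulated output distribution."""

    output_name: str
    n_draws: int
    seed: int
    mean: float
    sd: float
    median: float
    percentiles: dict[float, float] = field(default_factory=dict)
    n_rejected: int = 0
    rejection_warning: bool = False
    samples: Optional[tuple[float, ...]] = None
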