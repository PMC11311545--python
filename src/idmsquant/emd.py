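"""Exact-matching double IDMS (EMD-IDMS) quantification.

The sample blend B (sample X + labeled spike Y) and the calibration blend
Bc (primary standard Z + the same spike Y) are prepared so their A1/A2
signal ratios nearly match.  The mass fraction of the analyte in the
sample then follows from the ratio of ratios,

    w_X = w_Zc * (m_Y / m_X) * (m_Zc / m_Yc) * (R_B / R_Bc),

in which any multiplicative instrumental bias on the two measured ratios
cancels.  The expression is evaluated in exactly this grouping.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .quantities import (
    ConfigError,
    DomainError,
    EMDBlendPair,
    SequencingError,
)

logger = logging.getLogger(__name__)

#: Matching window for the individual blend ratios R_B and R_Bc: both
#: should fall inside this interval for minimum measurement uncertainty.
MATCHING_WINDOW: tuple[float, float] = (0.95, 1.15)


def emd_mass_fraction(pair: EMDBlendPair) -> float:
    """Analyte mass fraction w_X (mg/kg) of the sample from one
    sample-blend / calibration-blend pair.

    A pure function of the seven inputs; uncertainties on the pair are
    ignored here (see :mod:`idmsquant.uncertainty` for budgets).
    """
    return emd_formula(
        pair.m_X.value,
        pair.m_Y.value,
        pair.m_Zc.value,
        pair.m_Yc.value,
        pair.R_B.value,
        pair.R_Bc.value,
        pair.w_Zc.value,
    )


def emd_formula(
    m_X: float,
    m_Y: float,
    m_Zc: float,
    m_Yc: float,
    R_B: float,
    R_Bc: float,
    w_Zc: float,
) -> float:
    """The double-IDMS expression on raw values (used per Monte Carlo draw)."""
    if min(m_X, m_Y, m_Zc, m_Yc, R_B, R_Bc) <= 0:
        raise DomainError("masses and ratios must be > 0")
    return w_Zc * (m_Y / m_X) * (m_Zc / m_Yc) * (R_B / R_Bc)


@dataclass(frozen=True)
class MatchingReport:
    """QC flags of the exact-matching check (never raises on failure)."""

    r_b: float
    r_bc: float
    r_b_in_window: bool
    r_bc_in_window: bool
    ratio_of_ratios: float
    deviation_from_unity: float
    window: tuple[float, float]

    @property
    def all_pass(self) -> bool:
        return self.r_b_in_window and self.r_bc_in_window


def emd_matching_check(
    pair: EMDBlendPair,
    window_low: float = MATCHING_WINDOW[0],
    window_high: float = MATCHING_WINDOW[1],
) -> MatchingReport:
    """Check both blend ratios against the matching window and report
    how far R_B/R_Bc deviates from unity.

    The window constrains each ratio individually; the ratio of ratios is
    only reported, not gated.
    """
    if window_low >= window_high:
        raise ConfigError(
            f"matching window is empty: [{window_low}, {window_high}]"
        )
    r_b, r_bc = pair.R_B.value, pair.R_Bc.value
    ratio = r_b / r_bc
    return MatchingReport(
        r_b=r_b,
        r_bc=r_bc,
        r_b_in_window=window_low <= r_b <= window_high,
        r_bc_in_window=window_low <= r_bc <= window_high,
        ratio_of_ratios=ratio,
        deviation_from_unity=ratio - 1.0,
        window=(window_low, window_high),
    )


@dataclass(frozen=True)
class BracketedSummary:
    """Per-pair R_B/R_Bc ratios of a bracketed B/Bc sequence."""

    pairs: tuple[tuple[float, float], ...]  # (R_B, R_Bc) per bracket
    ratios: tuple[float, ...]
    mean: float
    sd: float


def bracketed_pairs(
    sequence: Sequence[tuple[str, float]],
) -> BracketedSummary:
    """Pair up an alternating bracketed measurement sequence.

    Parameters
    ----------
    sequence : list of (label, ratio)
        Labels are ``"B"`` (sample blend) or ``"Bc"`` (calibration blend);
        the sequence must alternate, starting with either label.  Each
        non-overlapping adjacent pair contributes one R_B/R_Bc value.

    An odd trailing measurement is dropped with a logged warning.
    """
    if len(sequence) < 2:
        raise SequencingError("bracketed sequence needs at least 2 measurements")
    for label, value in sequence:
        if label not in ("B", "Bc"):
            raise SequencingError(f"unknown label {label!r}; expected 'B' or 'Bc'")
        if value <= 0:
            raise DomainError("signal ratios must be > 0")
    for pos in range(1, len(sequence)):
        if sequence[pos][0] == sequence[pos - 1][0]:
            raise SequencingError(
                f"two {sequence[pos][0]!r} measurements adjacent at position {pos + 1}"
            )
    seq = list(sequence)
    if len(seq) % 2:
        logger.warning(
            "odd trailing %s measurement dropped from bracketed sequence", seq[-1][0]
        )
        seq = seq[:-1]
    pairs: list[tuple[float, float]] = []
    ratios: list[float] = []
    for i in range(0, len(seq), 2):
        (la, va), (lb, vb) = seq[i], seq[i + 1]
        r_b, r_bc = (va, vb) if la == "B" else (vb, va)
        pairs.append((r_b, r_bc))
        ratios.append(r_b / r_bc)
    sd = statistics.stdev(ratios) if len(ratios) > 1 else 0.0
    return BracketedSummary(
        pairs=tuple(pairs),
        ratios=tuple(ratios),
        mean=statistics.fmean(ratios),
        sd=sd,
    )
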