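"""Synthetic gravimetric IDMS experiments.

The simulator emulates the noise structure of a matched standard-addition
(or exact-matching double-IDMS) experiment: gravimetric noise of ~0.1%
relative on every mass, Gaussian signal-ratio noise of a few percent
relative, an optional multiplicative instrument bias f_inst and an
optional linear drift across the injection sequence.  The underlying
signal model takes the A1/A2 ratio proportional to the analyte-to-spike
mass ratio in the blend,

    r_ideal = f_inst * (m_x*w_X + m_z*w_Z) / (m_y * w_Y),

which inverts the linearized standard-addition relation exactly: with
zero noise the full pipeline recovers w_X = true_w_X to machine
precision, and f_inst cancels in a0/a1.

Drift is modelled as linear in injection order; this is the simulator's
model of the qualitative effect, chosen for its simplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emd import emd_mass_fraction
from .msa import quantify
from .quantities import (
    AdditionBlend,
    AdditionSeries,
    EMDBlendPair,
    UncertainQuantity,
    ValidationError,
)

#: Default blend design: constant ~500 mg sample and ~100 mg spike with
#: reference additions of 0/50/100/150 mg, as in a typical matrix series.
DEFAULT_DESIGN: tuple[tuple[float, float, float], ...] = (
    (500.0, 100.0, 0.0),
    (500.0, 100.0, 50.0),
    (500.0, 100.0, 100.0),
    (500.0, 100.0, 150.0),
)


def make_design(
    n_blends: int,
    m_x: float = 500.0,
    m_y: float = 100.0,
    z_step: float = 50.0,
) -> tuple[tuple[float, float, float], ...]:
    """A design with one binary blend and n_blends - 1 equally spaced
    reference additions."""
    if n_blends < 2:
        raise ValidationError("a design needs at least 2 blends")
    return tuple((m_x, m_y, z_step * i) for i in range(n_blends))


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions of one simulated experiment.

    ``w_Y`` is the effective mass fraction of the spike solution (it
    absorbs the isotopologue response factor); when None it is chosen so
    that the binary blend's ideal signal ratio is exactly 1 (a perfectly
    matched spike).
    """

    true_w_X: float = 12.4  # mg/kg
    w_Z: float = 10.08  # mg/kg
    blend_design: tuple[tuple[float, float, float], ...] = DEFAULT_DESIGN
    weighing_rsd: float = 1e-3
    ratio_rsd: float = 0.025
    f_inst: float = 1.0
    drift_per_injection: float = 0.0
    n_ratio_repeats: int = 3
    w_Y: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weighing_rsd < 0 or self.ratio_rsd < 0:
            raise ValidationError("relative standard deviations must be >= 0")
        if self.f_inst <= 0:
            raise ValidationError("f_inst must be > 0")
        if self.true_w_X <= 0 or self.w_Z <= 0:
            raise ValidationError("mass fractions must be > 0")
        if self.n_ratio_repeats < 1:
            raise ValidationError("n_ratio_repeats must be >= 1")
        if not any(m_z == 0 for _, _, m_z in self.blend_design):
            raise ValidationError("blend design needs a binary blend (m_z = 0)")
        if not any(m_z > 0 for _, _, m_z in self.blend_design):
            raise ValidationError("blend design needs a ternary blend (m_z > 0)")

    @property
    def spike_w(self) -> float:
        if self.w_Y is not None:
            return self.w_Y
        m_x0, m_y0, _ = self.blend_design[0]
        return self.true_w_X * m_x0 / m_y0


def _draw_mass(rng: np.random.Generator, target: float, rsd: float) -> UncertainQuantity:
    if target == 0:
        return UncertainQuantity(0.0, 0.0)
    u = rsd * target
    value = rng.normal(target, u) if u > 0 else target
    return UncertainQuantity(value, u)


def simulate_series(scenario: SimulationScenario) -> AdditionSeries:
    """Generate one standard-addition series under the scenario.

    Masses are the design targets plus Gaussian weighing noise; the
    observed ratio of blend i (injection index i, in design order) is the
    mean of ``n_ratio_repeats`` Gaussian draws around
    ``r_ideal * (1 + drift * i)``, with the repeat sample sd recorded
    (or the nominal noise level for a single repeat).  Deterministic
    under the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    w_y = scenario.spike_w
    blends = []
    for i, (t_x, t_y, t_z) in enumerate(scenario.blend_design):
        m_x = _draw_mass(rng, t_x, scenario.weighing_rsd)
        m_y = _draw_mass(rng, t_y, scenario.weighing_rsd)
        m_z = _draw_mass(rng, t_z, scenario.weighing_rsd)
        r_ideal = (
            scenario.f_inst
            * (m_x.value * scenario.true_w_X + m_z.value * scenario.w_Z)
            / (m_y.value * w_y)
        )
        r_det = r_ideal * (1.0 + scenario.drift_per_injection * i)
        n = scenario.n_ratio_repeats
        sigma = scenario.ratio_rsd * r_det
        if sigma > 0:
            repeats = rng.normal(r_det, sigma, n)
            r_val = float(repeats.mean())
            u_r = float(repeats.std(ddof=1)) if n > 1 else sigma
        else:
            r_val, u_r = r_det, 0.0
        blends.append(
            AdditionBlend(
                blend_id=str(i + 1),
                m_x=m_x,
                m_y=m_y,
                m_z=m_z,
                r_obs=UncertainQuantity(r_val, u_r, n_repeats=n),
            )
        )
    return AdditionSeries(blends, w_Z=UncertainQuantity(scenario.w_Z, 0.0))


def simulate_emd_pair(scenario: SimulationScenario) -> EMDBlendPair:
    """Generate a matched sample-blend / calibration-blend pair from the
    same signal model.

    The calibration blend's standard mass is chosen to match the sample
    blend's ideal ratio exactly, as in exact-matching practice."""
    rng = np.random.default_rng(scenario.seed)
    t_x, t_y, _ = scenario.blend_design[0]
    w_y = scenario.spike_w
    m_X = _draw_mass(rng, t_x, scenario.weighing_rsd)
    m_Y = _draw_mass(rng, t_y, scenario.weighing_rsd)
    t_zc = t_x * scenario.true_w_X / scenario.w_Z
    m_Zc = _draw_mass(rng, t_zc, scenario.weighing_rsd)
    m_Yc = _draw_mass(rng, t_y, scenario.weighing_rsd)
    r_b_ideal = scenario.f_inst * m_X.value * scenario.true_w_X / (m_Y.value * w_y)
    r_bc_ideal = scenario.f_inst * m_Zc.value * scenario.w_Z / (m_Yc.value * w_y)
    ratios = []
    for ideal in (r_b_ideal, r_bc_ideal):
        sigma = scenario.ratio_rsd * ideal
        n = scenario.n_ratio_repeats
        if sigma > 0:
            repeats = rng.normal(ideal, sigma, n)
            val = float(repeats.mean())
            u = float(repeats.std(ddof=1)) if n > 1 else sigma
        else:
            val, u = ideal, 0.0
        ratios.append(UncertainQuantity(val, u, n_repeats=n))
    return EMDBlendPair(
        m_X=m_X,
        m_Y=m_Y,
        m_Zc=m_Zc,
        m_Yc=m_Yc,
        R_B=ratios[0],
        R_Bc=ratios[1],
        w_Zc=UncertainQuantity(scenario.w_Z, 0.0),
    )


def recovered_w_x(series: AdditionSeries) -> float:
    """Convenience: run the full standard-addition pipeline on a series."""
    _, w_x = quantify(series)
    return w_x


def drift_study(
    base: SimulationScenario,
    drifts: Sequence[float],
    n_blends_list: Sequence[int] = (3, 4, 5),
    n_repeats_list: Sequence[int] = (1, 3),
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean signed relative bias of the recovered w_X over a grid of drift
    magnitudes, blend counts and ratio-repeat counts.

    Each grid cell averages ``n_replicates`` simulated experiments; the
    replicate seeds derive deterministically from ``seed``.
    """
    if not drifts:
        raise ValidationError("drift grid must be non-empty")
    rows = []
    cell = 0
    for drift in drifts:
        for n_blends in n_blends_list:
            design = make_design(n_blends)
            for n_rep in n_repeats_list:
                biases = np.empty(n_replicates)
                for r in range(n_replicates):
                    scen = replace(
                        base,
                        blend_design=design,
                        drift_per_injection=drift,
                        n_ratio_repeats=n_rep,
                        seed=(seed + 7919 * cell + r) % (2**31),
                    )
                    w_hat = recovered_w_x(simulate_series(scen))
                    biases[r] = (w_hat - scen.true_w_X) / scen.true_w_X
                rows.append(
                    {
                        "drift": drift,
                        "n_blends": n_blends,
                        "n_repeats": n_rep,
                        "mean_bias": float(biases.mean()),
                        "sd_bias": float(biases.std(ddof=1)),
                        "se_bias": float(biases.std(ddof=1) / math.sqrt(n_replicates)),
                        "n_replicates": n_replicates,
                    }
                )
                cell += 1
    return pd.DataFrame(rows)
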