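"""Worked-example blend tables shipped with the package.

These are the published input sets of the melamine / cyanuric acid
infant-formula study: one exact-matching double-IDMS measurement of
melamine in a proficiency-testing (PT) sample, two same-stock
standard-addition series (melamine and cyanuric acid solutions, target
value w_X/w_Z = 1) and one standard-addition series of melamine in the
PT matrix sample.  All numbers load from the CSV files under
``idmsquant/data`` through the ordinary blend-table reader.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_blend_table
from .quantities import AdditionSeries, EMDBlendPair, UncertainQuantity

#: Mass fraction of the melamine reference solution used for the PT-sample
#: standard additions (mg/kg).  The published budget treats it with the
#: same N = 2 repeat factor as the blend ratios (its tabulated c_i is
#: 1/sqrt 2), so the repeat count is carried here.
W_Z_PT = UncertainQuantity(10.080, 0.020, n_repeats=2)


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped fixture CSV."""
    return Path(str(resources.files("idmsquant").joinpath("data", name)))


def table2_emd_mel_pt() -> EMDBlendPair:
    """EMD-IDMS blend pair for melamine in the PT sample (w_X ~ 12.43 mg/kg)."""
    pair = read_blend_table(fixture_path("table2_emd_mel_pt.csv"), kind="emd")
    assert isinstance(pair, EMDBlendPair)
    return pair


def table4_msa_mel() -> AdditionSeries:
    """Same-stock melamine solution series (target a0/a1 = 1; measured 1.004)."""
    series = read_blend_table(fixture_path("table4_msa_mel.csv"), kind="msa")
    assert isinstance(series, AdditionSeries)
    return series


def table5_msa_cya() -> AdditionSeries:
    """Same-stock cyanuric acid solution series (target a0/a1 = 1; measured 0.994)."""
    series = read_blend_table(fixture_path("table5_msa_cya.csv"), kind="msa")
    assert isinstance(series, AdditionSeries)
    return series


def table6_msa_mel_pt() -> AdditionSeries:
    """Melamine standard additions in the PT infant-formula sample
    (w_Z = 10.08 mg/kg; recovered w_X ~ 12.8 mg/kg)."""
    series = read_blend_table(
        fixture_path("table6_msa_mel_pt.csv"), kind="msa", w_z=W_Z_PT
    )
    assert isinstance(series, AdditionSeries)
    return series
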