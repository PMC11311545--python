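"""Blend-table readers/writers and JSON report serialization.

Two CSV dialects (strict header, decimal point, UTF-8):

* ``msa`` — one row per blend:
  ``blend_id,m_x_mg,u_m_x_mg,m_y_mg,u_m_y_mg,m_z_mg,u_m_z_mg,r_obs,u_r_obs,n_repeats``
* ``emd`` — long format, one row per quantity:
  ``role,quantity,value,u,n_repeats`` with roles ``sample_blend``
  (quantities m_sample, m_spike, ratio), ``calib_blend`` (m_standard,
  m_spike, ratio) and ``standard`` (w_zc).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .quantities import (
    AdditionBlend,
    AdditionSeries,
    BlendTableError,
    EMDBlendPair,
    MCSResult,
    UncertainQuantity,
    UncertaintyBudget,
    ValidationError,
)

MSA_COLUMNS = [
    "blend_id",
    "m_x_mg",
    "u_m_x_mg",
    "m_y_mg",
    "u_m_y_mg",
    "m_z_mg",
    "u_m_z_mg",
    "r_obs",
    "u_r_obs",
    "n_repeats",
]

EMD_COLUMNS = ["role", "quantity", "value", "u", "n_repeats"]

_EMD_SLOTS = {
    ("sample_blend", "m_sample"): "m_X",
    ("sample_blend", "m_spike"): "m_Y",
    ("sample_blend", "ratio"): "R_B",
    ("calib_blend", "m_standard"): "m_Zc",
    ("calib_blend", "m_spike"): "m_Yc",
    ("calib_blend", "ratio"): "R_Bc",
    ("standard", "w_zc"): "w_Zc",
}


def _read_csv(path: Union[str, Path], expected: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise BlendTableError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            encoding="utf-8",
            dtype={"blend_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise BlendTableError(f"empty blend table: {path}") from exc
    for col in expected:
        if col not in df.columns:
            raise BlendTableError(f"missing column {col!r} in {path}")
    return df


def read_blend_table(
    path: Union[str, Path],
    kind: str,
    w_z: Optional[UncertainQuantity] = None,
) -> Union[EMDBlendPair, AdditionSeries]:
    """Parse a blend table.

    Parameters
    ----------
    kind : {"emd", "msa"}
    w_z : UncertainQuantity, optional
        Reference mass fraction for an MSA series.  Defaults to an exact
        1.0, the convention of target-value (same-stock) experiments
        where only a0/a1 is of interest.
    """
    if kind == "msa":
        return _read_msa(path, w_z or UncertainQuantity(1.0, 0.0))
    if kind == "emd":
        return _read_emd(path)
    raise ValidationError(f"unknown blend-table kind {kind!r}")


def _read_msa(path: Union[str, Path], w_z: UncertainQuantity) -> AdditionSeries:
    df = _read_csv(path, MSA_COLUMNS)
    blends = []
    for idx, row in df.iterrows():
        for col in ("m_x_mg", "m_y_mg", "m_z_mg"):
            if float(row[col]) < 0:
                raise ValidationError(
                    f"negative mass {col}={row[col]} in row {idx + 1}"
                )
        try:
            blends.append(
                AdditionBlend(
                    blend_id=str(row["blend_id"]),
                    m_x=UncertainQuantity(float(row["m_x_mg"]), float(row["u_m_x_mg"])),
                    m_y=UncertainQuantity(float(row["m_y_mg"]), float(row["u_m_y_mg"])),
                    m_z=UncertainQuantity(float(row["m_z_mg"]), float(row["u_m_z_mg"])),
                    r_obs=UncertainQuantity(
                        float(row["r_obs"]),
                        float(row["u_r_obs"]),
                        n_repeats=int(row["n_repeats"]),
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx + 1}: {exc}") from exc
    return AdditionSeries(blends, w_Z=w_z)


def _read_emd(path: Union[str, Path]) -> EMDBlendPair:
    df = _read_csv(path, EMD_COLUMNS)
    slots: dict[str, UncertainQuantity] = {}
    for idx, row in df.iterrows():
        key = (str(row["role"]), str(row["quantity"]))
        if key not in _EMD_SLOTS:
            raise BlendTableError(
                f"unknown role/quantity {key!r} in row {idx + 1}"
            )
        name = _EMD_SLOTS[key]
        if name in slots:
            raise BlendTableError(f"duplicate entry for {name} in row {idx + 1}")
        slots[name] = UncertainQuantity(
            float(row["value"]), float(row["u"]), n_repeats=int(row["n_repeats"])
        )
    missing = set(_EMD_SLOTS.values()) - set(slots)
    if missing:
        raise BlendTableError(f"missing quantities: {sorted(missing)}")
    return EMDBlendPair(**slots)


def write_blend_table(
    obj: Union[EMDBlendPair, AdditionSeries], path: Union[str, Path]
) -> None:
    """Serialize a blend pair or addition series to its CSV dialect.

    Values are written with full repr precision so a write/read round
    trip is bit-identical."""
    if isinstance(obj, AdditionSeries):
        rows = [
            {
                "blend_id": b.blend_id,
                "m_x_mg": b.m_x.value,
                "u_m_x_mg": b.m_x.u,
                "m_y_mg": b.m_y.value,
                "u_m_y_mg": b.m_y.u,
                "m_z_mg": b.m_z.value,
                "u_m_z_mg": b.m_z.u,
                "r_obs": b.r_obs.value,
                "u_r_obs": b.r_obs.u,
                "n_repeats": b.r_obs.n_repeats,
            }
            for b in obj.blends
        ]
        pd.DataFrame(rows, columns=MSA_COLUMNS).to_csv(path, index=False)
        return
    if isinstance(obj, EMDBlendPair):
        inv = {v: k for k, v in _EMD_SLOTS.items()}
        rows = []
        for name in ("m_X", "m_Y", "R_B", "m_Zc", "m_Yc", "R_Bc", "w_Zc"):
            role, quantity = inv[name]
            q: UncertainQuantity = getattr(obj, name)
            rows.append(
                {
                    "role": role,
                    "quantity": quantity,
                    "value": q.value,
                    "u": q.u,
                    "n_repeats": q.n_repeats,
                }
            )
        pd.DataFrame(rows, columns=EMD_COLUMNS).to_csv(path, index=False)
        return
    raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")


def budget_to_record(budget: UncertaintyBudget) -> dict:
    """JSON-ready budget report using the column names of published
    budget tables (Mean, u, c_i, (c_i*u_i)^2, Index)."""
    return {
        "output": budget.output_name,
        "value": budget.output_value,
        "u_c": budget.u_c,
        "k": budget.k,
        "U": budget.U,
        "rows": [
            {
                "Measurand": r.name,
                "Mean": r.value,
                "u": r.u,
                "c_i": r.c,
                "(c_i*u_i)^2": r.contribution,
                "Index": r.index,
            }
            for r in budget.rows
        ],
    }


def mcs_to_record(res: MCSResult) -> dict:
    d = asdict(res)
    d.pop("samples")
    d["percentiles"] = {str(k): v for k, v in res.percentiles.items()}
    return d


def write_report(record: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
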