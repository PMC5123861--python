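"""CSV/YAML readers and writers for all pipeline inputs and reports.

CSV dialect: comma-separated, dot decimal, UTF-8, header row required,
case-insensitive column matching. All readers validate their schema up
front and report the offending row/column in error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import LipidComposition
from .epr import SaturationCurve
from .errors import SchemaError
from .itc import InjectionHeats, TitrationProtocol
from .kinetics import KineticTrace, TraceMeta
from .partitioning import PartitionDataset, fraction_bound_from_depletion


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a CSV whose header must contain the schema's columns.

    ``schema`` maps column name -> dtype. Matching is case-insensitive;
    returned columns are renamed to the schema's canonical casing. Raises
    SchemaError naming the missing column or the first non-numeric cell.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for col in schema:
        if col.lower() not in lower:
            raise SchemaError(f"{path}: missing column {col!r} (found {list(df.columns)})")
        rename[lower[col.lower()]] = col
    df = df.rename(columns=rename)[list(schema)]
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = int(coerced.index[coerced.isna()][0])
                raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
            df[col] = coerced.astype(float)
    return df


# ---------------------------------------------------------------------------
# stage-specific readers

def read_trace(csv_path, meta_path=None) -> KineticTrace:
    """Stopped-flow trace CSV (`time_s, signal`) with optional YAML sidecar."""
    df = read_table(csv_path, {"time_s": float, "signal": float})
    meta = TraceMeta()
    if meta_path is not None:
        with open(meta_path) as fh:
            raw = yaml.safe_load(fh) or {}
        comp = raw.get("composition")
        meta = TraceMeta(
            protein_M=float(raw.get("protein_M", np.nan)),
            lipid_M=float(raw.get("lipid_M", np.nan)),
            composition=LipidComposition.from_dict(comp) if comp else None,
            temperature_K=float(raw.get("temp_K", 298.15)),
            ca_free_M=float(raw.get("ca_free_M", np.nan)),
        )
    return KineticTrace(t=df["time_s"].to_numpy(), F=df["signal"].to_numpy(), meta=meta)


def write_trace(trace: KineticTrace, csv_path) -> None:
    pd.DataFrame({"time_s": trace.t, "signal": trace.F}).to_csv(csv_path, index=False)


def read_itc(csv_path, protocol_path) -> InjectionHeats:
    """ITC CSV (`injection, volume_uL, heat_uJ`) plus protocol YAML.

    Heats are converted from microjoules to kJ internally.
    """
    df = read_table(csv_path, {"injection": int, "volume_uL": float, "heat_uJ": float})
    with open(protocol_path) as fh:
        raw = yaml.safe_load(fh)
    protocol = TitrationProtocol(
        cell_volume_L=float(raw["cell_volume_L"]),
        cell_conc_M=float(raw["cell_conc_M"]),
        syringe_conc_M=float(raw["syringe_conc_M"]),
        injection_volumes_L=tuple(df["volume_uL"].to_numpy() * 1e-6),
        temperature_K=float(raw.get("temperature_K", 298.15)),
    )
    q_kJ = df["heat_uJ"].to_numpy() * 1e-9
    from .itc import _concentration_schedule
    P_t, L_t, _ = _concentration_schedule(protocol)
    return InjectionHeats(q_kJ=q_kJ, molar_ratio=L_t / P_t, protocol=protocol)


def write_itc(heats: InjectionHeats, csv_path, protocol_path=None) -> None:
    vols = np.asarray(heats.protocol.injection_volumes_L) * 1e6
    pd.DataFrame({
        "injection": np.arange(1, len(vols) + 1),
        "volume_uL": vols,
        "heat_uJ": heats.q_kJ * 1e9,
    }).to_csv(csv_path, index=False)
    if protocol_path is not None:
        p = heats.protocol
        with open(protocol_path, "w") as fh:
            yaml.safe_dump({"cell_volume_L": p.cell_volume_L, "cell_conc_M": p.cell_conc_M,
                            "syringe_conc_M": p.syringe_conc_M,
                            "temperature_K": p.temperature_K}, fh)


def read_partition(csv_path, condition_path=None) -> PartitionDataset:
    """Sedimentation CSV: either (`lipid_total_M, f_b`) or raw supernatant columns."""
    head = pd.read_csv(csv_path, nrows=0)
    cols = {c.lower() for c in head.columns}
    condition = {}
    if condition_path is not None:
        with open(condition_path) as fh:
            condition = yaml.safe_load(fh) or {}
    if {"protein_sup_m", "protein_total_m"} <= cols:
        df = read_table(csv_path, {"lipid_total_M": float, "protein_sup_M": float,
                                   "protein_total_M": float})
        fb = fraction_bound_from_depletion(df["protein_sup_M"], df["protein_total_M"])
    else:
        df = read_table(csv_path, {"lipid_total_M": float, "f_b": float})
        fb = df["f_b"].to_numpy()
    return PartitionDataset(L=df["lipid_total_M"].to_numpy(), f_b=np.asarray(fb),
                            condition=condition)


def write_partition(data: PartitionDataset, csv_path) -> None:
    pd.DataFrame({"lipid_total_M": data.L, "f_b": data.f_b}).to_csv(csv_path, index=False)


def read_saturation(csv_path, condition: str = "N2") -> SaturationCurve:
    """Power-saturation CSV per condition: `power_mW, amplitude`."""
    df = read_table(csv_path, {"power_mW": float, "amplitude": float})
    return SaturationCurve(P_mW=df["power_mW"].to_numpy(),
                           A=df["amplitude"].to_numpy(), condition=condition)


def write_saturation(curve: SaturationCurve, csv_path) -> None:
    pd.DataFrame({"power_mW": curve.P_mW, "amplitude": curve.A}).to_csv(csv_path, index=False)


def read_peaks(csv_path) -> dict[int, tuple[float, float]]:
    """HSQC peak list CSV: `residue, dH_ppm, dN_ppm` (absolute positions)."""
    df = read_table(csv_path, {"residue": int, "dH_ppm": float, "dN_ppm": float})
    return {int(r): (float(h), float(n))
            for r, h, n in zip(df["residue"], df["dH_ppm"], df["dN_ppm"])}


def write_peaks(peaks: dict[int, tuple[float, float]], csv_path) -> None:
    rows = [(r, h, n) for r, (h, n) in sorted(peaks.items())]
    pd.DataFrame(rows, columns=["residue", "dH_ppm", "dN_ppm"]).to_csv(csv_path, index=False)


def read_restraints(csv_path):
    """Docking restraints CSV: `residue, target_A, range_A`."""
    from .docking import PlaneRestraint
    df = read_table(csv_path, {"residue": int, "target_A": float, "range_A": float})
    return [PlaneRestraint(site=int(r), target_x=float(t), range=float(w))
            for r, t, w in zip(df["residue"], df["target_A"], df["range_A"])]


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def write_report(report: dict, path) -> None:
    """Serialize a report dict (dataclasses, arrays allowed) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, default=str)
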