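"""Delimited-text and YAML persistence for curves, calibration tables,
count tables, fitted models, and design reports.

All tabular formats are plain CSV with mandatory headers (validated
strictly, so a malformed file fails with the offending column named).
Curve files carry the device's filtration area and label as ``# key: value``
comment lines above the header.  Fitted models persist as a small YAML
mapping so design runs are reproducible without refitting.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FiltrationModel
from .design import DesignSpec
from .estimation import CalibrationSet, FiltrationCurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_calibration",
    "write_calibration",
    "read_counts",
    "write_counts",
    "load_model",
    "save_model",
    "write_design_report",
]

CURVE_COLUMNS = ["time_s", "volume_uL"]
CALIBRATION_COLUMNS = ["area_mm2", "vq_uL"]
COUNT_COLUMNS = ["replicate", "sample_point", "cells", "volume_uL"]
DESIGN_COLUMNS = ["target_uL", "area_mm2", "predicted_uL", "rel_error", "feasible"]


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _read_header_meta(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def write_curve(curve: FiltrationCurve, path) -> None:
    """One curve per file: ``# area_mm2``/``# label`` header lines, then
    ``time_s,volume_uL`` rows."""
    path = Path(path)
    with open(path, "w") as fh:
        if curve.area is not None:
            fh.write(f"# area_mm2: {curve.area!r}\n")
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        pd.DataFrame({"time_s": curve.times, "volume_uL": curve.volumes}).to_csv(
            fh, index=False
        )


def read_curve(path) -> FiltrationCurve:
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    _check_columns(df, CURVE_COLUMNS, path)
    area = float(meta["area_mm2"]) if "area_mm2" in meta else None
    return FiltrationCurve(
        times=df["time_s"].to_numpy(float),
        volumes=df["volume_uL"].to_numpy(float),
        area=area,
        label=meta.get("label", ""),
    )


def write_calibration(cal: CalibrationSet, path) -> None:
    pd.DataFrame({"area_mm2": cal.areas, "vq_uL": cal.volumes}).to_csv(path, index=False)


def read_calibration(path) -> CalibrationSet:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, CALIBRATION_COLUMNS, path)
    return CalibrationSet(
        areas=df["area_mm2"].to_numpy(float), volumes=df["vq_uL"].to_numpy(float)
    )


def write_counts(table: pd.DataFrame, path) -> None:
    _check_columns(table, COUNT_COLUMNS, "<count table>")
    table[COUNT_COLUMNS].to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, COUNT_COLUMNS, path)
    return df


def save_model(model: FiltrationModel, path, **metadata) -> None:
    """Persist a fitted model as YAML; extra keyword metadata (fit RMS,
    data provenance, seeds) is stored under ``meta``."""
    doc = {
        "k": float(model.k),
        "Ve": float(model.Ve),
        "q_th": float(model.q_th),
        "units": {"k": "uL^2 mm^-4 min^-1", "Ve": "uL", "q_th": "1/min"},
    }
    if metadata:
        doc["meta"] = {k: _plain(v) for k, v in metadata.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def load_model(path) -> FiltrationModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("k", "Ve", "q_th"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key: {key}")
    return FiltrationModel(k=float(doc["k"]), Ve=float(doc["Ve"]), q_th=float(doc["q_th"]))


def write_design_report(specs: list[DesignSpec], path) -> pd.DataFrame:
    """Design table as CSV (columns target_uL, area_mm2, predicted_uL,
    rel_error, feasible); returns the DataFrame that was written."""
    df = pd.DataFrame(
        {
            "target_uL": [s.target_volume for s in specs],
            "area_mm2": [s.required_area for s in specs],
            "predicted_uL": [s.predicted_vq for s in specs],
            "rel_error": [s.relative_error for s in specs],
            "feasible": [s.feasible for s in specs],
        }
    )
    df.to_csv(path, index=False)
    return df
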