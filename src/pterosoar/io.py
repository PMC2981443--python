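"""Readers, writers, packaged fixtures and run configuration.

CSV dialect: comma-separated, UTF-8, header required, '.' decimal point.
Specimen tables may give cortical geometry either as inner radii
(a_in_mm, b_in_mm) or as a uniform cortical_thickness_mm; mass_kg may hold
several semicolon-separated candidates.  Errors name the offending row and
column.  Config files are YAML key-value maps; flags override config.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .bone_mechanics import (
    AvianScalingModel,
    BoneSection,
    MaterialParams,
    round_half_up,
)
from .flight_performance import BurstModel, GlidePolarParams, Planform
from .mass_scaling import SpanMassRegression

__all__ = [
    "load_table1",
    "load_table2",
    "load_avian_scaling",
    "read_specimen_csv",
    "read_planform_csv",
    "read_hull_csv",
    "load_config",
    "material_params_from_config",
    "glide_params_from_config",
    "burst_model_from_config",
    "regression_from_config",
    "write_report",
    "read_report",
    "table2_ratio_report",
]

logger = logging.getLogger("pterosoar")


def _data_file(name: str):
    return resources.files("pterosoar.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Packaged planform table: giant pterosaur and procellariiform wings."""
    with resources.as_file(_data_file("table1.csv")) as p:
        return pd.read_csv(p)


def load_table2() -> pd.DataFrame:
    """Packaged bone-strength table: azhdarchid RFFs and avian expectations."""
    with resources.as_file(_data_file("table2.csv")) as p:
        return pd.read_csv(p)


def load_avian_scaling() -> dict[str, AvianScalingModel]:
    """Per-element avian RFF scaling models (fixture calibration)."""
    with resources.as_file(_data_file("avian_scaling.csv")) as p:
        df = pd.read_csv(p)
    return {
        str(r["element"]): AvianScalingModel(
            intercept=float(r["intercept"]),
            exponent=float(r["exponent"]),
            source=str(r["source"]),
        )
        for _, r in df.iterrows()
    }


def _parse_masses(cell, row: int) -> tuple[float, ...]:
    try:
        masses = tuple(float(tok) for tok in str(cell).split(";") if tok.strip())
    except ValueError as exc:
        raise ValueError(f"row {row}, column mass_kg: non-numeric value {cell!r}") from exc
    if not masses:
        raise ValueError(f"row {row}, column mass_kg: empty")
    return masses


def read_specimen_csv(path) -> list[BoneSection]:
    """Read a bone cross-section morphometrics CSV into BoneSection records.

    Required columns: taxon, element, a_out_mm, b_out_mm, length_mm, mass_kg
    plus either (a_in_mm, b_in_mm) or cortical_thickness_mm.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    required = ["taxon", "element", "a_out_mm", "b_out_mm", "length_mm", "mass_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    has_inner = {"a_in_mm", "b_in_mm"}.issubset(df.columns)
    has_thickness = "cortical_thickness_mm" in df.columns
    if not (has_inner or has_thickness):
        raise ValueError(
            f"{path}: need either a_in_mm/b_in_mm or cortical_thickness_mm"
        )
    sections: list[BoneSection] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        numeric = {}
        cols = ["a_out_mm", "b_out_mm", "length_mm"]
        cols += ["a_in_mm", "b_in_mm"] if has_inner else ["cortical_thickness_mm"]
        for col in cols:
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {rownum}, column {col}: non-numeric value {row[col]!r}"
                ) from exc
        masses = _parse_masses(row["mass_kg"], rownum)
        wingspan = None
        if "wingspan_m" in df.columns and pd.notna(row["wingspan_m"]):
            wingspan = float(row["wingspan_m"])
        try:
            if has_inner:
                section = BoneSection(
                    taxon=str(row["taxon"]),
                    element=str(row["element"]),
                    a_out=numeric["a_out_mm"],
                    b_out=numeric["b_out_mm"],
                    a_in=numeric["a_in_mm"],
                    b_in=numeric["b_in_mm"],
                    length=numeric["length_mm"],
                    body_mass_candidates=masses,
                    wingspan=wingspan,
                )
            else:
                section = BoneSection.from_cortical_thickness(
                    taxon=str(row["taxon"]),
                    element=str(row["element"]),
                    a_out=numeric["a_out_mm"],
                    b_out=numeric["b_out_mm"],
                    cortical_thickness=numeric["cortical_thickness_mm"],
                    length=numeric["length_mm"],
                    body_mass_candidates=masses,
                    wingspan=wingspan,
                )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
        sections.append(section)
    if not sections:
        raise ValueError(f"{path}: no records")
    return sections


def read_planform_csv(path) -> list[Planform]:
    """Read a planform CSV (label, span_m, mass_kg, area_m2)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["span_m", "mass_kg", "area_m2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    planforms = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2
        try:
            planforms.append(
                Planform(
                    span=float(row["span_m"]),
                    area=float(row["area_m2"]),
                    mass=float(row["mass_kg"]),
                    label=str(row["label"]) if "label" in df.columns else str(idx),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    if not planforms:
        raise ValueError(f"{path}: no records")
    return planforms


def read_hull_csv(path) -> list[tuple[float, float]]:
    """Read a region hull as a CSV vertex list with columns x, y."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: hull CSV needs columns x, y")
    return [(float(r["x"]), float(r["y"])) for _, r in df.iterrows()]


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def _build(cls, cfg: dict, key: str):
    section = cfg.get(key, {}) or {}
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"config section {key}: unknown keys {sorted(unknown)}")
    return cls(**section)


def material_params_from_config(cfg: dict) -> MaterialParams:
    return _build(MaterialParams, cfg, "material")


def glide_params_from_config(cfg: dict) -> GlidePolarParams:
    return _build(GlidePolarParams, cfg, "glide")


def burst_model_from_config(cfg: dict) -> BurstModel:
    return _build(BurstModel, cfg, "burst")


def regression_from_config(cfg: dict) -> SpanMassRegression | None:
    section = cfg.get("span_mass_regression")
    if not section:
        return None
    return SpanMassRegression(
        coeff=float(section["coeff"]),
        exponent=float(section["exponent"]),
        source=str(section.get("source", "config")),
    )


def write_report(results, path, format: str = "csv", decimals: int = 2) -> None:
    """Write a report table as CSV or JSON.

    Column order is deterministic (input order); numeric columns get a
    printed-precision companion column (<name>_printed, half-up rounding)
    for comparison against published tables.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        records = list(results)
        if not records:
            raise ValueError("empty results")
        df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("empty results")
    for col in list(df.columns):
        if pd.api.types.is_float_dtype(df[col]):
            df[f"{col}_printed"] = df[col].map(
                lambda x: round_half_up(x, decimals) if pd.notna(x) else x
            )
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        payload = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r} (expected csv or json)")
    logger.info("wrote %d records to %s", len(df), path)


def read_report(path, format: str = "json") -> pd.DataFrame:
    """Read back a written report (round-trip partner of write_report)."""
    path = Path(path)
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    if format == "csv":
        return pd.read_csv(path)
    raise ValueError(f"unknown report format {format!r}")


def table2_ratio_report() -> pd.DataFrame:
    """Recompute the observed/expected ratio column from the packaged table.

    Ratios are rounded half-up to the 2 decimals of the printed table; rows
    without an avian expectation (the cervical) carry no ratio, and rows the
    printed table rounds inconsistently are flagged by ratio_consistent.
    """
    from .bone_mechanics import rff_ratio

    df = load_table2()
    ratios = []
    for _, row in df.iterrows():
        if pd.isna(row["avian_expectation"]):
            ratios.append(float("nan"))
        else:
            ratios.append(
                round_half_up(rff_ratio(row["rff"], row["avian_expectation"]), 2)
            )
    out = df.copy()
    out["ratio_computed"] = ratios
    return out
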