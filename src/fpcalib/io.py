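"""Readers and writers: plate-reader CSV exports, layouts, and calibration stores.

Wide instrument exports are unpivoted at the boundary using an explicit
:class:`Dialect` (no auto-sniffing): the dialect states the orientation, which
column identifies the well, and how the remaining columns map onto the tidy
schema.  The tidy long format of :mod:`fpcalib.model` is canonical everywhere
downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from .model import (
    STORE_SCHEMA_VERSION,
    TIDY_COLUMNS,
    CalibrationStore,
    PlateLayout,
    normalize_well,
    validate_tidy,
)

log = logging.getLogger(__name__)


class Dialect(BaseModel):
    """Declarative description of a plate-reader CSV export.

    orientation
        ``"long"``: the file already has tidy columns (at least ``well``,
        ``measure``, ``value``).  ``"wide"``: one row per well, one column per
        reading; column names are mapped through ``wide_value_columns``.
    wide_value_columns
        For wide files: map column name → dict of tidy fields for that column
        (e.g. ``{"A600": {"measure": "absorbance", "wavelength_nm": 600}}``).
    """

    orientation: str = "long"
    well_column: str = "well"
    wide_value_columns: dict[str, dict] = {}
    decimal: str = "."


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout CSV (columns: well, sample_id, calibrant_name,
    dilution_factor, buffer, volume_ul, replicate, role)."""
    df = pd.read_csv(path)
    if "well" not in df.columns:
        raise ValueError(f"layout {path}: no 'well' column")
    wells = {}
    for _, row in df.iterrows():
        meta = row.drop("well").to_dict()
        wells[normalize_well(row["well"])] = meta
    return PlateLayout(wells=wells)


def read_plate_data(
    path: str | Path, layout: PlateLayout, dialect: Dialect | None = None
) -> pd.DataFrame:
    """Read a plate-reader CSV and join layout metadata, returning a validated
    tidy table.

    Every measurement row must find its well in the layout; missing wells are
    reported together in one error rather than dropped.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, decimal=dialect.decimal)
    if raw.empty:
        raise ValueError(f"{path}: empty file")

    if dialect.orientation == "wide":
        records = []
        for _, row in raw.iterrows():
            well = row[dialect.well_column]
            for col, fields in dialect.wide_value_columns.items():
                rec = {"well": well, "value": row[col]}
                rec.update(fields)
                records.append(rec)
        tidy = pd.DataFrame(records)
    else:
        tidy = raw.rename(columns={dialect.well_column: "well"})

    bad = pd.to_numeric(tidy["value"], errors="coerce").isna() & tidy["value"].notna()
    if bad.any():
        culprits = tidy.loc[bad, ["well"]].assign(value=tidy.loc[bad, "value"])
        raise ValueError(
            f"{path}: non-numeric cells: "
            + "; ".join(f"well {r.well} value {r.value!r}" for r in culprits.itertuples())
        )
    tidy["value"] = pd.to_numeric(tidy["value"])
    tidy["well"] = tidy["well"].map(normalize_well)

    layout_df = layout.as_frame()
    missing = sorted(set(tidy["well"]) - set(layout_df["well"]))
    if missing:
        raise ValueError(f"{path}: wells missing from layout: {missing}")
    meta_cols = [c for c in layout_df.columns if c != "well" and c not in tidy.columns]
    tidy = tidy.merge(layout_df[["well"] + meta_cols], on="well", how="left")
    for col in TIDY_COLUMNS:
        if col not in tidy.columns:
            tidy[col] = pd.NA
    out = validate_tidy(tidy)
    log.info("read %s: %d measurement rows across %d wells", path, len(out), out["well"].nunique())
    return out


def write_tidy(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy table as the canonical long CSV."""
    validate_tidy(df).to_csv(path, index=False)


def read_tidy(path: str | Path) -> pd.DataFrame:
    """Read a canonical long CSV back into a validated tidy table."""
    return validate_tidy(pd.read_csv(path))


def write_calibration(store: CalibrationStore, path: str | Path) -> None:
    """Persist a calibration store as JSON (full numeric precision)."""
    Path(path).write_text(store.model_dump_json(indent=2))


def read_calibration(path: str | Path) -> CalibrationStore:
    """Load and validate a calibration store JSON file."""
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != STORE_SCHEMA_VERSION:
        raise ValueError(
            f"calibration store schema version {version} != supported {STORE_SCHEMA_VERSION}"
        )
    return CalibrationStore.model_validate(data)


def spectra_from_tidy(df: pd.DataFrame):
    """Group tidy absorbance rows into per-well AbsorbanceSpectrum objects."""
    from .spectra import AbsorbanceSpectrum

    out = {}
    ab = df[df["measure"] == "absorbance"]
    for well, grp in ab.groupby("well"):
        grp = grp.sort_values("wavelength_nm")
        vol = grp["volume_ul"].dropna()
        buf = grp["buffer"].dropna()
        out[well] = AbsorbanceSpectrum(
            well=well,
            wavelengths_nm=grp["wavelength_nm"].to_numpy(dtype=float),
            absorbance=grp["value"].to_numpy(dtype=float),
            volume_ul=float(vol.iloc[0]) if len(vol) else 225.0,
            buffer=str(buf.iloc[0]) if len(buf) else "",
        )
    return out
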