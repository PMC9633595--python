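"""Core data model: the tidy measurement table, plate layouts, and calibration records.

The package exchanges plate-reader data as a *tidy* long table (one row per
well/time/channel/gain/wavelength reading) carried in a :class:`pandas.DataFrame`
with a fixed column set (:data:`TIDY_COLUMNS`).  Calibration results are pydantic
records collected in a versioned :class:`CalibrationStore` that serializes to JSON.

Units are fixed package-wide: time in minutes, wavelengths in nm, volumes in µl,
path lengths in cm, concentrations in ng/µl or molar as named.
"""

from __future__ import annotations

import datetime
import enum
import re
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

#: Columns of the canonical tidy measurement table.
TIDY_COLUMNS = [
    "well",
    "time",
    "measure",
    "wavelength_nm",
    "gain",
    "value",
    "sample_id",
    "calibrant_name",
    "dilution_factor",
    "buffer",
    "volume_ul",
    "replicate",
    "role",
]

#: Columns forming the unique key of a tidy row.
TIDY_KEY = ["well", "measure", "wavelength_nm", "gain", "time"]

WELL_RE = re.compile(r"^[A-P](?:[1-9]|1[0-9]|2[0-4])$")


class Measure(str, enum.Enum):
    absorbance = "absorbance"
    fluorescence = "fluorescence"
    od600 = "od600"
    od700 = "od700"


class Role(str, enum.Enum):
    calibrant = "calibrant"
    standard = "standard"
    blank = "blank"
    control_cells = "control_cells"
    sample = "sample"


def normalize_well(well: str) -> str:
    """Normalize a well coordinate to letter+number, e.g. ``"a01"`` → ``"A1"``.

    Raises ``ValueError`` for anything that is not a row letter followed by a
    1-based column number.
    """
    w = str(well).strip().upper()
    m = re.match(r"^([A-P])0*([1-9][0-9]?)$", w)
    if m is None:
        raise ValueError(f"invalid well coordinate: {well!r}")
    return f"{m.group(1)}{m.group(2)}"


class PlateLayout(BaseModel):
    """Mapping from well coordinate to sample metadata.

    ``wells`` maps a normalized well name to a dict with keys ``sample_id``,
    ``calibrant_name``, ``dilution_factor`` (≥ 1), ``buffer``, ``volume_ul``
    (> 0), ``replicate`` and ``role``.
    """

    wells: dict[str, dict]

    @model_validator(mode="after")
    def _check_wells(self) -> "PlateLayout":
        seen = set()
        for well, meta in self.wells.items():
            norm = normalize_well(well)
            if norm in seen:
                raise ValueError(f"well {norm} assigned twice in layout")
            seen.add(norm)
            df = meta.get("dilution_factor")
            if df is not None and not (float(df) >= 1):
                raise ValueError(f"well {norm}: dilution_factor must be >= 1, got {df}")
            vol = meta.get("volume_ul")
            if vol is not None and not (float(vol) > 0):
                raise ValueError(f"well {norm}: volume_ul must be > 0, got {vol}")
            role = meta.get("role")
            if role is not None:
                Role(role)
        return self

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for well, meta in self.wells.items():
            row = {"well": normalize_well(well)}
            row.update(meta)
            rows.append(row)
        return pd.DataFrame(rows)


def validate_tidy(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy measurement table; returns the table with ordered columns.

    Checks the column set, the enum columns, per-row invariants
    (``dilution_factor >= 1``, ``volume_ul > 0``) and key uniqueness.
    """
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy table missing columns: {missing}")
    for col, enum_cls in [("measure", Measure), ("role", Role)]:
        bad = set(df[col].dropna().unique()) - {e.value for e in enum_cls}
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    df = df.copy()
    df["well"] = df["well"].map(normalize_well)
    if not np.isfinite(pd.to_numeric(df["value"], errors="coerce")).all():
        bad_rows = df[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
        raise ValueError(
            "non-numeric measurement values in wells "
            f"{sorted(bad_rows['well'].unique())}"
        )
    dil = pd.to_numeric(df["dilution_factor"], errors="coerce")
    if (dil.dropna() < 1).any():
        raise ValueError("dilution_factor < 1 in tidy table")
    vol = pd.to_numeric(df["volume_ul"], errors="coerce")
    if (vol.dropna() <= 0).any():
        raise ValueError("volume_ul <= 0 in tidy table")
    dup = df.duplicated(subset=TIDY_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, TIDY_KEY].drop_duplicates().to_dict("records")
        raise ValueError(f"duplicate measurement keys: {keys[:5]}")
    return df[TIDY_COLUMNS]


class FilterSet(BaseModel):
    """A fluorescence filter pair, e.g. excitation 560/20 with emission 620/20."""

    ex_center_nm: float
    ex_bandwidth_nm: float = Field(gt=0)
    em_center_nm: float
    em_bandwidth_nm: float = Field(gt=0)
    label: str = ""

    @model_validator(mode="after")
    def _no_full_overlap(self) -> "FilterSet":
        ex_lo = self.ex_center_nm - self.ex_bandwidth_nm / 2
        ex_hi = self.ex_center_nm + self.ex_bandwidth_nm / 2
        em_lo = self.em_center_nm - self.em_bandwidth_nm / 2
        em_hi = self.em_center_nm + self.em_bandwidth_nm / 2
        if ex_lo <= em_lo and em_hi <= ex_hi:
            raise ValueError("emission band fully inside excitation band")
        if not self.label:
            self.label = (
                f"{self.ex_center_nm:g}/{self.ex_bandwidth_nm:g}, "
                f"{self.em_center_nm:g}/{self.em_bandwidth_nm:g}"
            )
        return self


class ConversionFactor(BaseModel):
    """RFU emitted per molecule of a named FP on one instrument/filter/gain."""

    fp_name: str
    instrument: str = "sim"
    filterset: Optional[FilterSet] = None
    gain: int = 0
    cf_rfu_per_molecule: float = Field(gt=0)
    n_points: int = 0
    r_squared: float = Field(default=1.0, ge=0.0, le=1.0)
    normalized: bool = False
    reference_fp: Optional[str] = None
    date: Optional[str] = None


class ODCalibration(BaseModel):
    """Particles (microspheres) per unit blanked OD/cm for one OD wavelength."""

    od_wavelength: int
    particles_per_od_cm: float = Field(gt=0)
    diameter_um: float = Field(default=0.890, gt=0)
    density_g_cc: float = Field(default=2.0, gt=0)
    r_squared: float = Field(default=1.0, ge=0.0, le=1.0)
    instrument: str = "sim"
    date: Optional[str] = None


STORE_SCHEMA_VERSION = 1


class CalibrationStore(BaseModel):
    """Versioned, uniquely keyed collection of calibration records."""

    schema_version: int = STORE_SCHEMA_VERSION
    conversion_factors: list[ConversionFactor] = Field(default_factory=list)
    od_calibrations: list[ODCalibration] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_keys(self) -> "CalibrationStore":
        cf_keys = [
            (c.instrument, c.fp_name, c.filterset.label if c.filterset else None, c.gain)
            for c in self.conversion_factors
        ]
        if len(cf_keys) != len(set(cf_keys)):
            raise ValueError("duplicate conversion-factor keys in store")
        od_keys = [(o.instrument, o.od_wavelength) for o in self.od_calibrations]
        if len(od_keys) != len(set(od_keys)):
            raise ValueError("duplicate OD-calibration keys in store")
        return self

    def add(self, record: ConversionFactor | ODCalibration) -> None:
        if record.date is None:
            record = record.model_copy(
                update={"date": datetime.date.today().isoformat()}
            )
        if isinstance(record, ConversionFactor):
            self.conversion_factors.append(record)
        else:
            self.od_calibrations.append(record)
        self._unique_keys()

    def get_cf(self, fp_name: str, gain: int, instrument: str = "sim") -> ConversionFactor:
        for c in self.conversion_factors:
            if (c.fp_name, c.gain, c.instrument) == (fp_name, gain, instrument):
                return c
        raise KeyError(f"no conversion factor for ({fp_name}, gain {gain}, {instrument})")

    def get_od(self, od_wavelength: int, instrument: str = "sim") -> ODCalibration:
        for o in self.od_calibrations:
            if (o.od_wavelength, o.instrument) == (od_wavelength, instrument):
                return o
        raise KeyError(f"no OD calibration for ({od_wavelength}, {instrument})")
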