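"""Fluorescent-protein photophysical properties: FPbase API client and offline fixtures.

The ECmax concentration assay and brightness normalization both need per-FP
photophysics: the molar extinction coefficient at the peak excitation
wavelength (ECmax), the quantum yield, the molecular weight, and normalized
excitation/emission spectra.  These live on FPbase (https://www.fpbase.org/),
a community database keyed by slug, whose REST API this module can query and
cache.  Because tests and batch pipelines must run offline, the package also
ships fixture records for mTagBFP2, mGFPmut3 (slug ``gfpmut3``), mCherry and
fluorescein.  The fixture constants are representative literature values; the
fixture *spectra* are synthetic Gaussian stand-ins built from stored
peak/width parameters (the file is named accordingly), adequate for band-sum
arithmetic but not for spectral fine structure.

Spectra are resampled onto a 1 nm integer grid on load and normalized so the
maximum equals 1, which makes band sums well-defined and reproducible.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

FIXTURE_FILE = "fp_fixtures_synthetic.json"

# Pace/Edelhoch molar absorptivities at 280 nm (M^-1 cm^-1).
EC280_TRP = 5500
EC280_TYR = 1490
EC280_CYSTINE = 125

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class FPProperties(BaseModel):
    """Photophysical record for one fluorophore.

    ``ex_spectrum`` / ``em_spectrum`` are (n, 2) arrays of (wavelength nm,
    normalized value) on a 1 nm grid with maximum exactly 1.
    """

    model_config = {"arbitrary_types_allowed": True}

    name: str
    slug: str
    sequence: Optional[str] = None
    ec280_M_cm: Optional[float] = None
    ecmax_M_cm: float = Field(gt=0)
    lambda_max_nm: float = Field(gt=0)
    qy: float = Field(gt=0, le=1)
    mw_g_mol: float = Field(gt=0)
    ex_spectrum: np.ndarray
    em_spectrum: np.ndarray

    @model_validator(mode="before")
    @classmethod
    def _coerce_spectra(cls, data):
        for key in ("ex_spectrum", "em_spectrum"):
            data[key] = np.asarray(data[key], dtype=float)
        return data

    @model_validator(mode="after")
    def _check(self) -> "FPProperties":
        for key, spec in [("ex_spectrum", self.ex_spectrum), ("em_spectrum", self.em_spectrum)]:
            if spec.ndim != 2 or spec.shape[1] != 2:
                raise ValueError(f"{key} must be an (n, 2) array")
            if abs(spec[:, 1].max() - 1.0) > 1e-6:
                raise ValueError(f"{key} maximum must be 1 (got {spec[:, 1].max()})")
        lo, hi = self.ex_spectrum[0, 0], self.ex_spectrum[-1, 0]
        if not (lo <= self.lambda_max_nm <= hi):
            raise ValueError(
                f"lambda_max {self.lambda_max_nm} outside excitation support [{lo}, {hi}]"
            )
        return self


def _resample_1nm(spectrum: np.ndarray) -> np.ndarray:
    """Linear-interpolate a spectrum onto an integer-nm grid and renormalize."""
    spectrum = np.asarray(spectrum, dtype=float)
    lam = spectrum[:, 0]
    grid = np.arange(np.ceil(lam.min()), np.floor(lam.max()) + 1)
    vals = np.interp(grid, lam, spectrum[:, 1])
    vals = vals / vals.max()
    return np.column_stack([grid, vals])


def _gaussian_spectrum(center: float, sigma: float, halfspan: float = 120.0) -> np.ndarray:
    grid = np.arange(max(200.0, np.floor(center - halfspan)), np.floor(center + halfspan) + 1)
    vals = np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    vals = vals / vals.max()
    return np.column_stack([grid, vals])


def _load_fixture_records() -> dict:
    text = resources.files("fpcalib.data").joinpath(FIXTURE_FILE).read_text()
    records = json.loads(text)
    records.pop("_comment", None)
    return records


def list_fixture_keys() -> list[str]:
    return sorted(_load_fixture_records())


def _fixture_properties(key: str) -> FPProperties:
    records = _load_fixture_records()
    if key not in records:
        near = ", ".join(sorted(records))
        raise KeyError(f"unknown fluorophore {key!r}; packaged fixtures: {near}")
    rec = records[key]
    ex = _gaussian_spectrum(rec["lambda_max_nm"], rec["ex_sigma_nm"])
    em = _gaussian_spectrum(rec["em_max_nm"], rec["em_sigma_nm"])
    return FPProperties(
        name=rec["name"],
        slug=rec["slug"],
        ec280_M_cm=rec.get("ec280_M_cm"),
        ecmax_M_cm=rec["ecmax_M_cm"],
        lambda_max_nm=rec["lambda_max_nm"],
        qy=rec["qy"],
        mw_g_mol=rec["mw_g_mol"],
        ex_spectrum=ex,
        em_spectrum=em,
    )


def _api_properties(name: str, cache_dir: str | Path | None) -> FPProperties:
    """Fetch a protein record and spectra from the FPbase REST API.

    Responses are cached as JSON under ``cache_dir``; a warm cache is served
    without any network access.
    """
    import urllib.request

    cache_dir = Path(cache_dir or Path.home() / ".cache" / "fpcalib")
    cache_dir.mkdir(parents=True, exist_ok=True)
    slug = name.strip().lower()
    cache_file = cache_dir / f"{slug}.json"
    if cache_file.exists():
        payload = json.loads(cache_file.read_text())
    else:
        url = f"https://www.fpbase.org/api/proteins/?slug={slug}&format=json"
        with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
            hits = json.loads(resp.read().decode())
        if not hits:
            raise KeyError(f"FPbase has no entry with slug {slug!r}")
        payload = hits[0]
        spec_url = f"https://www.fpbase.org/spectra/{slug}/?format=json"
        try:  # pragma: no cover
            with urllib.request.urlopen(spec_url, timeout=30) as resp:
                payload["_spectra"] = json.loads(resp.read().decode())
        except Exception:
            payload["_spectra"] = None
        cache_file.write_text(json.dumps(payload))

    state = payload["states"][0]
    for fld in ("ext_coeff", "qy"):
        if state.get(fld) in (None, ""):
            raise ValueError(f"FPbase record {slug!r} missing required field {fld}")
    spectra = payload.get("_spectra") or {}
    ex = spectra.get("ex") or spectra.get("excitation")
    em = spectra.get("em") or spectra.get("emission")
    if ex is None or em is None:
        # fall back to Gaussian stand-ins around the documented maxima
        ex = _gaussian_spectrum(state["ex_max"], 20)
        em = _gaussian_spectrum(state["em_max"], 18)
    return FPProperties(
        name=payload["name"],
        slug=slug,
        sequence=payload.get("seq"),
        ec280_M_cm=None,
        ecmax_M_cm=state["ext_coeff"],
        lambda_max_nm=state["ex_max"],
        qy=state["qy"],
        mw_g_mol=(payload.get("mw") or 27.0) * 1000 if payload.get("mw") else 27000,
        ex_spectrum=_resample_1nm(np.asarray(ex, dtype=float)),
        em_spectrum=_resample_1nm(np.asarray(em, dtype=float)),
    )


def get_fp_properties(
    name: str, source: str = "fixture", cache_dir: str | Path | None = None
) -> FPProperties:
    """Resolve a fluorophore name to a validated :class:`FPProperties` record.

    ``source="fixture"`` (default) uses the packaged offline records and never
    touches the network; ``source="api"`` queries FPbase with disk caching.
    """
    key = name.strip().lower()
    if source == "fixture":
        return _fixture_properties(key)
    if source == "api":
        return _api_properties(key, cache_dir)
    raise ValueError(f"unknown source {source!r}; use 'fixture' or 'api'")


def ec280_from_sequence(sequence: str, n_cystine: int = 0) -> float:
    """Predict the 280 nm molar extinction coefficient of a pure protein.

    EC280 = 5500·n(Trp) + 1490·n(Tyr) + 125·n(cystine pairs).  Cysteines are
    assumed reduced by default (``n_cystine=0``).
    """
    seq = sequence.upper()
    bad = [i for i, ch in enumerate(seq) if ch not in AMINO_ACIDS]
    if bad:
        raise ValueError(f"invalid amino-acid letters at positions {bad[:10]}")
    if n_cystine < 0 or 2 * n_cystine > seq.count("C"):
        raise ValueError("n_cystine inconsistent with cysteine count")
    return EC280_TRP * seq.count("W") + EC280_TYR * seq.count("Y") + EC280_CYSTINE * n_cystine
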