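"""Synthetic plate-reader data with declared ground truth.

Every assay the pipeline consumes can be generated here from explicit truth
parameters, so the full calibration workflow is testable offline:

* :func:`sim_absorbance_plate` — dilution-series absorbance spectra
  (200–1000 nm): a Gaussian chromophore band obeying Beer's law with ECmax,
  an aromatic 280 nm band from EC280, power-law light scatter, a near-IR
  water band that encodes the per-well path length, and additive noise;
* :func:`sim_fluorescence_plate` — the matching fluorescence reads across
  gains with a known RFU-per-molecule conversion factor, multiplicative
  noise and a detector ceiling;
* :func:`sim_mixing_assay` — purified FP mixed with non-fluorescent cells at
  a range of ODs, quenched by a known exponential retained fraction;
* :func:`sim_growth_experiment` — logistic growth with FP expression, paired
  OD600/OD700 channels linked by a known linear relation, OD-dependent
  quenching and cellular autofluorescence.

Each simulator returns a tidy table (and/or plain arrays matching the
consuming fitter) plus a truth table sufficient to score every downstream
estimator.  All randomness flows from ``SimConfig.seed``; the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .fpbase import FPProperties, get_fp_properties
from .model import TIDY_COLUMNS
from .spectra import AbsorbanceSpectrum, K_WATER_PER_CM

AVOGADRO = 6.02214076e23


@dataclass
class SimConfig:
    """Ground-truth parameters for all simulators (units as named)."""

    seed: int = 0
    fp_name: str = "mcherry"

    # dilution series / plate geometry
    stock_conc_ng_ul: float = 500.0
    n_dilutions: int = 11
    dilution_step: float = 2.0
    volume_ul: float = 225.0
    #: straight-walled well: optical path proportional to fill volume
    path_cm_per_ul: float = 0.58 / 225.0
    buffer: str = "T5N15"

    # absorbance spectrum model
    wavelength_step_nm: float = 1.0
    chromophore_sigma_nm: float = 15.0
    aromatic_sigma_nm: float = 10.0
    scatter_a600: float = 0.01          # scatter absorbance at 600 nm
    scatter_exponent: float = -4.0
    k_water_per_cm: float = K_WATER_PER_CM
    od_noise_sd: float = 0.002          # additive absorbance noise
    background_280_factor: float = 0.0  # non-FP protein, as a multiple of the FP's A280

    # fluorescence model
    gains: tuple[int, ...] = (40, 60, 80, 100, 120)
    #: cf(gain) = base * 10^(slope*gain); defaults keep an 11-step two-fold
    #: calibrant series within the detector ceiling at low-mid gains
    base_cf_rfu_per_molecule: float = 2e-13
    cf_log10_per_gain: float = 0.025    # log10(cf) slope vs gain
    rfu_cv: float = 0.02                # multiplicative fluorescence noise
    detector_ceiling: float = 2.5e5
    blank_rfu: float = 30.0

    # quenching / autofluorescence
    quench_k_per_od: float = 0.178
    autofluor_rfu_per_od: float = 50.0
    fluor_blank_rfu: float = 10.0

    # growth experiment
    n_replicates: int = 3
    n_timepoints: int = 40
    dt_min: float = 30.0
    logistic_k_od: float = 1.93         # carrying capacity, OD600/cm
    logistic_r_per_min: float = 0.009
    initial_od: float = 0.006
    lag_min: float = 0.0
    media_blank_od: float = 0.04
    growth_pathlength_cm: float = 1.0
    pems_per_od: float = 1.6e8          # particles per OD600/cm per well
    expression_molecules_per_cell: float | Callable[[np.ndarray], np.ndarray] = 10000.0
    od600_od700_slope: float = 1.30
    od600_od700_intercept: float = -0.02
    growth_od_noise_sd: float = 0.002
    growth_gain: int = 120              # expression wells hold ~1000x fewer molecules
                                        # than calibrant wells, so read at high gain

    def fp(self) -> FPProperties:
        return get_fp_properties(self.fp_name, source="fixture")

    def true_cf(self, gain: int) -> float:
        return self.base_cf_rfu_per_molecule * 10 ** (self.cf_log10_per_gain * gain)

    def dilution_factors(self) -> np.ndarray:
        return self.dilution_step ** np.arange(self.n_dilutions)

    def path_cm(self) -> float:
        return self.volume_ul * self.path_cm_per_ul


def _tidy_rows(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    for col in TIDY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[TIDY_COLUMNS]


def _water_band(lam: np.ndarray, k_per_cm: float, path_cm: float) -> np.ndarray:
    """Smooth step from 0 (≤905 nm) to k·path (≥945 nm) emulating the water band."""
    ramp = np.clip((lam - 905.0) / 40.0, 0.0, 1.0)
    return k_per_cm * path_cm * ramp


def sim_absorbance_plate(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, AbsorbanceSpectrum], AbsorbanceSpectrum]:
    """Simulate a dilution-series absorbance scan plate.

    Returns ``(tidy, truth, spectra, blank)`` where ``truth`` has one row per
    sample well (conc_ng_ul, conc_M, path_cm, molecules) and ``spectra`` maps
    well → raw (un-blanked) :class:`AbsorbanceSpectrum`.
    """
    rng = np.random.default_rng(cfg.seed)
    fp = cfg.fp()
    lam = np.arange(200.0, 1000.0 + 1e-9, cfg.wavelength_step_nm)
    path = cfg.path_cm()
    dfs = cfg.dilution_factors()

    scatter_a = cfg.scatter_a600 * 600.0 ** (-cfg.scatter_exponent)
    water = _water_band(lam, cfg.k_water_per_cm, path)

    spectra: dict[str, AbsorbanceSpectrum] = {}
    tidy_records: list[dict] = []
    truth_rows: list[dict] = []
    ec280 = fp.ec280_M_cm or 0.0

    for i, dil in enumerate(dfs):
        well = f"A{i + 1}"
        conc_ng_ul = cfg.stock_conc_ng_ul / dil
        conc_M = conc_ng_ul / (fp.mw_g_mol * 1e3)  # ng/ul = ug/ml = mg/L
        chromo = (
            fp.ecmax_M_cm * conc_M * path
            * np.exp(-((lam - fp.lambda_max_nm) ** 2) / (2 * cfg.chromophore_sigma_nm**2))
        )
        aromatic_peak = ec280 * conc_M * path * (1.0 + cfg.background_280_factor)
        aromatic = aromatic_peak * np.exp(-((lam - 280.0) ** 2) / (2 * cfg.aromatic_sigma_nm**2))
        scatter = scatter_a * lam**cfg.scatter_exponent
        noise = rng.normal(0.0, cfg.od_noise_sd, lam.shape) if cfg.od_noise_sd > 0 else 0.0
        a = chromo + aromatic + scatter + water + noise
        spectra[well] = AbsorbanceSpectrum(well, lam.copy(), a, cfg.volume_ul, cfg.buffer)
        truth_rows.append(
            {
                "well": well,
                "dilution_factor": float(dil),
                "conc_ng_ul": conc_ng_ul,
                "conc_M": conc_M,
                "path_cm": path,
                "molecules": conc_ng_ul * cfg.volume_ul * 1e-9 / fp.mw_g_mol * AVOGADRO,
            }
        )
        for l, v in zip(lam, a):
            tidy_records.append(
                {
                    "well": well, "measure": "absorbance", "wavelength_nm": l,
                    "value": v, "sample_id": fp.slug, "calibrant_name": fp.name,
                    "dilution_factor": float(dil), "buffer": cfg.buffer,
                    "volume_ul": cfg.volume_ul, "replicate": 1, "role": "calibrant",
                }
            )

    blank_noise = rng.normal(0.0, cfg.od_noise_sd, lam.shape) if cfg.od_noise_sd > 0 else 0.0
    blank = AbsorbanceSpectrum("B1", lam.copy(), water + blank_noise, cfg.volume_ul, cfg.buffer)
    for l, v in zip(lam, blank.absorbance):
        tidy_records.append(
            {
                "well": "B1", "measure": "absorbance", "wavelength_nm": l, "value": v,
                "sample_id": "blank", "buffer": cfg.buffer, "volume_ul": cfg.volume_ul,
                "replicate": 1, "role": "blank", "dilution_factor": 1.0,
            }
        )
    return _tidy_rows(tidy_records), pd.DataFrame(truth_rows), spectra, blank


def sim_fluorescence_plate(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[int, list[tuple[float, float]]], pd.DataFrame]:
    """Simulate gain-series fluorescence reads of the same dilution series.

    RFU(gain) = true_cf(gain)·molecules·(1 + ε) + blank, clipped at the
    detector ceiling.  Returns ``(tidy, fluor_by_gain, truth)`` with
    ``fluor_by_gain`` shaped for :func:`fpcalib.calibration.generate_cfs`.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    fp = cfg.fp()
    dfs = cfg.dilution_factors()
    molecules = (
        cfg.stock_conc_ng_ul / dfs * cfg.volume_ul * 1e-9 / fp.mw_g_mol * AVOGADRO
    )
    tidy_records: list[dict] = []
    fluor_by_gain: dict[int, list[tuple[float, float]]] = {}
    truth_rows = [
        {"dilution_factor": float(d), "molecules": float(m), }
        for d, m in zip(dfs, molecules)
    ]
    for gain in cfg.gains:
        cf = cfg.true_cf(gain)
        series = []
        for i, (dil, mol) in enumerate(zip(dfs, molecules)):
            eps = rng.normal(0.0, cfg.rfu_cv) if cfg.rfu_cv > 0 else 0.0
            rfu = min(cf * mol * (1.0 + eps) + cfg.blank_rfu, cfg.detector_ceiling)
            series.append((float(dil), float(rfu)))
            tidy_records.append(
                {
                    "well": f"A{i + 1}", "measure": "fluorescence", "gain": gain,
                    "value": rfu, "sample_id": fp.slug, "calibrant_name": fp.name,
                    "dilution_factor": float(dil), "buffer": cfg.buffer,
                    "volume_ul": cfg.volume_ul, "replicate": 1, "role": "calibrant",
                }
            )
        fluor_by_gain[gain] = series
        tidy_records.append(
            {
                "well": "B1", "measure": "fluorescence", "gain": gain,
                "value": cfg.blank_rfu, "sample_id": "blank", "buffer": cfg.buffer,
                "volume_ul": cfg.volume_ul, "replicate": 1, "role": "blank",
                "dilution_factor": 1.0,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth_cfs = pd.DataFrame(
        [{"gain": g, "true_cf": cfg.true_cf(g)} for g in cfg.gains]
    )
    truth = truth.assign(key=1).merge(truth_cfs.assign(key=1), on="key").drop(columns="key")
    return _tidy_rows(tidy_records), fluor_by_gain, truth


def sim_mixing_assay(
    cfg: SimConfig,
    od_levels: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    rfu_without: float = 1e4,
    n_replicates: int = 2,
) -> list[tuple[float, float, float]]:
    """Simulate the FP + non-fluorescent-cells mixing assay.

    Rows are (od_per_cm, RFU with cells, RFU without cells), with cellular
    autofluorescence already subtracted (as the quench fitter requires):
    RFU_with = RFU_without · exp(−k·od) · (1 + ε).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for od in od_levels:
        for _ in range(n_replicates):
            eps = rng.normal(0.0, cfg.rfu_cv) if cfg.rfu_cv > 0 else 0.0
            with_cells = rfu_without * np.exp(-cfg.quench_k_per_od * od) * (1.0 + eps)
            rows.append((float(od), float(with_cells), float(rfu_without)))
    return rows


def _logistic_od(cfg: SimConfig, t_min: np.ndarray) -> np.ndarray:
    t = np.clip(t_min - cfg.lag_min, 0.0, None)
    k, n0, r = cfg.logistic_k_od, cfg.initial_od, cfg.logistic_r_per_min
    return k / (1.0 + (k - n0) / n0 * np.exp(-r * t))


def sim_growth_experiment(
    cfg: SimConfig, induced: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a growth + expression timecourse plate.

    Wells: ``A1..`` expressing samples, ``B1..`` no-FP control cells,
    ``C1`` media blank.  Measures per timepoint: od600, od700 (linked by the
    configured linear relation), fluorescence (configured gain).

    Returns ``(tidy, truth, meta)``: ``truth`` has one row per sample
    (well, time) with the generating OD/cm, cells, molecules per cell and per
    well; ``meta`` holds the scalar truths (cf, quench k, OD relation, PEMS).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    t = np.arange(cfg.n_timepoints) * cfg.dt_min
    od600_true = _logistic_od(cfg, t)  # per cm
    m, c = cfg.od600_od700_slope, cfg.od600_od700_intercept
    od700_true = (od600_true - c) / m
    cf = cfg.true_cf(cfg.growth_gain)

    if callable(cfg.expression_molecules_per_cell):
        mpc = np.asarray(cfg.expression_molecules_per_cell(t), dtype=float)
    else:
        mpc = np.full_like(t, float(cfg.expression_molecules_per_cell))
    if not induced:
        mpc = np.zeros_like(mpc)

    path = cfg.growth_pathlength_cm
    sd = cfg.growth_od_noise_sd
    records: list[dict] = []
    truth_rows: list[dict] = []

    def emit(well: str, role: str, measure: str, values: np.ndarray, gain=None) -> None:
        for ti, v in zip(t, values):
            records.append(
                {
                    "well": well, "time": float(ti), "measure": measure,
                    "gain": gain, "value": float(v), "sample_id": role,
                    "role": role, "volume_ul": 200.0, "dilution_factor": 1.0,
                    "replicate": int(well[1:]),
                }
            )

    def noisy(x: np.ndarray) -> np.ndarray:
        return x + rng.normal(0.0, sd, x.shape) if sd > 0 else x

    for rep in range(1, cfg.n_replicates + 1):
        well = f"A{rep}"
        cells = od600_true * cfg.pems_per_od
        molecules = mpc * cells
        quench = np.exp(-cfg.quench_k_per_od * od600_true)
        autofluor = cfg.autofluor_rfu_per_od * od600_true + cfg.fluor_blank_rfu
        eps = rng.normal(0.0, cfg.rfu_cv, t.shape) if cfg.rfu_cv > 0 else np.zeros_like(t)
        rfu = cf * molecules * quench * (1.0 + eps) + autofluor
        emit(well, "sample", "od600", noisy(od600_true * path + cfg.media_blank_od))
        emit(well, "sample", "od700", noisy(od700_true * path + cfg.media_blank_od))
        emit(well, "sample", "fluorescence", rfu, gain=cfg.growth_gain)
        for ti, odt, cell, mol, mp in zip(t, od600_true, cells, molecules, mpc):
            truth_rows.append(
                {
                    "well": well, "time": float(ti), "od600_per_cm": float(odt),
                    "od700_per_cm": float((odt - c) / m), "cells": float(cell),
                    "molecules_per_cell": float(mp), "molecules": float(mol),
                }
            )

    for rep in range(1, cfg.n_replicates + 1):
        well = f"B{rep}"
        autofluor = cfg.autofluor_rfu_per_od * od600_true + cfg.fluor_blank_rfu
        emit(well, "control_cells", "od600", noisy(od600_true * path + cfg.media_blank_od))
        emit(well, "control_cells", "od700", noisy(od700_true * path + cfg.media_blank_od))
        emit(well, "control_cells", "fluorescence", autofluor, gain=cfg.growth_gain)

    zeros = np.zeros_like(t)
    emit("C1", "blank", "od600", noisy(zeros + cfg.media_blank_od))
    emit("C1", "blank", "od700", noisy(zeros + cfg.media_blank_od))
    emit("C1", "blank", "fluorescence", zeros + cfg.fluor_blank_rfu, gain=cfg.growth_gain)

    meta = {
        "true_cf": cf,
        "gain": cfg.growth_gain,
        "quench_k_per_od": cfg.quench_k_per_od,
        "pems_per_od": cfg.pems_per_od,
        "od600_od700_slope": m,
        "od600_od700_intercept": c,
        "pathlength_cm": path,
        "media_blank_wells": ["C1"],
        "control_wells": [f"B{r}" for r in range(1, cfg.n_replicates + 1)],
        "sample_wells": [f"A{r}" for r in range(1, cfg.n_replicates + 1)],
        "culture_volume_ul": 200.0,
    }
    return _tidy_rows(records), pd.DataFrame(truth_rows), meta
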