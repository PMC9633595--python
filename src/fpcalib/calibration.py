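"""Conversion-factor generation and cross-calibrant normalization.

The central calibration quantity is the **conversion factor** (CF): the RFU an
instrument reports per molecule of a given FP at a given filter set and gain.
It is obtained by regressing blank-subtracted fluorescence of a calibrant
dilution series (after saturation trimming) against the absolute number of
molecules per well, through the origin.  Companion calibrations:

* **OD calibration** — blanked OD/cm of a microsphere dilution series against
  particles per well gives particles-per-OD, turning culture OD into
  "particles of equivalent microspheres" (PEMS).
* **gain curves** — log10(CF) is smooth in detector gain, so a polynomial fit
  over measured gains interpolates CFs at unmeasured gains.
* **brightness normalization** — CFs measured with different calibrants are
  made comparable by scaling with the ratio of *relative brightness*
  (EC · ex.eff · QY · em.eff), where ex.eff and em.eff are band sums of the
  normalized spectra over the instrument's filter bands in 1 nm steps.
"""

from __future__ import annotations

import math

import numpy as np

from .fpbase import FPProperties
from .model import ConversionFactor, FilterSet, ODCalibration

AVOGADRO = 6.02214076e23


def molecules_from_conc(conc_ng_ul: float, volume_ul: float, mw_g_mol: float) -> float:
    """Number of molecules in a well: conc·volume in grams over MW, times N_A."""
    if conc_ng_ul < 0 or volume_ul <= 0 or mw_g_mol <= 0:
        raise ValueError("inputs must be positive (conc may be 0)")
    grams = conc_ng_ul * volume_ul * 1e-9
    return grams / mw_g_mol * AVOGADRO


def _zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least squares through the origin; returns (slope, R^2 about zero)."""
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate fit: all x are zero")
    slope = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return slope, r2


def _trim_saturated(
    molecules: np.ndarray,
    rfu: np.ndarray,
    ceiling: float | None,
    slope_tol: float = 0.2,
) -> np.ndarray:
    """Boolean mask of retained points after saturation trimming.

    Points at or above the detector ceiling are dropped outright; then, working
    down from the brightest retained point, points are dropped while the local
    log-log slope to the next point below departs from 1 by more than
    ``slope_tol`` (a saturating detector bends the log-log response flat).
    """
    keep = np.ones(len(rfu), dtype=bool)
    if ceiling is not None:
        keep &= rfu < ceiling
    order = np.argsort(molecules)
    idx = [i for i in order if keep[i] and rfu[i] > 0 and molecules[i] > 0]
    while len(idx) >= 3:
        top, below = idx[-1], idx[-2]
        dlog_m = math.log(molecules[top]) - math.log(molecules[below])
        if dlog_m == 0:
            break
        local = (math.log(rfu[top]) - math.log(rfu[below])) / dlog_m
        if abs(local - 1.0) > slope_tol:
            keep[top] = False
            idx.pop()
        else:
            break
    return keep


def generate_cfs(
    fluor_by_gain: dict[int, list[tuple[float, float]]],
    molecules_by_dilution: dict[float, float],
    fp: FPProperties,
    blank_rfu_by_gain: dict[int, float] | None = None,
    ceiling_by_gain: dict[int, float] | None = None,
    instrument: str = "sim",
    filterset: FilterSet | None = None,
) -> list[ConversionFactor]:
    """Generate RFU-per-molecule conversion factors, one per gain.

    ``fluor_by_gain`` maps gain → list of (dilution_factor, RFU);
    ``molecules_by_dilution`` maps dilution_factor → molecules per well (from
    the protein assay and well volume).  Per gain: blank-subtract, trim
    saturated points, then fit net RFU vs molecules through the origin.
    """
    blank_rfu_by_gain = blank_rfu_by_gain or {}
    ceiling_by_gain = ceiling_by_gain or {}
    out = []
    for gain, series in sorted(fluor_by_gain.items()):
        dfs = np.array([d for d, _ in series], dtype=float)
        missing = [d for d in dfs if d not in molecules_by_dilution]
        if missing:
            raise ValueError(f"gain {gain}: no molecule count for dilutions {missing}")
        mols = np.array([molecules_by_dilution[d] for d in dfs])
        rfu = np.array([v for _, v in series], dtype=float)
        blank = blank_rfu_by_gain.get(gain, 0.0)
        net = rfu - blank
        ceiling = ceiling_by_gain.get(gain)
        # the ceiling applies to the raw reading, so shift it with the blank
        keep = _trim_saturated(mols, net, None if ceiling is None else ceiling - blank)
        if keep.sum() < 3:
            raise ValueError(f"gain {gain}: fewer than 3 usable points after trimming")
        slope, r2 = _zero_intercept_fit(mols[keep], net[keep])
        if slope <= 0:
            raise ValueError(f"gain {gain}: non-positive conversion factor {slope}")
        out.append(
            ConversionFactor(
                fp_name=fp.name,
                instrument=instrument,
                filterset=filterset,
                gain=int(gain),
                cf_rfu_per_molecule=slope,
                n_points=int(keep.sum()),
                r_squared=min(r2, 1.0),
            )
        )
    return out


class GainCurve:
    """Polynomial model of log10(CF) vs gain, valid only within the fitted range."""

    def __init__(self, gains: np.ndarray, log10_cfs: np.ndarray, degree: int):
        self.gains = gains
        self.degree = degree
        self.coefficients = np.polynomial.polynomial.polyfit(gains, log10_cfs, degree)
        pred = np.polynomial.polynomial.polyval(gains, self.coefficients)
        self.residual_rms = float(np.sqrt(np.mean((log10_cfs - pred) ** 2)))

    def __call__(self, gain: float) -> float:
        lo, hi = self.gains.min(), self.gains.max()
        if not (lo <= gain <= hi):
            raise ValueError(f"gain {gain} outside fitted range [{lo}, {hi}]; not extrapolating")
        return float(10 ** np.polynomial.polynomial.polyval(gain, self.coefficients))


def fit_gain_curve(cfs: list[ConversionFactor], degree: int = 3) -> GainCurve:
    """Fit log10(CF) vs gain over ≥5 gains of one channel."""
    if len(cfs) < 5:
        raise ValueError(f"need >= 5 gains to fit a gain curve, got {len(cfs)}")
    if len({c.gain for c in cfs}) != len(cfs):
        raise ValueError("duplicate gains in conversion-factor set")
    gains = np.array([c.gain for c in cfs], dtype=float)
    logs = np.log10([c.cf_rfu_per_molecule for c in cfs])
    return GainCurve(gains, logs, degree)


def microspheres_per_gram(diameter_um: float = 0.890, density_g_cc: float = 2.0) -> float:
    """Particles per gram of monodisperse spheres: 1 / (ρ · π/6 · d³)."""
    d_cm = diameter_um * 1e-4
    mass_per_sphere = density_g_cc * (np.pi / 6.0) * d_cm**3
    return 1.0 / mass_per_sphere


def calibrate_od(
    microsphere_series: list[tuple[float, float]],
    stock_particles_per_ul: float,
    volume_ul: float,
    pathlength_cm: float = 1.0,
    od_wavelength: int = 600,
    blank_od: float = 0.0,
    diameter_um: float = 0.890,
    density_g_cc: float = 2.0,
    instrument: str = "sim",
) -> ODCalibration:
    """Calibrate OD to particle counts from a microsphere dilution series.

    ``microsphere_series`` is (dilution_factor, raw OD) pairs.  Blanked OD/cm
    is fit against particles per well through the origin; the calibration is
    the reciprocal slope, particles per OD/cm.  R² < 0.95 flags departure from
    single-scattering linearity but does not abort.
    """
    pts = np.asarray(microsphere_series, dtype=float)
    particles = stock_particles_per_ul * volume_ul / pts[:, 0]
    od = (pts[:, 1] - blank_od) / pathlength_cm
    # zero-particle wells carry no information for a through-origin fit
    mask = (particles > 0) & np.isfinite(od)
    slope, r2 = _zero_intercept_fit(particles[mask], od[mask])
    if slope <= 0:
        raise ValueError("non-positive OD-per-particle slope")
    return ODCalibration(
        od_wavelength=od_wavelength,
        particles_per_od_cm=1.0 / slope,
        diameter_um=diameter_um,
        density_g_cc=density_g_cc,
        r_squared=min(r2, 1.0),
        instrument=instrument,
    )


def _band_indices(center: float, bandwidth: float) -> tuple[int, int]:
    """Inclusive integer-nm band endpoints; half-integer edges round inward."""
    lo = center - bandwidth / 2.0
    hi = center + bandwidth / 2.0
    return int(math.ceil(lo)), int(math.floor(hi))


def _band_sum(spectrum: np.ndarray, lo: int, hi: int) -> float:
    lam = spectrum[:, 0]
    mask = (lam >= lo) & (lam <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] nm outside spectrum support")
    return float(spectrum[mask, 1].sum())


def excitation_efficiency(fp: FPProperties, filters: FilterSet) -> float:
    """ex.eff: sum of the normalized absorbance over the excitation band, 1 nm steps."""
    lo, hi = _band_indices(filters.ex_center_nm, filters.ex_bandwidth_nm)
    return _band_sum(fp.ex_spectrum, lo, hi)


def emission_efficiency(fp: FPProperties, filters: FilterSet) -> float:
    """em.eff: emission band sum over the total emission sum (a capture fraction)."""
    lo, hi = _band_indices(filters.em_center_nm, filters.em_bandwidth_nm)
    total = float(fp.em_spectrum[:, 1].sum())
    return _band_sum(fp.em_spectrum, lo, hi) / total


def relative_brightness(
    fp: FPProperties, filters: FilterSet, ec_choice: str = "ecmax"
) -> float:
    """Relative brightness = EC · ex.eff · QY · em.eff for the given filter set."""
    if ec_choice == "ecmax":
        ec = fp.ecmax_M_cm
    elif ec_choice == "ec280":
        if not fp.ec280_M_cm:
            raise ValueError(f"{fp.name}: no EC280 on record")
        ec = fp.ec280_M_cm
    else:
        raise ValueError(f"unknown ec_choice {ec_choice!r}")
    return ec * excitation_efficiency(fp, filters) * fp.qy * emission_efficiency(fp, filters)


def normalise_cf(
    cf: ConversionFactor,
    calibrant: FPProperties,
    reference: FPProperties,
    filters: FilterSet,
) -> ConversionFactor:
    """Rescale a CF to reference-calibrant units:
    CFnorm = CF · brightness(reference) / brightness(calibrant)."""
    b_cal = relative_brightness(calibrant, filters)
    if b_cal == 0:
        raise ValueError(f"{calibrant.name}: zero brightness under {filters.label}")
    b_ref = relative_brightness(reference, filters)
    return cf.model_copy(
        update={
            "cf_rfu_per_molecule": cf.cf_rfu_per_molecule * b_ref / b_cal,
            "normalized": True,
            "reference_fp": reference.name,
        }
    )
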