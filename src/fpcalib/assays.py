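"""Protein concentration assays: A280, ECmax and microBCA, plus dilution-series fitting.

All three assays produce per-well :class:`ConcentrationEstimate` records that a
shared :func:`fit_dilution_series` turns into a stock concentration with a
linear range:

* **A280** — Beer's law at 280 nm: C (M) = A280 / (EC280 · L), with the EC280
  predicted from the protein sequence or taken from the property record.  It
  measures *total* aromatic protein, so it is only valid on pure samples.
* **ECmax** — Beer's law at the FP's peak excitation wavelength using the
  chromophore extinction coefficient: C = A(λmax) / (ECmax · L).  Because only
  the mature chromophore absorbs there, the assay is FP-specific and remains
  accurate in crude lysates.
* **microBCA** — colorimetric A562 response calibrated against a BSA standard
  curve (polynomial), with an extra pre-reagent baseline read so that the
  intrinsic A562 absorbance of red FPs does not inflate the result.

Absorbance reads are blank-subtracted, scatter-corrected and divided by a
per-well path length (see :mod:`fpcalib.spectra`), so everything is reported
per cm as in a cuvette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .fpbase import FPProperties, ec280_from_sequence
from .spectra import (
    AbsorbanceSpectrum,
    PathlengthModel,
    ScatterFit,
    absorbance_at,
    blank_correct,
    estimate_pathlength,
    fit_scatter,
)

AVOGADRO = 6.02214076e23

#: Default limits of detection (ng/µl) per assay, reflecting the observed
#: linear ranges: ECmax reaches ~0.1 ng/µl, A280 ~1 ng/µl, microBCA ~2 ng/µl.
DEFAULT_LOD_NG_UL = {"a280": 1.0, "ecmax": 0.1, "bca": 2.0}


@dataclass
class ConcentrationEstimate:
    """One well's protein concentration with quality flags."""

    well: str
    conc_ng_ul: float
    conc_M: float
    assay: str
    dilution_factor: float = 1.0
    below_lod: bool = False
    saturated: bool = False
    scatter_dominated: bool = False
    #: 3-sigma detection floor in concentration units; quantitative accuracy
    #: is only claimed above ~(10/3)x this (the limit of quantification)
    noise_floor_ng_ul: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_ng_ul < 0 or self.conc_M < 0:
            raise ValueError("concentrations must be floored at 0 upstream")


@dataclass
class ConcentrationFit:
    """Dilution-series fit: retained points, linear model, stock concentration."""

    series: list[tuple[float, float]]          # (dilution_factor, conc_ng_ul)
    retained: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    stock_conc_ng_ul: float
    lod_ng_ul: float


@dataclass
class StandardCurve:
    """BSA standard curve: net A562 as a polynomial in concentration (ng/µl)."""

    calibrant: str
    coefficients: np.ndarray        # ascending powers, passes through (0, 0)
    valid_range_ng_ul: tuple[float, float]
    residual_rms: float

    def predict(self, conc_ng_ul: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(conc_ng_ul, self.coefficients)


def _beer_estimate(
    spec: AbsorbanceSpectrum,
    blank: AbsorbanceSpectrum | None,
    lambda_nm: float,
    ec_M_cm: float,
    mw_g_mol: float,
    assay: str,
    pathlengths: dict[str, float] | None,
    pathlength_model: PathlengthModel | None,
    lod_ng_ul: float,
    halfwidth_nm: float,
    dilution_factor: float,
    scatter_window: tuple[float, float],
) -> ConcentrationEstimate:
    if pathlengths is not None and spec.well in pathlengths:
        path_cm = pathlengths[spec.well]
    else:
        path_cm = estimate_pathlength(spec, pathlength_model)
    corrected = blank_correct(spec, blank) if blank is not None else spec
    lo, hi = scatter_window
    if lo <= lambda_nm + 60 and lambda_nm - 60 <= hi and assay == "ecmax":
        raise ValueError(
            f"chromophore band around {lambda_nm} nm overlaps scatter window "
            f"[{lo}, {hi}]; choose a different window"
        )
    scatter = fit_scatter(corrected, scatter_window)
    a_band = absorbance_at(corrected, lambda_nm, halfwidth_nm, scatter)
    conc_M = max(a_band, 0.0) / (ec_M_cm * path_cm)
    # 1 M x MW g/mol = MW g/L = MW * 1e3 ng/ul
    conc_ng_ul = conc_M * mw_g_mol * 1e3
    scatter_at_band = float(scatter.predict(lambda_nm))
    # noise floor: in-window residual noise of the scatter fit, amplified by
    # the power-law lever arm when extrapolating from the window to the band
    mask = (corrected.wavelengths_nm >= scatter_window[0]) & (
        corrected.wavelengths_nm <= scatter_window[1]
    )
    resid = corrected.absorbance[mask] - scatter.predict(corrected.wavelengths_nm[mask])
    noise_rms = float(np.sqrt(np.mean(resid**2)))
    mid = float(np.sqrt(scatter_window[0] * scatter_window[1]))
    lever = max(1.0, (mid / lambda_nm) ** abs(scatter.b)) if scatter.a > 0 else 1.0
    noise_floor_a = 3.0 * noise_rms * lever
    return ConcentrationEstimate(
        well=spec.well,
        conc_ng_ul=conc_ng_ul,
        conc_M=conc_M,
        assay=assay,
        dilution_factor=dilution_factor,
        below_lod=conc_ng_ul < lod_ng_ul or a_band < noise_floor_a,
        scatter_dominated=scatter_at_band > max(a_band, 0.0),
        noise_floor_ng_ul=noise_floor_a / (ec_M_cm * path_cm) * mw_g_mol * 1e3,
    )


def get_conc_a280(
    spectra: list[AbsorbanceSpectrum],
    fp: FPProperties,
    pathlengths: dict[str, float] | None = None,
    blank: AbsorbanceSpectrum | None = None,
    dilution_factors: dict[str, float] | None = None,
    pathlength_model: PathlengthModel | None = None,
    lod_ng_ul: float = DEFAULT_LOD_NG_UL["a280"],
    halfwidth_nm: float = 2.0,
    scatter_window: tuple[float, float] = (700.0, 900.0),
) -> list[ConcentrationEstimate]:
    """A280 assay over a series of wells: C = A280,corrected / (EC280 · L)."""
    ec280 = fp.ec280_M_cm
    if ec280 is None and fp.sequence:
        ec280 = ec280_from_sequence(fp.sequence)
    if not ec280:
        raise ValueError(
            f"{fp.name}: no aromatic absorbance (EC280 unavailable or zero); "
            "A280 assay not applicable"
        )
    out = []
    for spec in spectra:
        df = (dilution_factors or {}).get(spec.well, 1.0)
        out.append(
            _beer_estimate(
                spec, blank, 280.0, ec280, fp.mw_g_mol, "a280",
                pathlengths, pathlength_model, lod_ng_ul, halfwidth_nm, df,
                scatter_window,
            )
        )
    return out


def get_conc_ecmax(
    spectra: list[AbsorbanceSpectrum],
    fp: FPProperties,
    pathlengths: dict[str, float] | None = None,
    blank: AbsorbanceSpectrum | None = None,
    dilution_factors: dict[str, float] | None = None,
    pathlength_model: PathlengthModel | None = None,
    lod_ng_ul: float = DEFAULT_LOD_NG_UL["ecmax"],
    halfwidth_nm: float = 2.0,
    scatter_window: tuple[float, float] = (700.0, 900.0),
) -> list[ConcentrationEstimate]:
    """ECmax assay: C = A(λmax, corrected) / (ECmax · L); valid on lysates."""
    out = []
    for spec in spectra:
        df = (dilution_factors or {}).get(spec.well, 1.0)
        out.append(
            _beer_estimate(
                spec, blank, fp.lambda_max_nm, fp.ecmax_M_cm, fp.mw_g_mol,
                "ecmax", pathlengths, pathlength_model, lod_ng_ul, halfwidth_nm,
                df, scatter_window,
            )
        )
    return out


def fit_bca_standard(
    bsa_series: list[tuple[float, float]], degree: int = 3, calibrant: str = "BSA"
) -> StandardCurve:
    """Fit a polynomial standard curve to blank-subtracted BSA standards.

    The intercept is anchored to the zero standard (net A = 0 at 0 ng/µl) and
    the fitted curve is checked numerically for monotonicity over the standard
    range; a non-monotone fit suggests the degree is too high for the data.
    """
    pts = np.asarray(bsa_series, dtype=float)
    if len(pts) < degree + 2:
        raise ValueError(f"need >= {degree + 2} standards for degree {degree}")
    conc, a562 = pts[:, 0], pts[:, 1]
    # anchor through origin: fit on basis x, x^2, ..., x^degree
    X = np.vander(conc, degree + 1, increasing=True)[:, 1:]
    beta, *_ = np.linalg.lstsq(X, a562, rcond=None)
    coeffs = np.concatenate([[0.0], beta])
    lo, hi = float(conc.min()), float(conc.max())
    grid = np.linspace(lo, hi, 512)
    vals = np.polynomial.polynomial.polyval(grid, coeffs)
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError(
            f"standard curve (degree {degree}) is non-monotone over [{lo}, {hi}] "
            "ng/ul; try a lower degree"
        )
    resid = a562 - np.polynomial.polynomial.polyval(conc, coeffs)
    return StandardCurve(
        calibrant=calibrant,
        coefficients=coeffs,
        valid_range_ng_ul=(lo, hi),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def get_conc_bca(
    samples: dict[str, float],
    curve: StandardCurve,
    baseline_a562: dict[str, float] | None = None,
    mw_g_mol: float = 27000.0,
    dilution_factors: dict[str, float] | None = None,
    lod_ng_ul: float = DEFAULT_LOD_NG_UL["bca"],
) -> list[ConcentrationEstimate]:
    """microBCA assay: invert the standard curve on net A562 reads.

    ``samples`` maps well → blank-subtracted A562 after reagent incubation;
    ``baseline_a562`` maps well → pre-reagent A562 of the sample itself, the
    extra subtraction that stops intrinsically red samples (FPs absorbing near
    562 nm) from reading as extra protein.
    """
    baseline_a562 = baseline_a562 or {}
    lo, hi = curve.valid_range_ng_ul
    y_lo, y_hi = float(curve.predict(lo)), float(curve.predict(hi))
    out = []
    for well, a in samples.items():
        net = a - baseline_a562.get(well, 0.0)
        df = (dilution_factors or {}).get(well, 1.0)
        below, saturated = False, False
        if net <= y_lo:
            conc, below = 0.0, True
        elif net >= y_hi:
            conc, saturated = hi, True
        else:
            conc = optimize.brentq(
                lambda c: float(curve.predict(c)) - net, lo, hi, xtol=1e-6
            )
        conc = max(conc, 0.0)
        out.append(
            ConcentrationEstimate(
                well=well,
                conc_ng_ul=conc,
                conc_M=conc / (mw_g_mol * 1e3),
                assay="bca",
                dilution_factor=df,
                below_lod=below or conc < lod_ng_ul,
                saturated=saturated,
            )
        )
    return out


def fit_dilution_series(
    series: list[tuple[float, float]], lod_ng_ul: float
) -> ConcentrationFit:
    """Fit conc ~ 1/dilution_factor over points above the assay's LOD.

    Duplicate dilution factors are averaged first; the stock concentration is
    the model prediction at dilution factor 1.
    """
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("series must be (dilution_factor, conc) pairs")
    # average duplicates per dilution factor
    order: dict[float, list[float]] = {}
    for df, conc in pts:
        order.setdefault(float(df), []).append(float(conc))
    averaged = [(df, float(np.mean(cs))) for df, cs in sorted(order.items())]
    retained = [(df, c) for df, c in averaged if c >= lod_ng_ul]
    if len(retained) < 3:
        raise ValueError(
            f"series below sensitivity: only {len(retained)} points above "
            f"LOD {lod_ng_ul} ng/ul (need >= 3)"
        )
    x = np.array([1.0 / df for df, _ in retained])
    y = np.array([c for _, c in retained])
    fit = stats.linregress(x, y)
    stock = float(fit.slope * 1.0 + fit.intercept)
    return ConcentrationFit(
        series=[(float(a), float(b)) for a, b in series],
        retained=retained,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        stock_conc_ng_ul=stock,
        lod_ng_ul=lod_ng_ul,
    )
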