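"""Absorbance-spectrum processing for microplate protein assays.

Absorbance assays here read a full 200–1000 nm spectrum per well rather than a
single wavelength, which makes three corrections possible:

* **blank subtraction** against a buffer-only well;
* **path-length estimation** from the near-infrared water absorbance band
  (the differential A(975) − A(900) scales with the liquid column height, so a
  per-well optical path in cm can be recovered without knowing the meniscus);
* **light-scatter correction** by fitting a power law A = a·λ^b over a window
  free of chromophore, aromatic and water bands and extrapolating it under the
  analysis bands.

Band reads (:func:`absorbance_at`) are simple means over λ ± halfwidth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Default water-band differential absorbance for a 1 cm path (instrument
#: constant; re-measure with buffer-only wells for accurate work).
K_WATER_PER_CM = 0.172

#: Default scatter-fit window: above FP chromophore bands, below the water band.
SCATTER_WINDOW = (700.0, 900.0)


@dataclass
class AbsorbanceSpectrum:
    """One well's absorbance spectrum on a strictly ascending wavelength grid."""

    well: str
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    volume_ul: float = 225.0
    buffer: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths_nm.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance arrays differ in length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly ascending")

    def band_mean(self, lo: float, hi: float) -> float:
        mask = (self.wavelengths_nm >= lo) & (self.wavelengths_nm <= hi)
        if not mask.any():
            raise ValueError(f"band [{lo}, {hi}] nm outside spectrum coverage")
        return float(self.absorbance[mask].mean())


class PathlengthMethod(str, enum.Enum):
    water_band = "water_band"
    geometry = "geometry"


@dataclass
class PathlengthModel:
    """Per-well optical path estimation.

    ``water_band`` divides the 975−900 nm absorbance differential by the
    instrument's 1 cm water-band constant.  ``geometry`` interpolates a
    volume → path table for the plate type in use.
    """

    method: PathlengthMethod = PathlengthMethod.water_band
    k_water_per_cm: float = K_WATER_PER_CM
    geometry_table: dict[float, float] = field(default_factory=dict)


@dataclass
class ScatterFit:
    """Fitted power-law scatter baseline A(λ) = a·λ^b, b ≤ 0."""

    window_nm: tuple[float, float]
    a: float
    b: float
    residual_rms: float

    def predict(self, wavelengths_nm: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(wavelengths_nm, dtype=float) ** self.b


def blank_correct(
    sample: AbsorbanceSpectrum, blank: AbsorbanceSpectrum
) -> AbsorbanceSpectrum:
    """Subtract a buffer blank point-wise; negatives are retained for diagnostics."""
    import warnings

    if blank.buffer and sample.buffer and blank.buffer != sample.buffer:
        warnings.warn(
            f"buffer mismatch: sample {sample.buffer!r} vs blank {blank.buffer!r}",
            stacklevel=2,
        )
    if np.array_equal(sample.wavelengths_nm, blank.wavelengths_nm):
        blank_a = blank.absorbance
    else:
        lo, hi = blank.wavelengths_nm[0], blank.wavelengths_nm[-1]
        if sample.wavelengths_nm[0] < lo or sample.wavelengths_nm[-1] > hi:
            raise ValueError("blank grid does not cover sample grid; cannot interpolate")
        blank_a = np.interp(sample.wavelengths_nm, blank.wavelengths_nm, blank.absorbance)
    return AbsorbanceSpectrum(
        well=sample.well,
        wavelengths_nm=sample.wavelengths_nm.copy(),
        absorbance=sample.absorbance - blank_a,
        volume_ul=sample.volume_ul,
        buffer=sample.buffer,
    )


def estimate_pathlength(
    sample: AbsorbanceSpectrum, model: PathlengthModel | None = None
) -> float:
    """Estimate the optical path (cm) for one well.

    Water-band mode: path = (A(975) − A(900)) / k_water_per_cm, each read
    averaged over a ±2 nm window of the raw (un-blanked) spectrum.
    """
    model = model or PathlengthModel()
    if model.method == PathlengthMethod.geometry:
        if not model.geometry_table:
            raise ValueError("geometry method requires a volume->path table")
        vols = np.array(sorted(model.geometry_table))
        paths = np.array([model.geometry_table[v] for v in vols])
        return float(np.interp(sample.volume_ul, vols, paths))
    if model.k_water_per_cm <= 0:
        raise ValueError("k_water_per_cm must be positive")
    diff = sample.band_mean(973, 977) - sample.band_mean(898, 902)
    if diff <= 0:
        raise ValueError(
            "non-positive water-band differential; spectrum may lack a water band "
            "- consider the geometry fallback"
        )
    return diff / model.k_water_per_cm


def fit_scatter(
    sample: AbsorbanceSpectrum,
    window_nm: tuple[float, float] = SCATTER_WINDOW,
    b_bounds: tuple[float, float] = (-4.5, 0.0),
) -> ScatterFit:
    """Fit log A vs log λ over a chromophore-free window; exponent clipped ≤ 0.

    Non-positive absorbances in the window are excluded from the fit; fewer
    than 5 usable points is an error.
    """
    lo, hi = window_nm
    mask = (sample.wavelengths_nm >= lo) & (sample.wavelengths_nm <= hi)
    if mask.sum() < 10:
        raise ValueError(f"scatter window [{lo}, {hi}] contains <10 grid points")
    lam = sample.wavelengths_nm[mask]
    a_vals = sample.absorbance[mask]
    pos = a_vals > 0
    if pos.sum() < 5:
        # effectively scatter-free well (blank-corrected noise around zero)
        return ScatterFit(window_nm=(lo, hi), a=0.0, b=0.0, residual_rms=0.0)
    x = np.log(lam[pos])
    y = np.log(a_vals[pos])
    slope, intercept = np.polyfit(x, y, 1)
    b0 = float(np.clip(slope, *b_bounds))
    if b0 != slope:
        intercept = float(np.mean(y - b0 * x))
    a0 = float(np.exp(intercept))
    # refine in linear space: the log-log fit is biased under additive noise
    # (small/negative readings are censored), which extrapolates badly
    from scipy.optimize import curve_fit

    try:
        popt, _ = curve_fit(
            lambda l, a, b: a * l**b,
            lam,
            a_vals,
            p0=[a0, b0],
            bounds=([0.0, b_bounds[0]], [np.inf, b_bounds[1] + 1e-12]),
            maxfev=5000,
        )
        a, b = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, b = a0, b0
    resid = a_vals - a * lam**b
    return ScatterFit(window_nm=(lo, hi), a=a, b=b, residual_rms=float(np.sqrt(np.mean(resid**2))))


def absorbance_at(
    sample: AbsorbanceSpectrum,
    lambda_nm: float,
    halfwidth_nm: float = 2.0,
    scatter: ScatterFit | None = None,
) -> float:
    """Band read: mean of (A − fitted scatter) over [λ − halfwidth, λ + halfwidth]."""
    lo, hi = lambda_nm - halfwidth_nm, lambda_nm + halfwidth_nm
    mask = (sample.wavelengths_nm >= lo) & (sample.wavelengths_nm <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] nm outside spectrum coverage")
    vals = sample.absorbance[mask]
    if scatter is not None:
        vals = vals - scatter.predict(sample.wavelengths_nm[mask])
    return float(vals.mean())


def subtract_scatter(sample: AbsorbanceSpectrum, scatter: ScatterFit) -> AbsorbanceSpectrum:
    """Return the spectrum with the fitted scatter baseline removed everywhere."""
    return AbsorbanceSpectrum(
        well=sample.well,
        wavelengths_nm=sample.wavelengths_nm.copy(),
        absorbance=sample.absorbance - scatter.predict(sample.wavelengths_nm),
        volume_ul=sample.volume_ul,
        buffer=sample.buffer,
    )


def normalise_fluor_spectrum(scan: np.ndarray) -> np.ndarray:
    """Normalize an (λ, intensity) scan so the highest intensity equals 1."""
    scan = np.asarray(scan, dtype=float)
    if scan.ndim != 2 or scan.shape[1] != 2:
        raise ValueError("scan must be an (n, 2) array of (wavelength, intensity)")
    peak = scan[:, 1].max()
    if peak <= 0:
        raise ValueError("cannot normalize a scan with no positive intensity")
    out = scan.copy()
    out[:, 1] = out[:, 1] / peak
    return out
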