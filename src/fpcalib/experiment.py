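"""Calibrated processing of growth-and-expression timecourses.

:func:`process_plate` converts a tidy OD + fluorescence timecourse into
absolute units through a fixed stage order:

1. blank OD against media wells and normalize per cm;
2. convert OD/cm to cell counts via the microsphere calibration (PEMS);
3. subtract cellular autofluorescence predicted at the matched OD from a
   no-FP control strain;
4. undo fluorescence quenching by the cell suspension (divide by the fitted
   retained fraction at the measured OD);
5. divide by the conversion factor → molecules of equivalent FP (MEFP);
6. divide by cells → molecules per cell (suppressed below a minimum count);
7. divide by the OD-specific total cell volume (~3.6 µl per OD600/cm per ml of
   culture) → molar concentration inside the cells.

Autofluorescence is subtracted *before* de-quenching: background fluorescence
is emitted from within the same quenching suspension, so both signals are
attenuated together and the FP-specific signal must be isolated first.

:func:`od_ratio_analysis` quantifies FP interference with cell-density reads
by fitting OD600 ~ OD700 on reference (uninduced) wells and expressing every
observation as a ratio to its prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ConversionFactor, ODCalibration

AVOGADRO = 6.02214076e23

#: OD-specific total cell volume (µl of cells per OD600/cm per ml of culture).
VOL_PER_OD_UL_PER_ML = 3.6

#: Below this many particles, per-cell division is suppressed as unstable.
MIN_CELLS_DEFAULT = 1e5


@dataclass
class QuenchModel:
    """Fraction of fluorescence retained as a function of cell density.

    Default form: retained(od) = exp(−k·od), fitted to a cell-mixing assay.
    Always satisfies retained(0) = 1 and monotone non-increase.
    """

    k_per_od: float = 0.0
    form: str = "exp_decay"
    fit_rms: float = 0.0
    od_range: tuple[float, float] = (0.0, np.inf)
    clamped: bool = False

    def retained_fraction(self, od_per_cm: np.ndarray | float) -> np.ndarray | float:
        od = np.clip(np.asarray(od_per_cm, dtype=float), 0.0, None)
        out = np.exp(-self.k_per_od * od)
        return float(out) if np.isscalar(od_per_cm) else out


@dataclass
class AutofluorModel:
    """Monotone mapping OD/cm → control-strain fluorescence (RFU).

    Piecewise linear between calibration points; predictions outside the
    calibrated OD range are clamped to the range ends.
    """

    od_points: np.ndarray
    rfu_points: np.ndarray
    channel: str = ""
    isotonic_applied: bool = False

    def predict(self, od_per_cm: np.ndarray | float) -> np.ndarray | float:
        out = np.interp(np.asarray(od_per_cm, dtype=float), self.od_points, self.rfu_points)
        return float(out) if np.isscalar(od_per_cm) else out


def blank_od(
    timecourse: pd.DataFrame,
    media_blank_wells: list[str],
    pathlength_cm: float,
    measure: str = "od600",
) -> pd.DataFrame:
    """Blank an OD timecourse against media wells, matched by nearest timepoint.

    Returns one row per (well, time) with ``od_per_cm`` (negatives floored at 0
    and flagged).
    """
    od = timecourse[timecourse["measure"] == measure]
    if od.empty:
        raise ValueError(f"no {measure} rows in timecourse")
    blanks = od[od["well"].isin(media_blank_wells)]
    if blanks.empty:
        raise ValueError(f"no media blank wells among {media_blank_wells}")
    blank_mean = blanks.groupby("time")["value"].mean()
    samples = od[~od["well"].isin(media_blank_wells)].copy()
    blank_times = blank_mean.index.to_numpy(dtype=float)

    def nearest_blank(t: float) -> float:
        return float(blank_mean.iloc[np.argmin(np.abs(blank_times - t))])

    samples["od_per_cm"] = samples.apply(
        lambda r: (r["value"] - nearest_blank(r["time"])) / pathlength_cm, axis=1
    )
    samples["od_floored"] = samples["od_per_cm"] < 0
    samples.loc[samples["od_floored"], "od_per_cm"] = 0.0
    return samples[["well", "time", "od_per_cm", "od_floored"]].reset_index(drop=True)


def fit_autofluorescence(
    control_points: list[tuple[float, float]], channel: str = ""
) -> AutofluorModel:
    """Fit the control-strain background fluorescence as a function of OD/cm.

    Points are averaged per OD, sorted, floored at 0 and made monotone by
    pool-adjacent-violators if needed (flagged on the model).
    """
    pts = np.asarray(control_points, dtype=float)
    if len(pts) < 5:
        raise ValueError(f"need >= 5 control points, got {len(pts)}")
    order = np.argsort(pts[:, 0])
    od = pts[order, 0]
    rfu = np.clip(pts[order, 1], 0.0, None)
    # average ties in od
    uod, inv = np.unique(od, return_inverse=True)
    urfu = np.zeros_like(uod)
    for i in range(len(uod)):
        urfu[i] = rfu[inv == i].mean()
    isotonic = False
    if np.any(np.diff(urfu) < -1e-9 * max(urfu.max(), 1.0)):
        urfu = _pava(urfu)
        isotonic = True
    return AutofluorModel(od_points=uod, rfu_points=urfu, channel=channel,
                          isotonic_applied=isotonic)


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-decreasing fit (uniform weights)."""
    y = y.astype(float).copy()
    n = len(y)
    blocks = [[i, i, y[i]] for i in range(n)]  # start, end, mean
    merged = [blocks[0]]
    for blk in blocks[1:]:
        merged.append(blk)
        while len(merged) > 1 and merged[-2][2] > merged[-1][2]:
            b = merged.pop()
            a = merged.pop()
            n_a, n_b = a[1] - a[0] + 1, b[1] - b[0] + 1
            merged.append([a[0], b[1], (a[2] * n_a + b[2] * n_b) / (n_a + n_b)])
    out = np.empty(n)
    for start, end, mean in merged:
        out[start : end + 1] = mean
    return out


def fit_quench_model(
    mixing_rows: list[tuple[float, float, float]], tolerance: float = 0.05
) -> QuenchModel:
    """Fit the quench model to a cell-mixing assay.

    Each row is (od_per_cm, RFU with cells, RFU without cells), autofluorescence
    already subtracted from the with-cells read.  The retained fraction per row
    is RFU_with / RFU_without and the default model retained = exp(−k·od) is
    fitted by nonlinear least squares with k ≥ 0.
    """
    import warnings

    pts = np.asarray(mixing_rows, dtype=float)
    od_levels = np.unique(pts[:, 0])
    if len(od_levels) < 4:
        raise ValueError(f"need >= 4 OD levels, got {len(od_levels)}")
    od = pts[:, 0]
    f = pts[:, 1] / pts[:, 2]
    if np.any(f > 1 + tolerance):
        warnings.warn(
            "retained fractions above 1: no quenching measurable at some ODs",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # k = 0 sits on the bound; the (unused) covariance is then singular
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            lambda x, k: np.exp(-k * x), od, f, p0=[0.1], maxfev=10000
        )
    k = float(popt[0])
    clamped = k < 0
    k = max(k, 0.0)
    rms = float(np.sqrt(np.mean((np.exp(-k * od) - f) ** 2)))
    return QuenchModel(
        k_per_od=k,
        fit_rms=rms,
        od_range=(float(od.min()), float(od.max())),
        clamped=clamped,
    )


def correct_quench(
    rfu_net: np.ndarray | float,
    od_per_cm: np.ndarray | float,
    model: QuenchModel,
    floor: float = 0.2,
) -> np.ndarray | float:
    """De-quench: divide the net FP signal by the retained fraction at this OD."""
    retained = model.retained_fraction(od_per_cm)
    if np.any(np.asarray(retained) < floor):
        raise ValueError(
            f"retained fraction below {floor}: extrapolating the quench model "
            "this far is not supported"
        )
    return rfu_net / retained


def od_to_cell_volume(
    od_per_cm: float | np.ndarray,
    culture_volume_ml: float,
    vol_per_od_ul_per_ml: float = VOL_PER_OD_UL_PER_ML,
) -> float | np.ndarray:
    """Total cell volume (µl) in a culture from its OD600/cm."""
    return od_per_cm * vol_per_od_ul_per_ml * culture_volume_ml


def process_plate(
    timecourse: pd.DataFrame,
    cf: ConversionFactor,
    odcal: ODCalibration,
    autofluor: AutofluorModel,
    quench: QuenchModel,
    culture_volume_ul: float,
    media_blank_wells: list[str],
    pathlength_cm: float,
    od_measure: str = "od600",
    min_cells: float = MIN_CELLS_DEFAULT,
    gain: int | None = None,
) -> pd.DataFrame:
    """Full calibrated-timecourse pipeline; returns one row per (well, time).

    Output columns: ``od_per_cm``, ``cells`` (PEMS), ``rfu_net``,
    ``rfu_dequenched``, ``mefp``, ``molecules_per_cell`` (NaN + flag below
    ``min_cells``) and ``conc_M``.
    """
    if gain is not None and cf.gain != gain:
        raise ValueError(f"conversion factor gain {cf.gain} != data gain {gain}")
    if cf.instrument != odcal.instrument:
        raise ValueError(
            f"calibration instrument mismatch: CF from {cf.instrument!r}, "
            f"OD calibration from {odcal.instrument!r}"
        )
    od = blank_od(timecourse, media_blank_wells, pathlength_cm, measure=od_measure)
    fluor = timecourse[timecourse["measure"] == "fluorescence"]
    if fluor.empty:
        raise ValueError("no fluorescence rows in timecourse")
    merged = od.merge(
        fluor[["well", "time", "value"]].rename(columns={"value": "rfu_raw"}),
        on=["well", "time"],
        how="inner",
    )
    if merged.empty:
        raise ValueError("OD and fluorescence rows share no (well, time) keys")

    merged["cells"] = merged["od_per_cm"] * odcal.particles_per_od_cm
    merged["rfu_net"] = merged["rfu_raw"] - autofluor.predict(merged["od_per_cm"].to_numpy())
    merged["rfu_net"] = merged["rfu_net"].clip(lower=0.0)
    merged["rfu_dequenched"] = correct_quench(
        merged["rfu_net"].to_numpy(), merged["od_per_cm"].to_numpy(), quench
    )
    merged["mefp"] = merged["rfu_dequenched"] / cf.cf_rfu_per_molecule
    few_cells = merged["cells"] < min_cells
    merged["molecules_per_cell"] = np.where(
        few_cells, np.nan, merged["mefp"] / merged["cells"].replace(0, np.nan)
    )
    merged["few_cells"] = few_cells
    cell_vol_l = od_to_cell_volume(
        merged["od_per_cm"].to_numpy(), culture_volume_ul / 1000.0
    ) * 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = merged["mefp"].to_numpy() / (AVOGADRO * cell_vol_l)
    merged["conc_M"] = np.where(cell_vol_l > 0, conc, np.nan)
    cols = [
        "well", "time", "od_per_cm", "od_floored", "cells", "rfu_net",
        "rfu_dequenched", "mefp", "molecules_per_cell", "few_cells", "conc_M",
    ]
    return merged[cols]


@dataclass
class ODRatioResult:
    """OD600 ~ OD700 reference relation and per-observation OD600 error."""

    slope: float
    intercept: float
    r_squared: float
    errors: pd.DataFrame  # well, time, od600, od700, expected_od600, od600_error


def od_ratio_analysis(
    timecourse: pd.DataFrame,
    reference_wells: list[str],
    min_reference_points: int = 5,
    media_blank_wells: list[str] | None = None,
    pathlength_cm: float = 1.0,
) -> ODRatioResult:
    """Fit OD600 = m·OD700 + c on reference wells; express all wells as
    observed/expected OD600 to expose FP absorbance artefacts.

    If ``media_blank_wells`` is given, both channels are media-blanked and
    normalized per cm first, so the intercept is not confounded by the media
    baseline.
    """
    if media_blank_wells:
        od600 = blank_od(timecourse, media_blank_wells, pathlength_cm, "od600").rename(
            columns={"od_per_cm": "value"}
        )[["well", "time", "value"]]
        od700 = blank_od(timecourse, media_blank_wells, pathlength_cm, "od700").rename(
            columns={"od_per_cm": "value"}
        )[["well", "time", "value"]]
    else:
        od600 = timecourse[timecourse["measure"] == "od600"][["well", "time", "value"]]
        od700 = timecourse[timecourse["measure"] == "od700"][["well", "time", "value"]]
    paired = od600.rename(columns={"value": "od600"}).merge(
        od700.rename(columns={"value": "od700"}), on=["well", "time"]
    )
    if paired.empty:
        raise ValueError("no paired od600/od700 reads")
    ref = paired[paired["well"].isin(reference_wells)]
    if len(ref) < min_reference_points:
        raise ValueError(
            f"only {len(ref)} reference points (< {min_reference_points})"
        )
    fit = stats.linregress(ref["od700"], ref["od600"])
    paired = paired.copy()
    paired["expected_od600"] = fit.slope * paired["od700"] + fit.intercept
    paired["od600_error"] = paired["od600"] / paired["expected_od600"]
    return ODRatioResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        errors=paired,
    )


def autofluorescence_points(
    timecourse: pd.DataFrame,
    control_wells: list[str],
    media_blank_wells: list[str],
    pathlength_cm: float,
    od_measure: str = "od600",
) -> list[tuple[float, float]]:
    """Extract (od_per_cm, raw RFU) pairs from no-FP control wells for
    :func:`fit_autofluorescence`."""
    od = blank_od(timecourse, media_blank_wells, pathlength_cm, measure=od_measure)
    od = od[od["well"].isin(control_wells)]
    fluor = timecourse[
        (timecourse["measure"] == "fluorescence")
        & (timecourse["well"].isin(control_wells))
    ]
    merged = od.merge(
        fluor[["well", "time", "value"]].rename(columns={"value": "rfu"}),
        on=["well", "time"],
    )
    if merged.empty:
        raise ValueError("control wells have no paired OD/fluorescence reads")
    return list(zip(merged["od_per_cm"], merged["rfu"]))
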