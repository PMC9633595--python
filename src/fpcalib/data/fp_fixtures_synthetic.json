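{
  "_comment": "Offline fluorophore property records in an FPbase-like schema. Photophysical constants (ECmax, lambda max, QY, MW) are representative literature values; the excitation/emission spectra are SYNTHETIC Gaussian stand-ins generated from the peak/width parameters below by the loader, not measured spectra.",
  "mtagbfp2": {
    "name": "mTagBFP2",
    "slug": "mtagbfp2",
    "ecmax_M_cm": 50600,
    "ec280_M_cm": 29800,
    "lambda_max_nm": 399,
    "em_max_nm": 454,
    "qy": 0.64,
    "mw_g_mol": 26700,
    "ex_sigma_nm": 18,
    "em_sigma_nm": 18
  },
  "gfpmut3": {
    "name": "mGFPmut3",
    "slug": "gfpmut3",
    "ecmax_M_cm": 56000,
    "ec280_M_cm": 21890,
    "lambda_max_nm": 501,
    "em_max_nm": 511,
    "qy": 0.77,
    "mw_g_mol": 26900,
    "ex_sigma_nm": 20,
    "em_sigma_nm": 16
  },
  "mcherry": {
    "name": "mCherry",
    "slug": "mcherry",
    "ecmax_M_cm": 72000,
    "ec280_M_cm": 34380,
    "lambda_max_nm": 587,
    "em_max_nm": 610,
    "qy": 0.22,
    "mw_g_mol": 26722,
    "ex_sigma_nm": 22,
    "em_sigma_nm": 20
  },
  "fluorescein": {
    "name": "fluorescein",
    "slug": "fluorescein",
    "ecmax_M_cm": 76900,
    "ec280_M_cm": null,
    "lambda_max_nm": 490,
    "em_max_nm": 514,
    "qy": 0.925,
    "mw_g_mol": 332.31,
    "ex_sigma_nm": 16,
    "em_sigma_nm": 14
  }
}
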