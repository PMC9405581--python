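{
  "version": "1.0",
  "units": {"thickness": "mm", "mua": "cm^-1", "mus": "cm^-1", "wavelength": "nm"},
  "wavelengths_nm": [515, 660, 880],
  "epidermis": {
    "thickness_mm": 0.55,
    "mus": {"515": 388.35, "660": 303.03, "880": 227.27},
    "mua_vfm_cells": {
      "vfm": [0.03, 0.10, 0.20, 0.30],
      "515": [1.96, 6.28, 12.43, 18.58],
      "660": [0.86, 2.75, 5.44, 8.13],
      "880": [0.33, 1.06, 2.09, 3.13]
    },
    "melanosome_mua": {"amplitude": 6.6e10, "exponent": 3.33}
  },
  "dermis": {
    "total_thickness_model": {
      "anchor_thickness_mm": 0.75,
      "anchor_age_years": 61.0,
      "thinning_mm_per_year": 0.0044,
      "age_range_years": [18.0, 80.0]
    },
    "sublayer_fractions": {
      "papillary_dermis": 0.082,
      "upper_blood_net": 0.0437,
      "reticular_dermis": 0.8197,
      "deep_blood_net": 0.0546
    },
    "mus": {"515": 389.99, "660": 208.65, "880": 118.94},
    "mua_rest": {
      "papillary_dermis": {"515": 1.2166, "660": 0.5249, "880": 0.2344},
      "upper_blood_net": {"515": 1.5328, "660": 0.5398, "880": 0.2546},
      "reticular_dermis": {"515": 1.2167, "660": 0.5256, "880": 0.2456},
      "deep_blood_net": {"515": 1.2896, "660": 0.5288, "880": 0.2462}
    },
    "mua_pulsed": {
      "papillary_dermis": {"515": 1.2202, "660": 0.5250, "880": 0.2346},
      "upper_blood_net": {"515": 1.5593, "660": 0.5410, "880": 0.2558},
      "reticular_dermis": {"515": 1.2202, "660": 0.5257, "880": 0.2458},
      "deep_blood_net": {"515": 1.2985, "660": 0.5292, "880": 0.2466}
    }
  },
  "subcutis": {
    "thickness_mm": 2.0,
    "mua": {"515": 6.0798, "660": 0.2827, "880": 0.3195},
    "mus": {"515": 336.18, "660": 249.74, "880": 191.53}
  },
  "pulse_blood_factors": {
    "ages": [23.0, 34.4, 44.8, 55.0],
    "factors": [1.124, 1.099, 1.083, 1.073]
  },
  "defaults": {"anisotropy_g": 0.9, "refractive_index_tissue": 1.4, "refractive_index_ambient": 1.0}
}
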