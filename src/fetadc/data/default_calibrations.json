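{
  "comment": "Default group calibrations for phantom cohorts. Group means are the published REC/PTRE summaries; the shared between-patient SDs are derived from the printed MD +/- SE via pooled_sd_from_md_se (ADC: 91 / sqrt(1/32 + 1/10); TBRmax: 0.45 / sqrt(1/32 + 1/10)). The lesion profile exponent is solved so the continuum IC80 mean/max ratio at TBR 3.18 equals 2.75/3.18.",
  "groups": {
    "REC": {
      "group": "REC",
      "tbrmax_mean": 3.18,
      "tbrmax_sd": 1.2421180068162376,
      "core_adc_mean_mean": 1313.0,
      "core_adc_mean_sd": 251.18386360061692,
      "bg_suv_mean": 0.94,
      "bg_adc_mean": 768.0,
      "tbr_truncation_floor": 1.4
    },
    "PTRE": {
      "group": "PTRE",
      "tbrmax_mean": 2.09,
      "tbrmax_sd": 1.2421180068162376,
      "core_adc_mean_mean": 1029.0,
      "core_adc_mean_sd": 251.18386360061692,
      "bg_suv_mean": 1.11,
      "bg_adc_mean": 755.0,
      "tbr_truncation_floor": 1.4
    }
  },
  "phantom": {
    "grid_shape": [64, 64, 48],
    "voxel_size_mm": [2.0, 2.0, 2.5],
    "brain_semi_axes_mm": [55.0, 65.0, 45.0],
    "bg_suv_sd": 0.03,
    "bg_adc_sd": 40.0,
    "core_adc_sd": 100.0,
    "lesion_center_mm": [27.0, 9.0, 8.75],
    "lesion_radius_mm": 13.0,
    "core_dilation_voxels": 1,
    "lesion_profile_sigma_mm": 6.0,
    "lesion_profile_exponent": 1.6343640271696414,
    "csf_adc": 3000.0,
    "csf_suv": 0.2
  }
}
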