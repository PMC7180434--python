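{
  "notes": [
    "Default per-tissue optical profiles for the synthetic trace generator.",
    "mean_dod_690 / mean_dod_850 are class-mean optical-density changes",
    "(dimensionless) at 690 and 850 nm. They were derived by forward-mapping",
    "physiologically ordered relative hemoglobin concentrations through the",
    "two-chromophore MBLL model with L = 1 cm and B(lambda) = 1, using the",
    "shipped extinction table (690 nm: eps_HbO2 = 276, eps_Hb = 2052;",
    "850 nm: eps_HbO2 = 1058, eps_Hb = 691 cm^-1 M^-1).",
    "Underlying relative concentrations ([HbO2], [Hb]) in micromolar:",
    "artery (65, 12), vein (45, 30), muscle (11, 9), fat (5.5, 4.5),",
    "skin (4, 3.3), lung (1.5, 1.3), pleural_cavity (85, 60).",
    "These satisfy every reported ordinal relation between tissues: vein >",
    "artery in dOD at 690 nm, artery > vein at 850 nm, muscle > fat > skin,",
    "lung minimal, pleural cavity maximal (the cavity reading reflects the",
    "probe measurement, not true tissue hemoglobin), vessel [HbO2]/[Hb]/StO2",
    "above the non-vessel tissues, and StO2 artery > vein.",
    "noise_sd, trial_sd, drift_amp are dimensionless fractions of the class",
    "mean at each wavelength: within-trial sample noise SD, between-trial",
    "mean jitter SD, and slow sinusoidal baseline drift amplitude."
  ],
  "classes": {
    "skin": {
      "mean_dod_690": 0.0078756,
      "mean_dod_850": 0.0065123,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "fat": {
      "mean_dod_690": 0.010752,
      "mean_dod_850": 0.0089285,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "muscle": {
      "mean_dod_690": 0.021504,
      "mean_dod_850": 0.017857,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "artery": {
      "mean_dod_690": 0.042564,
      "mean_dod_850": 0.077062,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "vein": {
      "mean_dod_690": 0.07398,
      "mean_dod_850": 0.06834,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "lung": {
      "mean_dod_690": 0.0030816,
      "mean_dod_850": 0.0024853,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    },
    "pleural_cavity": {
      "mean_dod_690": 0.14658,
      "mean_dod_850": 0.13139,
      "noise_sd": 0.25,
      "trial_sd": 0.1,
      "drift_amp": 0.05
    }
  }
}
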