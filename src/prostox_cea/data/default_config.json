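{
  "p_high": 0.1872,
  "soc_utilization": {"sbrt": 0.383, "cfrt": 0.1235, "prostatectomy": 0.4935},
  "surgery_diversion": 0.8,
  "radiation_adherence": 1.0,
  "tested_prostatectomy_share": null,
  "tox_p1": {
    "T1": 0.2778, "T2": 0.0396, "T3": 0.1189,
    "T4": 0.0124, "T5": 0.0396, "T6": 0.1189,
    "T7": 0.0499, "T8": 0.0396, "T9": 0.1189
  },
  "taper": 0.7013,
  "u_notox": 0.9,
  "u_tox": 0.7,
  "d_cost": 0.03,
  "d_util": 0.03,
  "discounting_enabled": true,
  "c_treat": {"sbrt": 20670.28, "cfrt": 42642.68, "prostatectomy": 97782.37},
  "c_test": 4000.0,
  "c_notox": 2914.9,
  "c_tox": 5774.58,
  "cohort_size": 10000,
  "start_age": 67,
  "cycle_length": 1.0,
  "wtp_default": 100000.0,
  "psa_iterations": 10000,
  "psa_default_se_frac": 0.1,
  "dsa_delta": 0.2
}
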