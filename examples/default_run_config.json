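{
  "seed": 0,
  "generator": {
    "n_flaps": 65,
    "seed": 0,
    "replicate_table2": true,
    "calibration": {
      "entries": [
        {
          "group": "R_minus",
          "quantity": "sto2",
          "timepoint": "overall",
          "mean": 43.2,
          "sd": 10.3
        },
        {
          "group": "R_plus",
          "quantity": "sto2",
          "timepoint": "overall",
          "mean": 32.6,
          "sd": 9.8
        },
        {
          "group": "R_minus",
          "quantity": "sto2_dref",
          "timepoint": "overall",
          "mean": -18.3,
          "sd": 15.9
        },
        {
          "group": "R_plus",
          "quantity": "sto2_dref",
          "timepoint": "overall",
          "mean": -38.1,
          "sd": 18.2
        },
        {
          "group": "R_minus",
          "quantity": "npi",
          "timepoint": "overall",
          "mean": 42.8,
          "sd": 9.8
        },
        {
          "group": "R_plus",
          "quantity": "npi",
          "timepoint": "overall",
          "mean": 32.9,
          "sd": 12.8
        },
        {
          "group": "R_minus",
          "quantity": "npi_dref",
          "timepoint": "overall",
          "mean": 8.8,
          "sd": 25.7
        },
        {
          "group": "R_plus",
          "quantity": "npi_dref",
          "timepoint": "overall",
          "mean": -13.4,
          "sd": 36.9
        },
        {
          "group": "R_minus",
          "quantity": "thi",
          "timepoint": "overall",
          "mean": 55.0,
          "sd": 12.0
        },
        {
          "group": "R_plus",
          "quantity": "thi",
          "timepoint": "overall",
          "mean": 55.0,
          "sd": 12.0
        },
        {
          "group": "R_minus",
          "quantity": "twi",
          "timepoint": "overall",
          "mean": 50.0,
          "sd": 10.0
        },
        {
          "group": "R_plus",
          "quantity": "twi",
          "timepoint": "overall",
          "mean": 46.0,
          "sd": 10.0
        },
        {
          "group": "R_minus",
          "quantity": "ref_thi",
          "timepoint": "overall",
          "mean": 55.0,
          "sd": 10.0
        },
        {
          "group": "R_plus",
          "quantity": "ref_thi",
          "timepoint": "overall",
          "mean": 55.0,
          "sd": 10.0
        },
        {
          "group": "R_minus",
          "quantity": "ref_twi",
          "timepoint": "overall",
          "mean": 50.0,
          "sd": 10.0
        },
        {
          "group": "R_plus",
          "quantity": "ref_twi",
          "timepoint": "overall",
          "mean": 50.0,
          "sd": 10.0
        }
      ]
    },
    "lead_time_law": {
      "family": "gamma",
      "mean": 4.8,
      "sd": 5.0
    },
    "clinical_detection_law": {
      "family": "gamma",
      "mean": 23.1,
      "sd": 21.9
    },
    "thi_congestion_shift": 12.0,
    "thi_arterial_shift": -5.0
  },
  "thresholds": "printed",
  "strict_printed_signs": false,
  "output_dir": "out",
  "log_level": "INFO"
}
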