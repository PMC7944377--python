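{
  "fixtures": {
    "lifetable_synthetic.csv": {
      "intended_use": "default calibration input",
      "note": "SYNTHETIC fallback lifetable: sex-specific Gompertz hazards solved so median survival from 50 is 22.6y (men) / 23.6y (women) and survival to 95 is 0.6% / 1.1% (~99.1% cumulative mortality overall at a 51% female split). Built by selsurv.fixtures.build_synthetic_lifetable; not a transcription of any published table.",
      "provenance": "synthetic-fallback",
      "sha256": "11252599f1f9b5ffc02b60fa30178f97cd1d1f9060aa521a20497c45c91b0876"
    },
    "target_rates_synthetic.csv": {
      "intended_use": "default calibration input",
      "note": "SYNTHETIC fallback male dementia incidence targets per 1000 person-years, rising from 2.0 (65-69) to 80 (90-94), roughly doubling per 5-year band. Built by selsurv.fixtures.build_synthetic_target_rates; a guide for calibration, not data.",
      "provenance": "synthetic-fallback",
      "sha256": "5f1b1648c6458e1eeb424e5030e2dafda24e9b4273663ef0b98887b4d3f39cbb"
    }
  }
}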