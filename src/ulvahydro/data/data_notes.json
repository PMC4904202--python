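{
  "source": "transcription of the published 16-run mixed-level hydrolysis design: process settings, duplicate-summarised outcome measurements (mean, sample sd over 2 replicates), and the corresponding larger-the-better S/N reference values",
  "units": {
    "rhamnose": "ug/ml", "glucose": "ug/ml", "xylose": "ug/ml",
    "glucuronic_acid": "ug/ml", "total": "ug", "yield_pct": "%",
    "density": "kg/m^3", "snr": "dB"
  },
  "replicates_per_run": 2,
  "suspect_cells": [
    {
      "run": 2, "column": "xylose_sd",
      "note": "printed value garbled ('0.125.0'); carried as 0.1, which reproduces the reference S/N 14.80 within 0.01 dB"
    },
    {
      "run": 1, "column": "glucuronic_acid_sd",
      "note": "printed sd 163.6 duplicates the Total sd and is inconsistent with the reference S/N 47.21; carried as printed, excluded from exact S/N checks"
    }
  ]
}
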