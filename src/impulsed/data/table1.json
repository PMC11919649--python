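{
  "gamma": 267500000.0,
  "sequences": [
    {
      "label": "DWI",
      "family": "pgse",
      "delta_ms": 18.0,
      "Delta_ms": 44.0,
      "TE_ms": 62.0,
      "TE_printed_ms": 59.5,
      "b_values_s_mm2": [0, 1000],
      "td_printed_ms": 36.8
    },
    {
      "label": "PGSE",
      "family": "pgse",
      "delta_ms": 15.9,
      "Delta_ms": 119.2,
      "TE_ms": 145.0,
      "b_values_s_mm2": [0, 250, 500, 750, 1000, 1400, 1800],
      "td_printed_ms": 26.7
    },
    {
      "label": "OGSE_17Hz",
      "family": "ogse",
      "delta_ms": 64.2,
      "Delta_ms": 72.7,
      "n_cycles": 1,
      "f_nominal_hz": 17.0,
      "TE_ms": 145.0,
      "b_values_s_mm2": [0, 250, 500, 750, 1000],
      "td_printed_ms": 15.0
    },
    {
      "label": "OGSE_33Hz",
      "family": "ogse",
      "delta_ms": 64.2,
      "Delta_ms": 72.7,
      "n_cycles": 2,
      "f_nominal_hz": 33.0,
      "TE_ms": 145.0,
      "b_values_s_mm2": [0, 100, 200, 300],
      "td_printed_ms": 7.5
    }
  ]
}
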