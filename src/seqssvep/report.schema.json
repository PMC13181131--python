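{
  "type": "object",
  "required": ["provenance", "summary", "conditions"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package_version", "config_hash", "seed", "thresholds"],
      "properties": {
        "package_version": {"type": "string"},
        "numpy_version": {"type": "string"},
        "scipy_version": {"type": "string"},
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "thresholds": {
          "type": "object",
          "required": ["band_hz", "size_threshold_au"],
          "properties": {
            "band_hz": {"type": "array", "items": {"type": "number"}},
            "size_threshold_au": {"type": "number"},
            "rf_snr_gate_au": {"type": "number"},
            "responsiveness_snr": {"type": "number"},
            "waveform_boundary_ms": {"type": "number"},
            "isi_qc_fraction": {"type": "number"}
          }
        }
      }
    },
    "summary": {
      "type": "object",
      "required": ["n_conditions", "n_sequential_conditions",
                   "distinct_repeat_frequencies_hz",
                   "n_distinct_repeat_frequencies"],
      "properties": {
        "n_conditions": {"type": "integer"},
        "n_sequential_conditions": {"type": "integer"},
        "distinct_repeat_frequencies_hz": {
          "type": "array", "items": {"type": "number"}
        },
        "n_distinct_repeat_frequencies": {"type": "integer"}
      }
    },
    "conditions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "kind", "sequential", "hf_amplitude_au",
                     "hf_size_channels", "hf_size_um"],
        "properties": {
          "name": {"type": "string"},
          "kind": {"type": "string"},
          "sequential": {"type": "boolean"},
          "n_sections": {"type": "integer"},
          "refresh_hz": {"type": "number"},
          "repeat_frequency_hz": {"type": ["number", "null"]},
          "hf_amplitude_au": {"type": "number"},
          "hf_size_channels": {"type": "integer"},
          "hf_size_um": {"type": "number"},
          "large_spread": {"type": "boolean"},
          "mean_ppc": {"type": ["number", "null"]},
          "n_units_with_ppc": {"type": "integer"}
        }
      }
    }
  }
}
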