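{
  "type": "object",
  "required": ["seed", "config_hash", "versions", "stages"],
  "properties": {
    "seed": {"type": "integer"},
    "config_hash": {"type": "string"},
    "versions": {"type": "object"},
    "stages": {
      "type": "object",
      "properties": {
        "synthetic": {
          "type": "object",
          "required": ["n_bins", "bin_size", "chromosomes"],
          "properties": {
            "n_bins": {"type": "integer"},
            "bin_size": {"type": "integer"},
            "chromosomes": {"type": "array"}
          }
        },
        "domains": {
          "type": "object",
          "required": ["counts", "summary"],
          "properties": {"counts": {"type": "object"}, "summary": {"type": "array"}}
        },
        "clustering": {
          "type": "object",
          "required": ["autosomes", "X"],
          "properties": {"autosomes": {"type": "array"}, "X": {"type": "array"}}
        },
        "fit": {
          "type": "object",
          "required": ["coefficients", "r_squared", "sse", "n_bins"],
          "properties": {
            "coefficients": {"type": "object"},
            "r_squared": {"type": "number"},
            "sse": {"type": "number"},
            "n_bins": {"type": "integer"}
          }
        },
        "integration": {
          "type": "object",
          "required": ["spearman", "quintile_fractions", "overlap", "n_de"],
          "properties": {
            "spearman": {"type": "number"},
            "pearson": {"type": "number"},
            "p_spearman": {"type": "number"},
            "quintile_fractions": {"type": "object"},
            "overlap": {"type": "object"},
            "n_de": {"type": "integer"}
          }
        },
        "ploidy": {
          "type": "object",
          "required": ["slope", "intercept", "relative_content"],
          "properties": {
            "slope": {"type": "number"},
            "intercept": {"type": "number"},
            "relative_content": {"type": "array"}
          }
        }
      }
    }
  }
}
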