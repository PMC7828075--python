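{
  "type": "object",
  "required": ["config_hash", "master_seed", "n_subjects", "metabolites",
               "subject_fits", "peb", "model_comparison"],
  "properties": {
    "config_hash": {"type": "string"},
    "master_seed": {"type": "integer"},
    "n_subjects": {"type": "integer"},
    "metabolites": {"type": "object"},
    "subject_fits": {"type": "object"},
    "peb": {
      "type": "object",
      "required": ["beta", "free_energy", "effects"],
      "properties": {
        "beta": {"type": "object"},
        "free_energy": {"type": "number"},
        "effects": {"type": "object"}
      }
    },
    "model_comparison": {
      "type": "object",
      "required": ["models", "free_energy", "posterior_prob"],
      "properties": {
        "models": {"type": "array"},
        "free_energy": {"type": "array"},
        "posterior_prob": {"type": "array"}
      }
    }
  }
}
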