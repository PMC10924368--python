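{
  "version": 1,
  "model_kind": "psyco",
  "factors": [
    {"name": "impaired_communication", "domain": "ordinal4", "related_bpsd": [0, 2]},
    {"name": "somatic_diseases", "domain": "ordinal4", "related_bpsd": [0]},
    {"name": "mmse", "domain": "mmse", "related_bpsd": [0, 1, 2]},
    {"name": "weight_loss", "domain": "ordinal4", "related_bpsd": [1]},
    {"name": "loss_of_insight", "domain": "ordinal4", "related_bpsd": [1, 2]},
    {"name": "stressful_events", "domain": "ordinal4", "related_bpsd": [2]},
    {"name": "self_esteem", "domain": "ordinal4", "related_bpsd": [2]},
    {"name": "anxiety", "domain": "ordinal4", "related_bpsd": [2]}
  ],
  "entries": {
    "impaired_communication": {
      "0": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]}
    },
    "somatic_diseases": {
      "0": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]}
    },
    "mmse": {
      "0": {"high": [0, 22], "mild": [22, 27], "none": [27, 30]},
      "1": {"high": [0, 22], "mild": [22, 27], "none": [27, 30]},
      "2": {"high": [0, 22], "mild": [22, 27], "none": [27, 30]}
    },
    "weight_loss": {
      "0": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "1": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]},
      "2": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]}
    },
    "loss_of_insight": {
      "0": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "1": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]},
      "2": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]}
    },
    "stressful_events": {
      "0": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]}
    },
    "self_esteem": {
      "0": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [2, 3], "mild": [1, 3], "none": [0, 1]}
    },
    "anxiety": {
      "0": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [1, 3], "mild": [2, 3], "none": [0, 1]}
    }
  }
}
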