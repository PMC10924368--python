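{
  "version": 1,
  "model_kind": "bephyen",
  "factors": [
    {"name": "time", "domain": "time6", "related_bpsd": [0, 2]},
    {"name": "environmental_change", "domain": "ordinal4", "related_bpsd": [0, 2]},
    {"name": "walking_speed", "domain": "ordinal4", "related_bpsd": [0, 1, 2]},
    {"name": "hrv", "domain": "ordinal4", "related_bpsd": [0, 2]},
    {"name": "daytime_activity", "domain": "ordinal4", "related_bpsd": [1]},
    {"name": "wandering", "domain": "binary", "related_bpsd": [2]}
  ],
  "entries": {
    "time": {
      "0": {"high": [2, 2], "mild": [0, 2], "none": [0, 5]},
      "1": {"high": [0, 5], "mild": [0, 5], "none": [0, 5]},
      "2": {"high": [3, 3], "mild": [2, 4], "none": [0, 5]}
    },
    "environmental_change": {
      "0": {"high": [2, 3], "mild": [1, 3], "none": [0, 2]},
      "1": {"high": [0, 2], "mild": [0, 2], "none": [0, 2]},
      "2": {"high": [2, 3], "mild": [1, 3], "none": [0, 2]}
    },
    "walking_speed": {
      "0": {"high": [0, 0], "mild": [0, 2], "none": [2, 3]},
      "1": {"high": [0, 0], "mild": [0, 2], "none": [2, 3]},
      "2": {"high": [0, 0], "mild": [0, 2], "none": [2, 3]}
    },
    "hrv": {
      "0": {"high": [3, 3], "mild": [2, 3], "none": [2, 2]},
      "1": {"high": [2, 2], "mild": [2, 2], "none": [2, 2]},
      "2": {"high": [0, 1], "mild": [0, 2], "none": [2, 2]}
    },
    "daytime_activity": {
      "0": {"high": [1, 3], "mild": [1, 3], "none": [1, 3]},
      "1": {"high": [0, 2], "mild": [1, 2], "none": [1, 3]},
      "2": {"high": [1, 3], "mild": [1, 3], "none": [1, 3]}
    },
    "wandering": {
      "0": {"high": [0, 0], "mild": [0, 0], "none": [0, 0]},
      "1": {"high": [0, 0], "mild": [0, 0], "none": [0, 0]},
      "2": {"high": [0, 1], "mild": [0, 1], "none": [0, 0]}
    }
  }
}
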