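{
  "description": "Fitted two-population piecewise demographic model for the northern (NWR) and southern (SWR) white rhinoceros, consumed as constants. Sizes are diploid effective sizes; times are in generations before present.",
  "N_anc": 14024,
  "split_time_generations": 5864,
  "recent_change_generations": 37,
  "final_epoch_generations": 28,
  "migration_Nm": 0.031,
  "generation_time_years": {"tunstall": 8.0, "moodley": 25.5},
  "epochs": {
    "NWR": [
      {"name": "NWR1", "start_size": 13456, "end_size": 1042, "dynamics": "linear", "from_generations": 5864, "to_generations": 37},
      {"name": "NWR2", "start_size": 192, "end_size": 192, "dynamics": "instantaneous", "from_generations": 37, "to_generations": 28},
      {"name": "NWR3", "start_size": 474, "end_size": 474, "dynamics": "instantaneous", "from_generations": 28, "to_generations": 0}
    ],
    "SWR": [
      {"name": "SWR1", "start_size": 4945, "end_size": 1533, "dynamics": "linear", "from_generations": 5864, "to_generations": 37},
      {"name": "SWR2", "start_size": 349, "end_size": 349, "dynamics": "instantaneous", "from_generations": 37, "to_generations": 28},
      {"name": "SWR3", "start_size": 140, "end_size": 140, "dynamics": "instantaneous", "from_generations": 28, "to_generations": 0}
    ]
  }
}
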