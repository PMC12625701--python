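{
 "element": "C",
 "nodes": [
  {
   "process_id": "aerobic_carbon_fixation",
   "x": 0.0,
   "y": 1.0
  },
  {
   "process_id": "anaerobic_carbon_fixation",
   "x": 0.782,
   "y": 0.623
  },
  {
   "process_id": "aerobic_respiration",
   "x": 0.975,
   "y": -0.223
  },
  {
   "process_id": "fermentation",
   "x": 0.434,
   "y": -0.901
  },
  {
   "process_id": "methanogenesis",
   "x": -0.434,
   "y": -0.901
  },
  {
   "process_id": "methane_oxidation",
   "x": -0.975,
   "y": -0.223
  },
  {
   "process_id": "co_oxidation",
   "x": -0.782,
   "y": 0.623
  }
 ],
 "arrows": [
  [
   "aerobic_carbon_fixation",
   "aerobic_respiration"
  ],
  [
   "aerobic_respiration",
   "fermentation"
  ],
  [
   "fermentation",
   "methanogenesis"
  ],
  [
   "methanogenesis",
   "methane_oxidation"
  ],
  [
   "methane_oxidation",
   "anaerobic_carbon_fixation"
  ],
  [
   "anaerobic_carbon_fixation",
   "co_oxidation"
  ],
  [
   "co_oxidation",
   "aerobic_carbon_fixation"
  ]
 ]
}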