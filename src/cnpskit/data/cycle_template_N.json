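{
 "element": "N",
 "nodes": [
  {
   "process_id": "nitrogen_fixation",
   "x": 0.0,
   "y": 1.0
  },
  {
   "process_id": "ammonia_oxidation",
   "x": 0.342,
   "y": 0.94
  },
  {
   "process_id": "hydroxylamine_oxidation",
   "x": 0.643,
   "y": 0.766
  },
  {
   "process_id": "nitrite_oxidation",
   "x": 0.866,
   "y": 0.5
  },
  {
   "process_id": "dissimilatory_nitrate_reduction",
   "x": 0.985,
   "y": 0.174
  },
  {
   "process_id": "denitrification_nitrite_reduction",
   "x": 0.985,
   "y": -0.174
  },
  {
   "process_id": "nitric_oxide_reduction",
   "x": 0.866,
   "y": -0.5
  },
  {
   "process_id": "nitrous_oxide_reduction",
   "x": 0.643,
   "y": -0.766
  },
  {
   "process_id": "dnra",
   "x": 0.342,
   "y": -0.94
  },
  {
   "process_id": "assimilatory_nitrate_reduction",
   "x": 0.0,
   "y": -1.0
  },
  {
   "process_id": "assimilatory_nitrite_reduction",
   "x": -0.342,
   "y": -0.94
  },
  {
   "process_id": "anammox",
   "x": -0.643,
   "y": -0.766
  },
  {
   "process_id": "ammonium_uptake",
   "x": -0.866,
   "y": -0.5
  },
  {
   "process_id": "nitrate_uptake",
   "x": -0.985,
   "y": -0.174
  },
  {
   "process_id": "nitrite_uptake",
   "x": -0.985,
   "y": 0.174
  },
  {
   "process_id": "ureolysis",
   "x": -0.866,
   "y": 0.5
  },
  {
   "process_id": "nitrogen_assimilation",
   "x": -0.643,
   "y": 0.766
  },
  {
   "process_id": "organic_nitrogen_mineralization",
   "x": -0.342,
   "y": 0.94
  }
 ],
 "arrows": [
  [
   "nitrogen_fixation",
   "ammonium_uptake"
  ],
  [
   "ammonium_uptake",
   "nitrogen_assimilation"
  ],
  [
   "ammonia_oxidation",
   "hydroxylamine_oxidation"
  ],
  [
   "hydroxylamine_oxidation",
   "nitrite_oxidation"
  ],
  [
   "nitrite_oxidation",
   "dissimilatory_nitrate_reduction"
  ],
  [
   "dissimilatory_nitrate_reduction",
   "denitrification_nitrite_reduction"
  ],
  [
   "denitrification_nitrite_reduction",
   "nitric_oxide_reduction"
  ],
  [
   "nitric_oxide_reduction",
   "nitrous_oxide_reduction"
  ],
  [
   "nitrous_oxide_reduction",
   "nitrogen_fixation"
  ],
  [
   "dissimilatory_nitrate_reduction",
   "dnra"
  ],
  [
   "dnra",
   "ammonium_uptake"
  ],
  [
   "nitrate_uptake",
   "assimilatory_nitrate_reduction"
  ],
  [
   "assimilatory_nitrate_reduction",
   "assimilatory_nitrite_reduction"
  ],
  [
   "assimilatory_nitrite_reduction",
   "nitrogen_assimilation"
  ],
  [
   "nitrite_uptake",
   "assimilatory_nitrite_reduction"
  ],
  [
   "ammonia_oxidation",
   "anammox"
  ],
  [
   "anammox",
   "nitrogen_fixation"
  ],
  [
   "ureolysis",
   "ammonium_uptake"
  ],
  [
   "organic_nitrogen_mineralization",
   "ammonium_uptake"
  ]
 ]
}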