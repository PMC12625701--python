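{
 "element": "S",
 "nodes": [
  {
   "process_id": "assimilatory_sulfate_reduction",
   "x": 0.0,
   "y": 1.0
  },
  {
   "process_id": "aps_reduction",
   "x": 0.407,
   "y": 0.914
  },
  {
   "process_id": "dissimilatory_sulfite_reduction",
   "x": 0.743,
   "y": 0.669
  },
  {
   "process_id": "sulfide_oxidation",
   "x": 0.951,
   "y": 0.309
  },
  {
   "process_id": "thiosulfate_oxidation_sox",
   "x": 0.995,
   "y": -0.105
  },
  {
   "process_id": "sulfite_oxidation",
   "x": 0.866,
   "y": -0.5
  },
  {
   "process_id": "thiosulfate_disproportionation",
   "x": 0.588,
   "y": -0.809
  },
  {
   "process_id": "sulfur_reduction",
   "x": 0.208,
   "y": -0.978
  },
  {
   "process_id": "sulfur_oxidation",
   "x": -0.208,
   "y": -0.978
  },
  {
   "process_id": "tetrathionate_reduction",
   "x": -0.588,
   "y": -0.809
  },
  {
   "process_id": "tetrathionate_oxidation",
   "x": -0.866,
   "y": -0.5
  },
  {
   "process_id": "organic_sulfur_mineralization",
   "x": -0.995,
   "y": -0.105
  },
  {
   "process_id": "dmsp_degradation",
   "x": -0.951,
   "y": 0.309
  },
  {
   "process_id": "dmso_reduction",
   "x": -0.743,
   "y": 0.669
  },
  {
   "process_id": "taurine_utilization",
   "x": -0.407,
   "y": 0.914
  }
 ],
 "arrows": [
  [
   "assimilatory_sulfate_reduction",
   "organic_sulfur_mineralization"
  ],
  [
   "aps_reduction",
   "dissimilatory_sulfite_reduction"
  ],
  [
   "dissimilatory_sulfite_reduction",
   "sulfide_oxidation"
  ],
  [
   "sulfide_oxidation",
   "sulfur_oxidation"
  ],
  [
   "sulfur_oxidation",
   "sulfite_oxidation"
  ],
  [
   "sulfite_oxidation",
   "aps_reduction"
  ],
  [
   "thiosulfate_oxidation_sox",
   "sulfite_oxidation"
  ],
  [
   "thiosulfate_disproportionation",
   "sulfide_oxidation"
  ],
  [
   "tetrathionate_oxidation",
   "tetrathionate_reduction"
  ],
  [
   "tetrathionate_reduction",
   "thiosulfate_disproportionation"
  ],
  [
   "sulfur_reduction",
   "sulfide_oxidation"
  ],
  [
   "dmsp_degradation",
   "dmso_reduction"
  ],
  [
   "dmso_reduction",
   "sulfide_oxidation"
  ],
  [
   "organic_sulfur_mineralization",
   "sulfite_oxidation"
  ],
  [
   "taurine_utilization",
   "sulfite_oxidation"
  ]
 ]
}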