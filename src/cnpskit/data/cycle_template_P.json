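{
 "element": "P",
 "nodes": [
  {
   "process_id": "organic_p_mineralization",
   "x": 0.0,
   "y": 1.0
  },
  {
   "process_id": "inorganic_p_solubilization",
   "x": 0.0,
   "y": -1.0
  }
 ],
 "arrows": [
  [
   "organic_p_mineralization",
   "inorganic_p_solubilization"
  ],
  [
   "inorganic_p_solubilization",
   "organic_p_mineralization"
  ]
 ]
}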