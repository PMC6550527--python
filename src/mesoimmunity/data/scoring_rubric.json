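[
  {"score": 0, "description": "No spots of lysis or plaques"},
  {"score": 1, "description": "Spots of lysis at highest 1-2 titers but no plaques"},
  {"score": 2, "description": "Superinfecting phage produces plaques with an efficiency of plating of less than ~10^-3-10^-4 or spots of lysis at highest 3 titers but no plaques"},
  {"score": 3, "description": "Superinfecting phage produces plaques with an efficiency of plating from 10^-1-10^-3 or spots of lysis at highest 4-5 titers but no plaques"},
  {"score": 4, "description": "Superinfecting phage produces plaques with an efficiency of plating of 1, but spots/plaques exhibit increased turbidity or reduced size compared to infection of the naive host"},
  {"score": 5, "description": "Superinfecting phage produces plaques with an efficiency of plating of 1, and there is no phenotypic difference compared to infection of the naive host"},
  {"score": 6, "description": "Superinfecting phage produces plaques with an efficiency of plating of 1, but spots/plaques exhibit reduced turbidity or increased size compared to infection of the naive host"}
]
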