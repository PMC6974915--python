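{
  "name": "corolla415",
  "description": "Five-petal corolla landmark template: 25 primary + 390 secondary = 415 landmarks. Each lobe-lobe rim carries 7 ordered entries whose distal entry is the primary-I lobe-intersection landmark.",
  "petal_cycle": ["ventral", "lateral-1", "dorsal-1", "dorsal-2", "lateral-2"],
  "dorsal_petals": ["dorsal-1", "dorsal-2"],
  "petal_layout": [
    {"series": "point", "role": "primary-II", "region": "tube"},
    {"series": "tube_midrib", "count": 25, "region": "tube"},
    {"series": "point", "role": "primary-IV", "region": "tube"},
    {"series": "lobe_midrib", "count": 7, "region": "lobe"},
    {"series": "point", "role": "primary-III", "region": "lobe"},
    {"series": "lobe_contour", "count": 15, "region": "lobe"}
  ],
  "rim_layout": [
    {"series": "point", "role": "primary-V", "region": "tube"},
    {"series": "tube_tube_rim", "count": 25, "region": "tube"},
    {"series": "lobe_lobe_rim", "count": 7, "region": "lobe", "distal_role": "primary-I"}
  ]
}
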