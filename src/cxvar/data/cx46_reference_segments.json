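{
  "description": "Domain segmentation of the sheep Cx46 gap-junction reference structure. Boundaries are approximate resolved-range/topology boundaries in sheep Cx46 numbering; override with your own config for other references.",
  "segments": [
    {"label": "NT", "start": 1, "end": 22},
    {"label": "M1", "start": 23, "end": 45},
    {"label": "E1", "start": 46, "end": 75},
    {"label": "M2", "start": 76, "end": 96},
    {"label": "CL", "start": 97, "end": 136},
    {"label": "M3", "start": 137, "end": 159},
    {"label": "E2", "start": 160, "end": 191},
    {"label": "M4", "start": 192, "end": 220},
    {"label": "CT", "start": 221, "end": 440}
  ]
}
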