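{
  "_comment": "Default immunophenoscore configuration. Determinant weights follow the four-category construction: effector cells and MHC molecules +1, suppressor cells and inhibitory checkpoints -1. Entries flagged unlisted_default are package defaults taken from the original immunophenogram publication's gene families because the categories are stated as having ten members without full enumeration here; override via a custom config file. Cell-type metagene gene lists are likewise package defaults and fully overridable.",
  "categories": {
    "effector_cells": [
      {"name": "acCD4", "weight": 1, "genes": ["CD4", "CD69", "CD40LG", "IL2", "TNF"], "unlisted_default": true},
      {"name": "acCD8", "weight": 1, "genes": ["CD8A", "GZMA", "GZMB", "PRF1", "IFNG"], "unlisted_default": true},
      {"name": "TemCD4", "weight": 1, "genes": ["IL7R", "KLRB1", "CCR6", "CD28"], "unlisted_default": true},
      {"name": "TemCD8", "weight": 1, "genes": ["EOMES", "GZMK", "KLRG1", "CXCR3"], "unlisted_default": true}
    ],
    "suppressor_cells": [
      {"name": "Tregs", "weight": -1, "genes": ["FOXP3", "IL2RA", "IKZF2", "TNFRSF18"], "unlisted_default": true},
      {"name": "MDSCs", "weight": -1, "genes": ["CD14", "ITGAM", "S100A8", "S100A9"], "unlisted_default": true}
    ],
    "mhc": [
      {"name": "HLA-A", "weight": 1, "genes": ["HLA-A"]},
      {"name": "HLA-B", "weight": 1, "genes": ["HLA-B"]},
      {"name": "HLA-C", "weight": 1, "genes": ["HLA-C"]},
      {"name": "HLA-DPA1", "weight": 1, "genes": ["HLA-DPA1"]},
      {"name": "HLA-DPB1", "weight": 1, "genes": ["HLA-DPB1"]},
      {"name": "HLA-E", "weight": 1, "genes": ["HLA-E"], "unlisted_default": true},
      {"name": "HLA-F", "weight": 1, "genes": ["HLA-F"], "unlisted_default": true},
      {"name": "B2M", "weight": 1, "genes": ["B2M"], "unlisted_default": true},
      {"name": "TAP1", "weight": 1, "genes": ["TAP1"], "unlisted_default": true},
      {"name": "TAP2", "weight": 1, "genes": ["TAP2"], "unlisted_default": true}
    ],
    "checkpoints": [
      {"name": "ICOS", "weight": 1, "genes": ["ICOS"]},
      {"name": "CD27", "weight": 1, "genes": ["CD27"]},
      {"name": "PD-1", "weight": -1, "genes": ["PDCD1"]},
      {"name": "CTLA4", "weight": -1, "genes": ["CTLA4"]},
      {"name": "LAG3", "weight": -1, "genes": ["LAG3"]},
      {"name": "TIGIT", "weight": -1, "genes": ["TIGIT"]},
      {"name": "TIM3", "weight": -1, "genes": ["HAVCR2"]},
      {"name": "PD-L1", "weight": -1, "genes": ["CD274"]},
      {"name": "PD-L2", "weight": -1, "genes": ["PDCD1LG2"]},
      {"name": "IDO1", "weight": -1, "genes": ["IDO1"], "unlisted_default": true}
    ]
  }
}
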