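{
 "reference": "PER3",
 "groups": {
  "in_phase": [
   {
    "gene": "CIPC",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "DBP",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "HLF",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "KLF9",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "MTHFD1L",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PFKFB3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PIK3IP1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TEF",
    "rs": null,
    "dphi_h": null
   }
  ],
  "anti_phase": [
   {
    "gene": "ARNTL",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NPAS2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PDIA6",
    "rs": null,
    "dphi_h": null
   }
  ],
  "quadrature": [
   {
    "gene": "RORC",
    "rs": null,
    "dphi_h": null
   }
  ]
 },
 "thresholds": null,
 "dataset_label": [
  "mammalian_lung_curated"
 ]
}
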