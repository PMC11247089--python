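{
 "reference": "PER3",
 "groups": {
  "in_phase": [
   {
    "gene": "ALAS1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ARHGEF26",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "BHLHE40",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "BHLHE41",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CCBE1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CEP85",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CIPC",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CLDN12",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "COQ10B",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CPEB1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CYP3A13",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "DBP",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "FAM76A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "FBXO3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GLUL",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GPR155",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GRAMD2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "HDAC11",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "HERPUD1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "HIF3A",
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
    "gene": "LPIN2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "MACO1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "MTHFD1L",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NANOS1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NR1D2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "OTUD1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PER1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PER2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PFKFB3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PI4K2B",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PIK3IP1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "POR",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RAC3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RERE",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "REV1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RNASEH2B",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SEPSECS",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SIK1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SLC25A33",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SLC46A3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SOCS2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SORD",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "STK35",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TEF",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TEX11",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TRIM24",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TSC22D3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TSPAN4",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "USP2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "WEE1",
    "rs": null,
    "dphi_h": null
   }
  ],
  "anti_phase": [
   {
    "gene": "ACACA",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ADAM17",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ADM",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ADRA1A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "AHCYL2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "AKR1E1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ALDH3A1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ARNTL",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "AVPR1A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "BIK",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CALR",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CCNJL",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CDKN1A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "CXCL5",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "DAPK1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "DPY19L3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "DTX4",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "ELN",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "FAM124B",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "FAM210B",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "FOXS1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GDPD2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GLIPR2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GLRX",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "GPRIN3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "HEATR1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "IKZF4",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "INSYN1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "LEO1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "LMTK2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "LPCAT3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "MED24",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NECTIN1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NFIL3",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "NPAS2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "P2RX5",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PDIA6",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PFKP",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "PNRC1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RAB27A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RASL11A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RBM45",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SCD1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SDF2L1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SLC43A2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SNX30",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SPAAR",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "SPON2",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TMEM140",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TMEM171",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TMEM45A",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "TOR4A",
    "rs": null,
    "dphi_h": null
   }
  ],
  "quadrature": [
   {
    "gene": "CRY1",
    "rs": null,
    "dphi_h": null
   },
   {
    "gene": "RORC",
    "rs": null,
    "dphi_h": null
   }
  ]
 },
 "thresholds": null,
 "dataset_label": [
  "mouse_lung_curated"
 ]
}
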