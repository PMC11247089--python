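{
 "hughey": [
  "ARNTL",
  "CRY1",
  "DBP",
  "FMO2",
  "LONRF3",
  "NPAS2",
  "NR1D1",
  "NR1D2",
  "PER1",
  "PER2",
  "PER3",
  "TEF",
  "TSC22D3"
 ],
 "wittenbrink": [
  "CRISPLD2",
  "CRY1",
  "ELMO2",
  "FKBP4",
  "HSPH1",
  "KLF9",
  "LGALS3",
  "NR1D1",
  "NR1D2",
  "PER1",
  "PER2",
  "PER3"
 ],
 "talamanca": [
  "ARNTL",
  "CIART",
  "CRY1",
  "CRY2",
  "DBP",
  "NPAS2",
  "NR1D1",
  "NR1D2",
  "PER1",
  "PER2",
  "PER3",
  "TEF"
 ],
 "shilts": [
  "ARNTL",
  "CLOCK",
  "CRY1",
  "CRY2",
  "DBP",
  "NPAS2",
  "NR1D1",
  "NR1D2",
  "PER1",
  "PER2",
  "PER3",
  "TEF"
 ],
 "wu": [
  "ARNTL",
  "CIART",
  "CLOCK",
  "CRY1",
  "CRY2",
  "DBP",
  "NPAS2",
  "NR1D1",
  "PER1",
  "PER2"
 ]
}
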