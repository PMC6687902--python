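{
 "grid": {
  "start": 0.0,
  "stop": 0.25,
  "rate": 600.0
 },
 "condition_labels": [
  "early",
  "late"
 ],
 "channel_labels": [
  "ch0",
  "ch1",
  "ch2",
  "ch3"
 ],
 "design": [
  0.0,
  1.0
 ],
 "files": [
  "erp_00_early.csv",
  "erp_01_late.csv"
 ]
}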