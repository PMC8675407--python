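[
  "name",
  "birth",
  "date",
  "address",
  "institution",
  "operator",
  "patient",
  "physician",
  "station",
  "device.?serial",
  "accession",
  "comment"
]
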