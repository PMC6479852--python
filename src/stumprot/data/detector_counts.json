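{
  "description": "Reference stump-detection outcome on a held-out test fold of 201 images: detections matched to labeled stumps at sq >= 0.5.",
  "tp": 162,
  "fp": 9,
  "fn": 39,
  "printed_precision": "95%",
  "printed_recall": "80%"
}
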