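{
  "description": "Reference confusion-matrix counts from the field study this pipeline reimplements. Rows are true classes, columns predicted classes. 'printed_accuracy' carries the per-class accuracy strings as originally published; entries flagged in 'printed_inconsistent' do not follow from their own count row under any standard rendering (publication typos) and the arithmetically correct truncated value is given in 'recomputed_accuracy'.",
  "class_orders": {
    "2": ["NO_ROT", "ROT"],
    "3": ["NO_ROT", "ROT_LT_50", "ROT_GE_50"]
  },
  "tables": {
    "1a": {"approach": "BS", "mode": "manual", "n_classes": 2,
           "counts": [[65, 38], [25, 73]],
           "printed_accuracy": ["63.0%", "74.4%"],
           "printed_inconsistent": [true, false],
           "recomputed_accuracy": ["63.1%", "74.4%"]},
    "1b": {"approach": "VS", "mode": "manual", "n_classes": 2,
           "counts": [[89, 14], [29, 70]],
           "printed_accuracy": ["86.4%", "71.4%"],
           "printed_inconsistent": [false, true],
           "recomputed_accuracy": ["86.4%", "70.7%"]},
    "1c": {"approach": "VF", "mode": "manual", "n_classes": 2,
           "counts": [[94, 9], [9, 89]],
           "printed_accuracy": ["91.2%", "90.8%"],
           "printed_inconsistent": [false, false],
           "recomputed_accuracy": ["91.2%", "90.8%"]},
    "2a": {"approach": "BS", "mode": "manual", "n_classes": 3,
           "counts": [[61, 7, 35], [7, 26, 28], [8, 4, 25]],
           "printed_accuracy": ["59.2%", "42.6%", "67.5%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["59.2%", "42.6%", "67.5%"]},
    "2b": {"approach": "VS", "mode": "manual", "n_classes": 3,
           "counts": [[67, 16, 20], [5, 47, 9], [5, 8, 24]],
           "printed_accuracy": ["65.0%", "77.0%", "64.8%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["65.0%", "77.0%", "64.8%"]},
    "2c": {"approach": "VF", "mode": "manual", "n_classes": 3,
           "counts": [[84, 12, 7], [6, 51, 4], [3, 5, 29]],
           "printed_accuracy": ["81.5%", "83.6%", "78.3%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["81.5%", "83.6%", "78.3%"]},
    "3a": {"approach": "BS", "mode": "detector_tp", "n_classes": 2,
           "counts": [[19, 54], [27, 62]],
           "printed_accuracy": ["26.0%", "69.6%"],
           "printed_inconsistent": [false, false],
           "recomputed_accuracy": ["26.0%", "69.6%"]},
    "3b": {"approach": "VS", "mode": "detector_tp", "n_classes": 2,
           "counts": [[36, 37], [9, 80]],
           "printed_accuracy": ["49.3%", "89.8%"],
           "printed_inconsistent": [false, false],
           "recomputed_accuracy": ["49.3%", "89.8%"]},
    "3c": {"approach": "VF", "mode": "detector_tp", "n_classes": 2,
           "counts": [[61, 12], [20, 69]],
           "printed_accuracy": ["83.5%", "77.5%"],
           "printed_inconsistent": [false, false],
           "recomputed_accuracy": ["83.5%", "77.5%"]},
    "4a": {"approach": "BS", "mode": "detector_tp", "n_classes": 3,
           "counts": [[12, 9, 52], [12, 15, 31], [2, 5, 24]],
           "printed_accuracy": ["16.4%", "25.8%", "77.4%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["16.4%", "25.8%", "77.4%"]},
    "4b": {"approach": "VS", "mode": "detector_tp", "n_classes": 3,
           "counts": [[32, 24, 17], [14, 33, 11], [2, 14, 15]],
           "printed_accuracy": ["43.8%", "56.8%", "48.3%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["43.8%", "56.8%", "48.3%"]},
    "4c": {"approach": "VF", "mode": "detector_tp", "n_classes": 3,
           "counts": [[58, 11, 4], [4, 42, 12], [1, 7, 23]],
           "printed_accuracy": ["79.4%", "72.4%", "74.1%"],
           "printed_inconsistent": [false, false, false],
           "recomputed_accuracy": ["79.4%", "72.4%", "74.1%"]}
  }
}
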