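{
  "version": "1.0",
  "provenance": "Occipital + bilateral temporal 8-source/8-detector montage with one 8-mm short channel per source. Source/detector label pairs reconstructed from the published probe figures; only ROI membership, the one-SC-per-source rule, and the limited-subset sources (C5, POz, CP6) enter any computation.",
  "wavelengths_nm": [760, 850],
  "channels": [
    {"id": 1,  "source": "C5",  "detector": "FT7", "roi": "left_temporal",  "distance_mm": 32.0},
    {"id": 2,  "source": "C5",  "detector": "TP7", "roi": "left_temporal",  "distance_mm": 31.0},
    {"id": 3,  "source": "T7",  "detector": "FT7", "roi": "left_temporal",  "distance_mm": 33.0},
    {"id": 4,  "source": "T7",  "detector": "TP7", "roi": "left_temporal",  "distance_mm": 30.0},
    {"id": 5,  "source": "POz", "detector": "PO3", "roi": "occipital",      "distance_mm": 30.0},
    {"id": 6,  "source": "POz", "detector": "PO4", "roi": "occipital",      "distance_mm": 30.0},
    {"id": 7,  "source": "O1",  "detector": "PO3", "roi": "occipital",      "distance_mm": 29.0},
    {"id": 8,  "source": "O1",  "detector": "PO7", "roi": "occipital",      "distance_mm": 31.0},
    {"id": 9,  "source": "Oz",  "detector": "PO3", "roi": "occipital",      "distance_mm": 33.0},
    {"id": 10, "source": "O2",  "detector": "PO4", "roi": "occipital",      "distance_mm": 29.0},
    {"id": 11, "source": "O2",  "detector": "PO8", "roi": "occipital",      "distance_mm": 31.0},
    {"id": 12, "source": "CP6", "detector": "FT8", "roi": "right_temporal", "distance_mm": 32.0},
    {"id": 13, "source": "CP6", "detector": "TP8", "roi": "right_temporal", "distance_mm": 31.0},
    {"id": 14, "source": "T8",  "detector": "FT8", "roi": "right_temporal", "distance_mm": 33.0},
    {"id": 15, "source": "T8",  "detector": "TP8", "roi": "right_temporal", "distance_mm": 30.0},
    {"id": 16, "source": "CP6", "detector": "PO8", "roi": "excluded",       "distance_mm": 38.0}
  ],
  "short_channels": [
    {"id": 1, "source": "C5",  "distance_mm": 8.0},
    {"id": 2, "source": "T7",  "distance_mm": 8.0},
    {"id": 3, "source": "POz", "distance_mm": 8.0},
    {"id": 4, "source": "O1",  "distance_mm": 8.0},
    {"id": 5, "source": "Oz",  "distance_mm": 8.0},
    {"id": 6, "source": "O2",  "distance_mm": 8.0},
    {"id": 7, "source": "CP6", "distance_mm": 8.0},
    {"id": 8, "source": "T8",  "distance_mm": 8.0}
  ],
  "limited_subset": {"left_temporal": "C5", "occipital": "POz", "right_temporal": "CP6"},
  "layout_2d": {
    "C5":  [-0.85, 0.30], "T7":  [-0.95, 0.10], "FT7": [-0.90, 0.45], "TP7": [-0.92, -0.05],
    "POz": [0.00, -0.70], "O1":  [-0.25, -0.90], "Oz":  [0.00, -0.95], "O2":  [0.25, -0.90],
    "PO3": [-0.15, -0.78], "PO4": [0.15, -0.78], "PO7": [-0.40, -0.80], "PO8": [0.40, -0.80],
    "CP6": [0.85, 0.10], "T8":  [0.95, 0.10], "FT8": [0.90, 0.45], "TP8": [0.92, -0.05]
  }
}
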