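{
  "schema": "nodulequant.published_tables.v1",
  "cohort": {
    "total": 375,
    "subtype_counts": {
      "AIS": 41,
      "MIA": 51,
      "lepidic": 49,
      "acinar": 176,
      "papillary": 32,
      "micropapillary": 5,
      "solid": 11,
      "variants": 10
    },
    "noninvasive_subtypes": ["AIS", "MIA"]
  },
  "appearance_hu": {
    "comment": "mean CT value (HU) per visual appearance class, whole class and by enhancement stratum: [n, mean, sd]",
    "pGGO": {
      "whole": [58, -553.38, 101.1],
      "enhanced": [33, -533.36, 103.79],
      "non_enhanced": [25, -579.8, 92.92],
      "printed_t": -1.764,
      "printed_p": 0.083
    },
    "PSN": {
      "whole": [159, -364.87, 129.61],
      "enhanced": [94, -379.49, 128.8],
      "non_enhanced": [65, -343.74, 128.82],
      "printed_t": 1.721,
      "printed_p": 0.087
    },
    "SN": {
      "whole": [158, -104.24, 93.05],
      "enhanced": [55, -95.67, 94.3],
      "non_enhanced": [103, -108.82, 92.51],
      "printed_t": -0.845,
      "printed_p": 0.399
    }
  },
  "invasiveness": {
    "comment": "invasive vs non-invasive adenocarcinoma; contingency rows are [invasive, non-invasive] counts, summaries are [n, mean, sd] per group",
    "n_invasive": 283,
    "n_noninvasive": 92,
    "contingency": {
      "location": {
        "rows": {"centre": [50, 14], "periphery": [233, 78]},
        "printed_chi2": 0.295,
        "printed_p": 0.587
      },
      "contour": {
        "rows": {"smooth": [36, 40], "lobular": [143, 42], "spiculated": [104, 10]},
        "printed_chi2": 48.04,
        "printed_p": "<0.001"
      },
      "necrosis": {
        "rows": {"yes": [33, 1], "no": [250, 91]},
        "printed_chi2": 9.415,
        "printed_p": 0.002
      },
      "vacuole_cyst": {
        "rows": {"none": [172, 77], "vacuole": [89, 12], "cyst": [22, 3]},
        "printed_chi2": 16.346,
        "printed_p": "<0.001"
      }
    },
    "summaries": {
      "size_cm": {
        "invasive": [283, 2.04, 0.55],
        "noninvasive": [92, 1.55, 0.51],
        "printed_t": -7.601
      },
      "ggoc_pct": {
        "invasive": [283, 14.0, 17.0],
        "noninvasive": [92, 44.0, 29.0],
        "printed_t": 9.461
      },
      "sc_pct": {
        "invasive": [283, 56.0, 30.0],
        "noninvasive": [92, 14.0, 21.0],
        "printed_t": -14.822
      },
      "suv_max": {
        "invasive": [137, 3.75, 2.85],
        "noninvasive": [10, 1.54, 2.41],
        "printed_t": -2.21
      }
    }
  },
  "thresholds": {
    "t_ggo_hu": -411.5,
    "t_sc_hu": -189.5,
    "sc_invasiveness_cutoff_pct": 25.8
  }
}
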