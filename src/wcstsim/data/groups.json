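{
  "version": 1,
  "indices": ["cc", "pe", "npe", "fms"],
  "groups": {
    "control_children": {
      "condition": "control",
      "age": "children",
      "params": {"mu": 0.08, "phi": 0.37, "tau": 0.18, "lam": 0.17},
      "n": 52,
      "n_alternate": 42,
      "profile": {
        "mean": {"cc": 5.06, "pe": 12.27, "npe": 14.13, "fms": 3.06},
        "sd": {"cc": 0.93, "pe": 3.26, "npe": 4.44, "fms": 1.75}
      }
    },
    "control_teenagers": {
      "condition": "control",
      "age": "teenagers",
      "params": {"mu": 0.17, "phi": 0.09, "tau": 0.12, "lam": 0.23},
      "n": 13,
      "profile": {
        "mean": {"cc": 6.0, "pe": 10.08, "npe": 8.62, "fms": 0.38},
        "sd": {"cc": 0.0, "pe": 2.3, "npe": 3.36, "fms": 0.62}
      }
    },
    "control_young_adults": {
      "condition": "control",
      "age": "young_adults",
      "params": {"mu": 0.21, "phi": 0.73, "tau": 0.12, "lam": 0.33},
      "n": 10,
      "profile": {
        "mean": {"cc": 5.9, "pe": 6.2, "npe": 8.5, "fms": 1.8},
        "sd": {"cc": 0.3, "pe": 1.89, "npe": 4.13, "fms": 1.72}
      }
    },
    "control_middle_adults": {
      "condition": "control",
      "age": "middle_adults",
      "params": {"mu": 0.05, "phi": 0.41, "tau": 0.18, "lam": 0.52},
      "n": 20,
      "profile": {
        "mean": {"cc": 5.5, "pe": 7.9, "npe": 12.05, "fms": 2.7},
        "sd": {"cc": 0.81, "pe": 2.32, "npe": 3.53, "fms": 1.71}
      }
    },
    "asc_children": {
      "condition": "asc",
      "age": "children",
      "params": {"mu": 0.11, "phi": 0.93, "tau": 0.83, "lam": 0.01},
      "n": 26,
      "profile": {
        "mean": {"cc": 0.12, "pe": 24.77, "npe": 38.04, "fms": 0.69},
        "sd": {"cc": 0.32, "pe": 4.48, "npe": 4.4, "fms": 1.1}
      }
    },
    "asc_teenagers": {
      "condition": "asc",
      "age": "teenagers",
      "params": {"mu": 0.2, "phi": 0.19, "tau": 0.14, "lam": 0.0},
      "n": 13,
      "profile": {
        "mean": {"cc": 5.08, "pe": 12.77, "npe": 13.92, "fms": 2.85},
        "sd": {"cc": 1.21, "pe": 3.12, "npe": 3.12, "fms": 1.23}
      }
    },
    "asc_young_adults": {
      "condition": "asc",
      "age": "young_adults",
      "params": {"mu": 0.08, "phi": 0.11, "tau": 0.08, "lam": 0.02},
      "n": 9,
      "profile": {
        "mean": {"cc": 5.44, "pe": 32.44, "npe": 14.33, "fms": 0.11},
        "sd": {"cc": 0.68, "pe": 10.23, "npe": 5.79, "fms": 0.31}
      }
    },
    "asc_middle_adults": {
      "condition": "asc",
      "age": "middle_adults",
      "params": {"mu": 0.2, "phi": 0.19, "tau": 0.14, "lam": 0.0},
      "n": 27,
      "profile": {
        "mean": {"cc": 4.44, "pe": 12.93, "npe": 15.07, "fms": 3.11},
        "sd": {"cc": 1.03, "pe": 3.17, "npe": 4.29, "fms": 1.59}
      }
    }
  }
}
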