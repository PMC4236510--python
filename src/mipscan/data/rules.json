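{
  "version": 1,
  "comment": "Allowed Ar/R selectivity-filter residue sets per MIP subfamily. Fungal subgroups with multiple observed filter compositions are encoded as the union of their row sets. npa_sub_pct is the published fraction of members with at least one substituted NPA box; the generator uses it as a substitution rate. sip_like_max_mw_da is calibrated on generator output (see scripts/build_reference_data.py).",
  "fungal": {
    "Fps1-like":   {"TM2": "W",    "TM5": "LIMN",     "LE1": "TCAS",  "LE2": "R",  "npa_sub_pct": 61.7},
    "Yfl054-like": {"TM2": "W",    "TM5": "ASTGDVIM", "LE1": "GALFY", "LE2": "R",  "npa_sub_pct": 66.7},
    "alpha":       {"TM2": "W",    "TM5": "G",        "LE1": "YWF",   "LE2": "R",  "npa_sub_pct": 95.8},
    "beta":        {"TM2": "W",    "TM5": "G",        "LE1": "Y",     "LE2": "R",  "npa_sub_pct": 12.5},
    "gamma1":      {"TM2": "TNS",  "TM5": "CT",       "LE1": "F",     "LE2": "R",  "npa_sub_pct": 20.0},
    "gamma2":      {"TM2": "WMI",  "TM5": "G",        "LE1": "Y",     "LE2": "R",  "npa_sub_pct": 0.0},
    "delta":       {"TM2": "FYM",  "TM5": "VIA",      "LE1": "ILV",   "LE2": "R",  "npa_sub_pct": 100.0},
    "AQP":         {"TM2": "FMAIY","TM5": "HEMLVAQ",  "LE1": "TACSG", "LE2": "R",  "npa_sub_pct": 28.8},
    "XIP":         {"TM2": "NSA",  "TM5": "SAG",      "LE1": "AF",    "LE2": "RK", "npa_sub_pct": 82.4},
    "SIP-like":    {"TM2": "VILM", "TM5": "ASG",      "LE1": "G",     "LE2": "LI", "npa_sub_pct": 81.2,
                    "require_non_arg_le2": true, "max_mw_da": 23700.0}
  },
  "plant": {
    "TIP": {"TM2": "HQN", "TM5": "IVMTSA", "LE1": "AGS", "LE2": "RVLIC", "npa_sub_pct": 1.1},
    "SIP": {"TM2": "VFILSTYA", "TM5": "VIHF", "LE1": "PG", "LE2": "NSAIF", "npa_sub_pct": 84.0}
  }
}
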