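{
  "name": "RIBOSUM85-60",
  "comment": "RIBOSUM85-60 log-odds matrices for RNA alignment (single-nucleotide 4x4 and base-pair 16x16), transcribed from the RSEARCH matrix set; background nucleotide probabilities estimated from the NCBI nucleotide database.",
  "nucleotides": ["A", "C", "G", "U"],
  "background": {"A": 0.27, "C": 0.23, "G": 0.23, "U": 0.27},
  "Rs": [
    [ 2.22, -1.86, -1.46, -1.39],
    [-1.86,  1.16, -2.48, -1.05],
    [-1.46, -2.48,  1.03, -1.74],
    [-1.39, -1.05, -1.74,  1.65]
  ],
  "pair_order": ["AA","AC","AG","AU","CA","CC","CG","CU","GA","GC","GG","GU","UA","UC","UG","UU"],
  "Rp_upper": {
    "AA": {"AA": -2.49, "AC": -7.04, "AG": -8.24, "AU": -4.32, "CA": -8.84, "CC": -14.37, "CG": -4.68, "CU": -12.64, "GA": -6.86, "GC": -5.03, "GG": -8.39, "GU": -5.84, "UA": -4.01, "UC": -11.32, "UG": -6.16, "UU": -9.05},
    "AC": {"AC": -2.11, "AG": -8.89, "AU": -2.04, "CA": -9.37, "CC": -9.08, "CG": -5.86, "CU": -10.45, "GA": -9.73, "GC": -3.81, "GG": -11.05, "GU": -4.72, "UA": -5.33, "UC": -8.67, "UG": -6.93, "UU": -7.83},
    "AG": {"AG": -0.80, "AU": -5.13, "CA": -10.41, "CC": -14.53, "CG": -4.57, "CU": -10.14, "GA": -8.61, "GC": -5.77, "GG": -5.38, "GU": -6.60, "UA": -5.43, "UC": -8.87, "UG": -5.94, "UU": -11.07},
    "AU": {"AU":  4.49, "CA": -5.56, "CC": -6.71, "CG":  1.67, "CU": -5.17, "GA": -5.33, "GC":  2.70, "GG": -5.61, "GU":  0.59, "UA":  1.61, "UC": -4.81, "UG": -0.51, "UU": -2.98},
    "CA": {"CA": -5.13, "CC": -10.45, "CG": -3.57, "CU": -8.49, "GA": -7.98, "GC": -5.95, "GG": -11.36, "GU": -7.93, "UA": -2.42, "UC": -7.08, "UG": -5.63, "UU": -8.39},
    "CC": {"CC": -3.59, "CG": -5.71, "CU": -5.77, "GA": -12.43, "GC": -3.70, "GG": -12.58, "GU": -7.88, "UA": -6.88, "UC": -7.40, "UG": -8.41, "UU": -5.41},
    "CG": {"CG":  5.36, "CU": -4.96, "GA": -6.00, "GC":  2.11, "GG": -4.66, "GU":  1.61, "UA":  2.75, "UC": -4.91, "UG":  0.99, "UU": -3.67},
    "CU": {"CU": -2.28, "GA": -7.71, "GC": -5.84, "GG": -13.69, "GU": -5.61, "UA": -4.72, "UC": -3.83, "UG": -7.36, "UU": -5.21},
    "GA": {"GA": -1.05, "GC": -4.88, "GG": -8.67, "GU": -6.10, "UA": -5.85, "UC": -6.63, "UG": -7.55, "UU": -11.54},
    "GC": {"GC":  5.62, "GG": -4.13, "GU":  1.21, "UA":  1.60, "UC": -4.49, "UG": -0.08, "UU": -3.90},
    "GG": {"GG": -1.98, "GU": -5.77, "UA": -5.75, "UC": -12.01, "UG": -4.27, "UU": -10.79},
    "GU": {"GU":  3.47, "UA": -0.40, "UC": -6.24, "UG":  1.06, "UU": -4.22},
    "UA": {"UA":  4.97, "UC": -6.34, "UG":  0.30, "UU": -2.51},
    "UC": {"UC": -2.98, "UG": -4.76, "UU": -5.30},
    "UG": {"UG":  3.36, "UU": -4.38},
    "UU": {"UU": -2.49}
  }
}
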