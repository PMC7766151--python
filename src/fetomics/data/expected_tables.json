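{
  "table2": {
    "tbr_mean": {"sensitivity": 75, "specificity": 61, "ppv": 63, "npv": 73,
                 "fnr": 25, "fpr": 39, "accuracy": 68, "f1": 0.69, "mcc": 0.36,
                 "auc": 0.73, "cutoff": 1.95, "fisher_p": 0.045},
    "tbr_max":  {"sensitivity": 81, "specificity": 67, "ppv": 68, "npv": 80,
                 "fnr": 19, "fpr": 33, "accuracy": 74, "f1": 0.74, "mcc": 0.48,
                 "auc": 0.79, "cutoff": 2.25, "fisher_p": 0.007},
    "ttp":      {"sensitivity": 75, "specificity": 44, "ppv": 55, "npv": 67,
                 "fnr": 25, "fpr": 56, "accuracy": 59, "f1": 0.63, "mcc": 0.20,
                 "cutoff": 25, "fisher_p": 0.297},
    "slope":    {"sensitivity": 56, "specificity": 61, "ppv": 56, "npv": 61,
                 "fnr": 44, "fpr": 39, "accuracy": 59, "f1": 0.56, "mcc": 0.17,
                 "cutoff": 0.3, "fisher_p": 0.492}
  },
  "table3": {
    "tbr_mean+tbr_max":     {"sensitivity": 75, "specificity": 72, "ppv": 71, "npv": 76,
                             "fnr": 25, "fpr": 28, "accuracy": 74, "f1": 0.73, "mcc": 0.47,
                             "fisher_p": 0.015},
    "tbr_mean+ttp":         {"sensitivity": 69, "specificity": 78, "ppv": 73, "npv": 74,
                             "fnr": 31, "fpr": 22, "accuracy": 74, "f1": 0.71, "mcc": 0.47,
                             "fisher_p": 0.014},
    "tbr_mean+slope":       {"sensitivity": 50, "specificity": 78, "ppv": 67, "npv": 64,
                             "fnr": 50, "fpr": 22, "accuracy": 65, "f1": 0.57, "mcc": 0.29,
                             "fisher_p": 0.151},
    "tbr_max+ttp":          {"sensitivity": 69, "specificity": 83, "ppv": 79, "npv": 75,
                             "fnr": 31, "fpr": 17, "accuracy": 76, "f1": 0.73, "mcc": 0.53,
                             "fisher_p": 0.005},
    "tbr_max+slope":        {"sensitivity": 50, "specificity": 89, "ppv": 80, "npv": 67,
                             "fnr": 50, "fpr": 11, "accuracy": 71, "f1": 0.62, "mcc": 0.43,
                             "fisher_p": 0.023},
    "ttp+slope":            {"sensitivity": 56, "specificity": 61, "ppv": 56, "npv": 61,
                             "fnr": 44, "fpr": 39, "accuracy": 59, "f1": 0.56, "mcc": 0.17,
                             "fisher_p": 0.492},
    "tbr_mean+tbr_max+ttp": {"sensitivity": 69, "specificity": 89, "ppv": 85, "npv": 76,
                             "fnr": 31, "fpr": 11, "accuracy": 79, "f1": 0.76, "mcc": 0.59,
                             "fisher_p": 0.001}
  }
}
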