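{
  "probe_id": "cg21790626",
  "description": "Per-cancer-type reference values for the ZNF154 CpG-island methylation marker across 11 TCGA solid tumor types: driver-gene sets with non-silent SNV mutation prevalences (percent of tumors), the beta-value hypermethylation cutoff excluding 95% of controls, the percent of tumors hypermethylated at cg21790626, the percent mutated in any gene of the set, the percent carrying a TP53 mutation, and cohort sizes. Gene sets are OncoKB-listed genes recurrently mutated in >10% of tumors for the type; KIRP is the single-gene exception (no gene exceeded 10%; the top mutated gene, MET, was used).",
  "cancer_types": {
    "OV": {
      "n_controls": 12, "n_tumors": 302,
      "cutoff": 0.313, "pct_hypermethylated": 92.4, "pct_mutated": 73.2, "tp53_pct": 73.2,
      "genes": {"TP53": 73.2}
    },
    "BRCA": {
      "n_controls": 82, "n_tumors": 664,
      "cutoff": 0.190, "pct_hypermethylated": 74.4, "pct_mutated": 54.2, "tp53_pct": 24.8,
      "genes": {"PIK3CA": 31.6, "TP53": 24.8, "CDH1": 7.1}
    },
    "PAAD": {
      "n_controls": 10, "n_tumors": 150,
      "cutoff": 0.070, "pct_hypermethylated": 90.7, "pct_mutated": 95.3, "tp53_pct": 61.3,
      "genes": {"KRAS": 90.7, "TP53": 61.3, "SMAD4": 16.7, "CDKN2A": 10.7}
    },
    "LUAD": {
      "n_controls": 32, "n_tumors": 185,
      "cutoff": 0.071, "pct_hypermethylated": 75.7, "pct_mutated": 85.4, "tp53_pct": 41.1,
      "genes": {"TP53": 41.1, "KRAS": 31.9, "LRP1B": 25.4, "PCLO": 18.4, "STK11": 8.6,
                "KEAP1": 15.1, "RELN": 14.1, "FAT4": 15.7, "EGFR": 9.2, "PTPRD": 13.5,
                "CPS1": 10.3, "GRIN2A": 10.8, "NF1": 8.1, "EPHA5": 9.2, "FAT1": 10.8,
                "MKI67": 8.6, "SETBP1": 8.1, "NOTCH4": 10.3}
    },
    "LIHC": {
      "n_controls": 50, "n_tumors": 373,
      "cutoff": 0.058, "pct_hypermethylated": 90.1, "pct_mutated": 46.9, "tp53_pct": 24.1,
      "genes": {"TP53": 24.1, "CTNNB1": 25.2, "ALB": 4.3}
    },
    "KIRP": {
      "n_controls": 45, "n_tumors": 267,
      "cutoff": 0.025, "pct_hypermethylated": 50.6, "pct_mutated": 7.5, "tp53_pct": 1.9,
      "genes": {"MET": 7.5}
    },
    "PRAD": {
      "n_controls": 49, "n_tumors": 498,
      "cutoff": 0.523, "pct_hypermethylated": 52.0, "pct_mutated": 20.5, "tp53_pct": 9.8,
      "genes": {"TP53": 9.8, "SPOP": 11.0}
    },
    "HNSC": {
      "n_controls": 45, "n_tumors": 510,
      "cutoff": 0.181, "pct_hypermethylated": 98.6, "pct_mutated": 85.3, "tp53_pct": 59.8,
      "genes": {"TP53": 59.8, "FAT1": 15.9, "CDKN2A": 17.5, "PIK3CA": 18.0, "NOTCH1": 14.5,
                "LRP1B": 17.1, "KMT2D": 12.7, "PCLO": 15.3, "NSD1": 9.2, "CASP8": 9.2}
    },
    "STAD": {
      "n_controls": 2, "n_tumors": 349,
      "cutoff": 0.161, "pct_hypermethylated": 96.6, "pct_mutated": 82.5, "tp53_pct": 39.3,
      "genes": {"TP53": 39.3, "LRP1B": 24.6, "ARID1A": 12.0, "FAT4": 18.6, "PCLO": 16.0,
                "KMT2D": 10.0, "PIK3CA": 16.9, "ACVR2A": 1.4, "LRRK2": 13.5, "KMT2C": 8.6,
                "CIC": 8.9, "UBR5": 4.3, "PREX2": 11.7, "APC": 7.7, "ERBB4": 11.5,
                "TRRAP": 10.6, "RNF213": 9.7, "STK19": 0.3, "KMT2B": 4.6, "RPL22": 1.7,
                "PTPRT": 8.9, "PRKDC": 7.4, "ZFHX3": 7.2, "RELN": 9.7, "EP400": 7.7}
    },
    "BLCA": {
      "n_controls": 21, "n_tumors": 130,
      "cutoff": 0.316, "pct_hypermethylated": 94.6, "pct_mutated": 63.8, "tp53_pct": 45.4,
      "genes": {"TP53": 45.4, "ARID1A": 16.9, "KDM6A": 15.4, "PIK3CA": 20.0}
    },
    "KIRC": {
      "n_controls": 160, "n_tumors": 263,
      "cutoff": 0.016, "pct_hypermethylated": 75.3, "pct_mutated": 52.9, "tp53_pct": 3.0,
      "genes": {"VHL": 36.1, "PBRM1": 19.8, "SETD2": 9.5}
    }
  }
}
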