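{
  "comment": "Published count data used as fixed inputs: cluster-by-group subject counts from the two-step FA cluster analysis, per-SNP genotype counts (AA, Aa, aa by declared major allele) for the study strata, and the MetS cluster-1 vs cluster-2 genotype tables used in the association scan. rs174545 and rs174546 counts are identical to rs174537 (complete LD, r2 = 1.0).",
  "cluster_by_group": {
    "rows": ["MetS", "CON"],
    "cols": ["cluster1", "cluster2"],
    "table": [[109, 57], [71, 117]]
  },
  "snp_alleles": {
    "rs174537": ["G", "T"],
    "rs174545": ["G", "C"],
    "rs174546": ["G", "A"],
    "rs968567": ["C", "T"],
    "rs174570": ["C", "T"],
    "rs174575": ["C", "G"],
    "rs174602": ["T", "C"],
    "rs174589": ["C", "G"]
  },
  "genotype_counts_by_stratum": {
    "rs174537": {"MetS": [70, 64, 16], "CON": [74, 91, 15], "CON1": [34, 31, 3], "CON2": [40, 60, 12]},
    "rs174570": {"MetS": [110, 37, 3], "CON": [135, 44, 1], "CON1": [56, 12, 0], "CON2": [79, 32, 1]},
    "rs174575": {"MetS": [90, 54, 6], "CON": [95, 74, 11], "CON1": [41, 23, 4], "CON2": [54, 51, 7]},
    "rs174602": {"MetS": [102, 43, 5], "CON": [122, 54, 4], "CON1": [51, 16, 1], "CON2": [71, 38, 3]},
    "rs174589": {"MetS": [99, 46, 5], "CON": [117, 61, 2], "CON1": [50, 18, 0], "CON2": [67, 43, 2]},
    "rs968567": {"MetS": [111, 37, 2], "CON": [123, 54, 3], "CON1": [50, 17, 1], "CON2": [73, 37, 2]}
  },
  "mets_cluster_genotype_tables": {
    "rows": ["MetS1", "MetS2"],
    "cols": ["AA", "Aa", "aa"],
    "rs174537": [[52, 38, 4], [18, 26, 12]],
    "rs174570": [[76, 18, 0], [34, 19, 3]],
    "rs174575": [[62, 30, 2], [28, 24, 4]],
    "rs174602": [[70, 23, 1], [32, 20, 4]],
    "rs174589": [[67, 26, 1], [32, 20, 4]],
    "rs968567": [[73, 21, 0], [38, 16, 2]]
  }
}
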