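"""Published benchmark contingency tables for identifier conversion.

Two evaluations of ten conversion tools over 1,000 sampled Entrez queries
each: gene-symbol targets (TABLE_SYMBOL) and curated RefSeq targets
(TABLE_REFSEQ).  Row format: (tool, totalMapped, TP, FP, FN, TN,
TPR, FPR, ACC, FDR, F1) with the metric columns as printed (2 decimals).

Note: the "HMS & ID" row of TABLE_REFSEQ prints totalMapped=461 although its
own TP+FP=657; every other row satisfies totalMapped=TP+FP, so that single
cell is treated as a typo and excluded from totalMapped checks.
"""

TABLE_SYMBOL = [
    ("coordinate-based converter", 885, 866, 19, 109, 6, 88.82, 76.00, 87.20, 2.15, 93.12),
    ("DAVID", 853, 790, 63, 146, 1, 84.40, 98.44, 79.10, 7.39, 88.32),
    ("MADGene", 854, 730, 124, 145, 1, 83.43, 99.20, 73.10, 14.52, 84.44),
    ("HMS & IC", 724, 723, 1, 270, 6, 72.81, 14.29, 72.90, 0.14, 84.22),
    ("Onto-Translate", 823, 722, 101, 176, 1, 80.40, 99.02, 72.30, 12.27, 83.90),
    ("MatchMiner", 539, 457, 82, 458, 3, 49.95, 96.47, 46.00, 15.21, 62.86),
    ("Clone/Gene ID converter", 537, 441, 96, 457, 6, 49.11, 94.12, 44.70, 17.88, 61.46),
    ("g:Convert", 445, 433, 12, 549, 6, 44.09, 66.67, 43.90, 2.70, 60.69),
    ("Synergizer", 445, 433, 12, 549, 6, 44.09, 66.67, 43.90, 2.70, 60.69),
    ("Babelomics", 486, 421, 65, 508, 6, 45.32, 91.55, 42.70, 13.37, 59.51),
]

TABLE_REFSEQ = [
    ("coordinate-based converter", 586, 362, 224, 20, 394, 94.76, 36.25, 75.60, 38.23, 74.79),
    ("MADGene", 551, 335, 216, 49, 400, 87.24, 35.06, 73.50, 39.20, 71.66),
    ("Onto-Translate", 501, 291, 210, 99, 400, 74.62, 34.43, 69.10, 41.92, 65.32),
    ("DAVID", 549, 311, 238, 72, 379, 81.20, 38.57, 69.00, 43.35, 66.74),
    ("Synergizer", 482, 278, 204, 121, 397, 69.67, 33.94, 67.50, 42.32, 63.11),
    ("g:Convert", 482, 278, 204, 121, 397, 69.67, 33.94, 67.50, 42.32, 63.11),
    ("MatchMiner", 474, 268, 206, 126, 400, 68.02, 33.99, 66.80, 43.46, 61.75),
    ("Babelomics", 501, 267, 234, 128, 371, 67.59, 38.68, 63.80, 46.71, 59.60),
    ("Clone/Gene ID converter", 421, 219, 202, 195, 384, 52.90, 34.47, 60.30, 47.98, 52.46),
    ("HMS & ID", 461, 227, 430, 181, 162, 55.64, 72.64, 38.90, 65.45, 42.63),
]

TOTAL_MAPPED_TYPOS = {("TABLE_REFSEQ", "HMS & ID")}
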