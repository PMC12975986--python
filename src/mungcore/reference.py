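"""Published reference values from the Indian National Genebank mungbean
characterization study (3,903 accessions, augmented block design, 21
quantitative + 7 qualitative traits).

These frozen tables serve two purposes:

1. internal-identity checks -- e.g. broad-sense heritability must equal
   ``100 * (GCV/PCV)**2`` and genetic gain must equal ``100 * GA / mean`` row
   by row, which is how the package verifies its variability formulas against
   the printed study output without access to the raw field data;
2. realistic defaults for the synthetic-collection generator, whose trait
   means, variance components, descriptor-state counts and geographic-group
   frequencies are taken from (or calibrated to) these values.

Note on the variability table: the study's printed column header order is
"PCV GCV", but the printed h2 values are reproduced only when the *smaller*
printed coefficient is read as GCV (genotypic variation cannot exceed
phenotypic variation). The table below stores the coefficients under that
reading.
"""

from __future__ import annotations

# trait -> (gcv, pcv, h2_pct, h2_cat, ga, ga_cat, gg, gg_cat)
VARIABILITY_TABLE = {
    "TLL": (5.98, 13.17, 20.62, "Low", 0.48, "Low", 5.60, "Low"),
    "TLW": (8.16, 16.03, 25.92, "Low", 0.58, "Low", 8.57, "Low"),
    "PH": (17.18, 19.74, 75.70, "High", 22.02, "High", 30.83, "High"),
    "PTL": (11.62, 19.35, 36.05, "Medium", 1.40, "Low", 14.39, "Medium"),
    "PDL": (21.05, 28.30, 55.32, "Medium", 4.85, "Low", 32.30, "High"),
    "PL": (13.15, 15.54, 71.63, "High", 1.81, "Low", 22.96, "High"),
    "NPPC": (23.10, 31.52, 53.70, "Medium", 1.42, "Low", 34.92, "High"),
    "SD": (15.16, 19.31, 61.62, "High", 2.80, "Low", 24.55, "High"),
    "NPB": (20.42, 28.97, 49.68, "Medium", 1.18, "Low", 29.69, "High"),
    "NSPP": (5.96, 8.58, 48.36, "Medium", 1.03, "Low", 8.56, "Low"),
    "NPPP": (29.75, 52.26, 32.42, "Medium", 15.95, "Medium", 34.95, "High"),
    "PB": (38.09, 45.61, 69.76, "High", 31.69, "High", 65.63, "High"),
    "DFF": (16.48, 17.84, 85.40, "High", 15.48, "Medium", 31.42, "High"),
    "DM": (7.53, 9.55, 62.10, "High", 9.76, "Low", 12.23, "Medium"),
    "GY": (23.41, 57.80, 16.40, "Low", 2.29, "Low", 19.55, "Medium"),
    "SW": (25.83, 30.03, 74.01, "High", 1.52, "Low", 45.85, "High"),
    "SA": (16.66, 18.97, 77.14, "High", 4.79, "Low", 30.19, "High"),
    "SL": (8.65, 9.93, 75.80, "High", 0.79, "Low", 15.53, "Medium"),
    "SB": (7.28, 8.98, 65.74, "High", 0.49, "Low", 12.18, "Medium"),
    "SR": (2.30, 4.19, 30.03, "Medium", 0.02, "Low", 2.60, "Low"),
    "PWPP": (21.08, 54.55, 14.93, "Low", 3.19, "Low", 16.80, "Medium"),
}

# Entire-collection summary per quantitative trait: (mean, sd, unit, full name)
SUMMARY_TABLE = {
    "TLL": (8.5, 1.1, "cm", "terminal leaf length"),
    "TLW": (6.7, 1.1, "cm", "terminal leaf width"),
    "PTL": (9.7, 1.9, "cm", "petiole length"),
    "PB": (48.4, 22.0, "g", "plant biomass"),
    "DFF": (49.3, 8.8, "d", "days to 50% flowering"),
    "DM": (79.9, 7.6, "d", "days to 80% maturity"),
    "PH": (71.3, 14.1, "cm", "plant height"),
    "SD": (11.4, 2.2, "mm", "stem diameter"),
    "PDL": (15.0, 4.3, "cm", "peduncle length"),
    "NPB": (4.0, 1.1, "", "number of primary branches"),
    "NPPP": (45.4, 23.8, "", "number of pods per plant"),
    "NPPC": (4.1, 1.3, "", "number of pods per cluster"),
    "PL": (7.9, 1.2, "cm", "pod length"),
    "NSPP": (12.0, 1.0, "", "number of seeds per pod"),
    "PWPP": (18.9, 10.3, "g", "pod weight per plant"),
    "GY": (11.7, 6.8, "g", "grain yield per plant"),
    "SW": (3.3, 1.0, "g", "100-seed weight"),
    "SA": (15.9, 3.0, "mm2", "seed area"),
    "SL": (5.1, 0.5, "mm", "seed length"),
    "SB": (4.0, 0.4, "mm", "seed breadth"),
    "SR": (0.8, 0.03, "", "seed roundness"),
}

# PCA of the entire collection: eigenvalues of the first six components of a
# correlation-matrix PCA over the 21 quantitative traits.
PCA_EIGENVALUES_EC = (5.30, 3.53, 3.14, 2.18, 1.10, 1.03)
N_QUANT_TRAITS = 21

# Shannon diversity of qualitative traits:
# trait -> (n_states, H' entire collection, H' core collection)
SHANNON_TABLE = {
    "hypocotyl_color": (5, 1.119, 1.187),
    "seedling_vigor": (3, 0.873, 0.949),
    "growth_habit": (3, 0.686, 0.857),
    "raceme_position": (3, 0.586, 0.737),
    "pod_attachment": (2, 0.330, 0.504),
    "pod_pubescence": (4, 0.689, 0.844),
    "seed_color": (9, 1.346, 1.536),
}

# Geographic origin counts of the collection's accessions.
ORIGIN_COUNTS = {
    "india": 3411,
    "taiwan": 215,
    "pakistan": 92,
    "unknown": 60,
    "china": 49,
    "thailand": 40,
    "sri_lanka": 10,
    "japan": 9,
    "usa": 7,
    "other": 7,
    "hungary": 3,
}

# Trial layout: five check varieties, each sown twice in every one of the
# 50 blocks; 3,903 unreplicated test accessions.
CHECKS = ("Virat", "Samrat", "IPM2-14", "SML-668", "MH-421")
N_TEST = 3903
N_BLOCKS = 50
REPS_PER_CHECK = 2
CORE_FRACTION = 0.10
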