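"""Published summary statistics bundled as analysis inputs.

These are printed summary numbers from the source cohort study and the
Global Lipids Genetics Consortium adult meta-analysis: per-visit phenotype
summaries of the birth cohort, and the child-vs-adult effect-size table
(consortium beta/SE vs child mixed-model beta/SE on inverse-normal scale).
They are inputs to the comparison machinery, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

#: Phenotypic summaries of the children (N = 544): mean and SD of age (years),
#: BMI (kg/m^2) and the four lipid traits (concentration units) at each of the
#: three visits (birth, 3 y, 5 y). Fraction male = 0.4963.
CHILD_SEX_MALE_FRACTION = 0.4963

CHILD_PHENOTYPE_SUMMARY = pd.DataFrame(
    [
        ("age", 0, 0.007, 0.012),
        ("age", 3, 3.088, 0.166),
        ("age", 5, 5.121, 0.195),
        ("BMI", 0, 13.961, 1.362),
        ("BMI", 3, 16.212, 1.241),
        ("BMI", 5, 15.908, 1.618),
        ("TC", 0, 1.635, 0.414),
        ("TC", 3, 4.049, 0.703),
        ("TC", 5, 4.098, 0.702),
        ("LDL", 0, 0.677, 0.262),
        ("LDL", 3, 2.420, 0.636),
        ("LDL", 5, 2.346, 0.662),
        ("HDL", 0, 0.795, 0.277),
        ("HDL", 3, 1.324, 0.291),
        ("HDL", 5, 1.437, 0.321),
        ("TG", 0, 0.370, 0.210),
        ("TG", 3, 0.670, 0.265),
        ("TG", 5, 0.703, 0.312),
    ],
    columns=["trait", "visit", "mean", "sd"],
)

#: Nominally significant child SNPs compared with consortium adults.
#: Columns: trait, gene, rsid, adult (consortium) beta/SE/p, child (cohort,
#: mixed model, inverse-normal trait scale) beta/SE/p, printed Z and printed
#: one-sided p. The ABCA1 row has no consortium entry in the source table.
ADULT_CHILD_COMPARISON = pd.DataFrame(
    [
        ("TC", "ABCG5", "rs6756629", 0.122, 0.010, 4.35e-36, 0.219, 0.100, 2.88e-2, -0.965, 1.67e-1),
        ("TC", "APOA1", "rs12292921", 0.096, 0.007, 2.22e-42, -0.193, 0.107, 6.99e-2, 2.695, 3.52e-3),
        ("TC", "OSBPL7", "rs12452315", 0.024, 0.004, 2.67e-10, 0.123, 0.048, 1.01e-2, -2.055, 1.99e-2),
        ("TC", "LDLR", "rs6511720", 0.185, 0.006, 5.43e-202, 0.188, 0.073, 1.02e-2, -0.041, 4.84e-1),
        ("TC", "TOMM40", "rs2075650", 0.143, 0.005, 8.93e-158, 0.230, 0.065, 3.91e-4, -1.335, 9.10e-2),
        ("TC", "FER1LA", "rs2277862", 0.035, 0.005, 2.26e-13, 0.154, 0.069, 2.54e-2, -1.720, 4.27e-2),
        ("HDL", "ATG7", "rs2606736", 0.025, 0.004, 4.80e-8, -0.098, 0.050, 5.23e-2, 2.452, 7.10e-3),
        ("HDL", "VEGFA", "rs998584", 0.026, 0.004, 2.27e-11, 0.094, 0.048, 4.87e-2, -1.412, 7.90e-2),
        ("HDL", "ABCA1", "rs1883025", None, None, None, 0.143, 0.053, 7.53e-3, None, None),
        ("HDL", "LIPC", "rs1077834", 0.125, 0.004, 7.77e-180, 0.171, 0.058, 3.28e-3, -0.791, 2.14e-1),
        ("HDL", "CETP", "rs3764261", 0.241, 0.004, 1.39e-769, 0.238, 0.052, 5.38e-6, 0.058, 4.77e-1),
        ("HDL", "ABCA8", "rs4148008", 0.028, 0.004, 1.13e-12, -0.139, 0.051, 5.85e-3, 3.264, 5.48e-4),
        ("LDL", "CELSR2", "rs646776", 0.160, 0.004, 1.63e-272, 0.158, 0.061, 9.83e-3, 0.033, 4.87e-1),
        ("LDL", "ABCG5", "rs6756629", 0.129, 0.010, 1.77e-34, 0.213, 0.103, 3.92e-2, -0.812, 2.08e-1),
        ("LDL", "APOB", "rs1367117", 0.119, 0.004, 9.48e-183, 0.134, 0.053, 1.20e-2, -0.282, 3.89e-1),
        ("LDL", "APOA1", "rs12292921", 0.068, 0.007, 7.21e-20, -0.175, 0.110, 1.11e-1, 2.205, 1.37e-2),
        ("LDL", "BRCA2", "rs4942486", 0.024, 0.004, 2.26e-11, 0.082, 0.050, 9.85e-2, -1.156, 1.24e-1),
        ("LDL", "OSBPL7", "rs12452315", 0.025, 0.004, 2.37e-10, 0.114, 0.049, 2.17e-2, -1.810, 3.51e-2),
        ("LDL", "LDLR", "rs6511720", 0.221, 0.006, 3.85e-262, 0.194, 0.075, 1.02e-2, 0.359, 3.60e-1),
        ("LDL", "TOMM40", "rs157580", 0.108, 0.005, 9.24e-119, 0.128, 0.051, 1.22e-2, -0.390, 3.48e-1),
        ("TG", "GCKR", "rs1260326", 0.115, 0.003, 2.29e-239, 0.116, 0.048, 1.28e-2, -0.021, 4.92e-1),
        ("TG", "INSR", "rs7248104", 0.022, 0.003, 5.05e-10, 0.138, 0.047, 3.28e-3, -2.463, 6.89e-3),
    ],
    columns=[
        "trait", "gene", "rsid",
        "adult_beta", "adult_se", "adult_p",
        "child_beta", "child_se", "child_p",
        "printed_z", "printed_p",
    ],
)

#: Theoretical variance explained (%) by the trait panels in consortium
#: adults, with the panel sizes, as printed in the variance comparison table.
ADULT_VARIANCE_EXPLAINED_PCT = pd.DataFrame(
    [
        ("TC", 69, 6.4),
        ("LDL", 59, 7.4),
        ("HDL", 73, 7.1),
        ("TG", 40, 4.2),
    ],
    columns=["trait", "n_snps", "adult_pct"],
)

#: Trait panel sizes: number of adult GWAS SNPs per lipid trait.
PANEL_SIZES = {"TC": 69, "LDL": 59, "HDL": 73, "TG": 40}

#: Per-visit child sample sizes of the cohort's regression models.
VISIT_SAMPLE_SIZES = {0: 456, 3: 421, 5: 361}
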