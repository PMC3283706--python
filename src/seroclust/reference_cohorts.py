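"""Published summary statistics of the two LIPS SLE cohorts this analysis models.

The original profiling study deposited no raw titers, only cohort-level
summaries: per-antigen control/patient mean titers with 95% CIs, per-antigen
sensitivity and specificity, cluster prevalences, and per-cluster clinical
manifestation percentages. Those printed numbers serve two purposes here:

* they parameterize the synthetic-cohort generator (control titer
  distributions, class-conditional seropositivity, clinical rates), and
* together with the printed group sizes they allow the headline contingency
  tables to be reconstructed exactly (see
  :func:`seroclust.association_stats.counts_from_percent`).

All titers are in light units (LU); all rates are percentages as printed.
"""

from __future__ import annotations

PILOT_N_SLE = 76
PILOT_N_CONTROL = 18
VALIDATION_N_SLE = 129
VALIDATION_N_CONTROL = 15

#: Pilot-cohort relative-ratio cluster counts (Sm/RNP, Ro/La, seronegative).
PILOT_CLUSTER_COUNTS = (31, 36, 9)
#: Validation-cohort cluster counts.
VALIDATION_CLUSTER_COUNTS = (61, 66, 2)
#: Validation-cohort cluster proportions used as generator defaults.
VALIDATION_CLUSTER_PROBS = (0.47, 0.51, 0.02)

#: Pilot cohort: six-core-antigen panel detected >=1 positive in 67/76 SLE.
PILOT_PANEL_POSITIVE = 67

#: Validation cohort, healthy-control mean titer and 95% CI per core antigen
#: (LU). CIs are normal-theory intervals on the printed control n of 15.
VALIDATION_CONTROL_TITERS = {
    "Ro52": (10_000, 6_000, 14_000),
    "Ro60": (5_000, 3_400, 7_200),
    "La": (4_700, 3_300, 6_100),
    "Sm-D3": (4_800, 4_200, 5_400),
    "RNP-A": (12_600, 8_200, 17_000),
    "RNP-70k": (28_800, 24_800, 32_800),
}

#: Validation cohort, per-antigen sensitivity % (fraction of SLE seropositive).
VALIDATION_SENSITIVITY = {
    "Ro52": 51,
    "Ro60": 51,
    "La": 71,
    "Sm-D3": 65,
    "RNP-A": 55,
    "RNP-70k": 85,
}

#: Extra (cytokine / neuronal) antigens: control mean titer, 95% CI, and
#: overall sensitivity % in the validation cohort.
VALIDATION_EXTRA_TITERS = {
    "IFN-a": (2_000, 1_600, 2_500),
    "IFN-w": (1_900, 1_700, 2_000),
    "AQP-4": (10_600, 2_000, 19_000),
    "GAD65": (4_300, 2_700, 6_000),
    "GFAP": (7_700, 5_100, 10_000),
    "TH": (11_600, 3_700, 20_000),
}
VALIDATION_EXTRA_SENSITIVITY = {
    "IFN-a": 12,
    "IFN-w": 38,
    "AQP-4": 5,
    "GAD65": 5,
    "GFAP": 17,
    "TH": 8,
}

#: Validation cohort: percentage of patients in each relative-ratio cluster
#: with each clinical manifestation, keyed flag -> (Ro/La %, Sm/RNP %).
CLUSTER_CLINICAL_PCT = {
    "cns": (7, 2),
    "musculoskeletal": (30, 44),
    "mucocutaneous": (39, 33),
    "nephritis": (37, 25),
    "serositis": (0, 13),
    "hematological": (18, 13),
    "sacq": (7, 10),
    "quiescent": (4, 13),
}

#: Same table, autoantibody rows: % seropositive per cluster (Ro/La, Sm/RNP).
CLUSTER_ANTIBODY_PCT = {
    "IFN-a": (6, 17),
    "IFN-w": (41, 35),
    "TH": (8, 10),
    "AQP-4": (5, 5),
    "GAD65": (2, 6),
    "GFAP": (15, 17),
}

#: Headline cross-cohort associations, as (pct_in_group1, n1, pct_in_group2,
#: n2) with the printed two-sided Fisher p. Group sizes come from the printed
#: cluster counts / marginal prevalences of the validation cohort.
HEADLINE_FISHER = {
    # serositis: 0% of 66 Ro/La vs 13% of 61 Sm/RNP
    "serositis_by_cluster": dict(pct1=0, n1=66, pct2=13, n2=61, p_printed=0.0022),
    # anti-IFN-a: 4/11 SACQ patients vs 11 of the 118 remaining (36% v. 9%)
    "ifn_alpha_by_sacq": dict(counts=((4, 7), (11, 107)), p_printed=0.024),
    # anti-Sm: 80% of 49 IFN-w positives vs 56% of 80 IFN-w negatives
    "sm_by_ifn_omega": dict(pct1=80, n1=49, pct2=56, n2=80, p_printed=0.0079),
    # anti-IFN-a: 22% of 49 IFN-w positives vs 5% of 80 IFN-w negatives
    "ifn_alpha_by_ifn_omega": dict(pct1=22, n1=49, pct2=5, n2=80, p_printed=0.0041),
}

#: Validation cohort demographics: 13:1 female:male, age at diagnosis
#: 31 +/- 12.1 years, 58% anti-dsDNA positive (75/129).
FEMALE_FRACTION = 13 / 14
DSDNA_POSITIVE_FRACTION = 75 / 129
#: Age-group split implied by a normal(31, 12.1) age-at-diagnosis model.
AGE_GROUP_PROBS = {"<20": 0.18, "20-40": 0.59, ">40": 0.23}

#: Mixture assay (six-antigen single-well test), validation cohort.
MIXTURE_SENSITIVITY = 83
MIXTURE_SPECIFICITY = 93
MIXTURE_SUM_SPEARMAN_R = 0.95
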