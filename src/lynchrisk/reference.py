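"""Published reference estimates for MMR variant carriers under surveillance.

The individual-level registry data behind the published gene-, sex- and
organ-specific estimates are not public, but the printed summary statistics
are, and the desk-scale derived statistics (crude mortality to 75, death
shares, incidence-overlap arithmetic) are exactly reproducible from them.
This module ships those printed inputs so the corresponding routines can be
exercised and checked without any registry access.

All incidence values are percentages at the printed precision; survival
values are proportions.
"""

from __future__ import annotations

#: 10-year crude survival after a cancer diagnosed before age 65, pooled
#: over genes, as published (proportions).
SURVIVAL_10Y: dict[str, float] = {
    "colon": 0.87,
    "rectum": 0.72,
    "endometrium": 0.92,
    "ovary": 0.85,
    "ureter_kidney": 0.73,
    "urinary_bladder": 0.71,
    "prostate": 0.76,
    "bile_duct": 0.42,
    "stomach": 0.63,
    "small_intestine": 0.70,
    "pancreas": 0.17,
    "brain": 0.34,
}

#: Published mortality table cells: (organ, gene, sex, cumulative incidence
#: at 65 in percent, published mortality at 75 in integer percent).
#: Sex-restricted organs list only the applicable sex.  The female PMS2
#: brain cell rests on a single case and is included as printed.
MORTALITY_CELLS: list[tuple[str, str, str, float, int]] = [
    ("colon", "MLH1", "M", 48.4, 6),
    ("colon", "MLH1", "F", 36.3, 5),
    ("colon", "MSH2", "M", 41.5, 5),
    ("colon", "MSH2", "F", 29.8, 4),
    ("colon", "MSH6", "M", 12.7, 2),
    ("colon", "MSH6", "F", 10.1, 1),
    ("colon", "PMS2", "M", 9.5, 1),
    ("colon", "PMS2", "F", 2.8, 0),
    ("rectum", "MLH1", "M", 6.0, 2),
    ("rectum", "MLH1", "F", 4.6, 1),
    ("rectum", "MSH2", "M", 12.6, 4),
    ("rectum", "MSH2", "F", 7.6, 2),
    ("rectum", "MSH6", "M", 5.1, 1),
    ("rectum", "MSH6", "F", 3.9, 1),
    ("rectum", "PMS2", "M", 0.0, 0),
    ("rectum", "PMS2", "F", 2.2, 1),
    ("endometrium", "MLH1", "F", 31.7, 3),
    ("endometrium", "MSH2", "F", 37.6, 3),
    ("endometrium", "MSH6", "F", 32.1, 3),
    ("endometrium", "PMS2", "F", 12.7, 1),
    ("ovary", "MLH1", "F", 8.0, 1),
    ("ovary", "MSH2", "F", 10.6, 2),
    ("ovary", "MSH6", "F", 2.9, 0),
    ("ovary", "PMS2", "F", 2.5, 0),
    ("stomach", "MLH1", "M", 2.8, 1),
    ("stomach", "MLH1", "F", 2.0, 1),
    ("stomach", "MSH2", "M", 4.3, 2),
    ("stomach", "MSH2", "F", 2.6, 1),
    ("stomach", "MSH6", "M", 0.7, 0),
    ("stomach", "MSH6", "F", 0.7, 0),
    ("stomach", "PMS2", "M", 2.7, 1),
    ("stomach", "PMS2", "F", 0.0, 0),
    ("small_intestine", "MLH1", "M", 4.4, 1),
    ("small_intestine", "MLH1", "F", 2.5, 1),
    ("small_intestine", "MSH2", "M", 4.5, 1),
    ("small_intestine", "MSH2", "F", 3.2, 1),
    ("small_intestine", "MSH6", "M", 0.7, 0),
    ("small_intestine", "MSH6", "F", 0.6, 0),
    ("small_intestine", "PMS2", "M", 3.3, 1),
    ("small_intestine", "PMS2", "F", 2.1, 1),
    ("bile_duct", "MLH1", "M", 2.9, 2),
    ("bile_duct", "MLH1", "F", 1.5, 1),
    ("bile_duct", "MSH2", "M", 1.0, 1),
    ("bile_duct", "MSH2", "F", 0.8, 0),
    ("bile_duct", "MSH6", "M", 0.0, 0),
    ("bile_duct", "MSH6", "F", 0.0, 0),
    ("bile_duct", "PMS2", "M", 0.0, 0),
    ("bile_duct", "PMS2", "F", 0.0, 0),
    ("pancreas", "MLH1", "M", 1.1, 1),
    ("pancreas", "MLH1", "F", 1.9, 2),
    ("pancreas", "MSH2", "M", 1.4, 1),
    ("pancreas", "MSH2", "F", 1.2, 1),
    ("pancreas", "MSH6", "M", 0.0, 0),
    ("pancreas", "MSH6", "F", 0.7, 1),
    ("pancreas", "PMS2", "M", 0.0, 0),
    ("pancreas", "PMS2", "F", 0.0, 0),
    ("ureter_kidney", "MLH1", "M", 2.5, 1),
    ("ureter_kidney", "MLH1", "F", 1.7, 0),
    ("ureter_kidney", "MSH2", "M", 11.5, 3),
    ("ureter_kidney", "MSH2", "F", 9.7, 3),
    ("ureter_kidney", "MSH6", "M", 1.4, 0),
    ("ureter_kidney", "MSH6", "F", 3.2, 1),
    ("ureter_kidney", "PMS2", "M", 0.0, 0),
    ("ureter_kidney", "PMS2", "F", 0.0, 0),
    ("urinary_bladder", "MLH1", "M", 3.3, 1),
    ("urinary_bladder", "MLH1", "F", 1.3, 0),
    ("urinary_bladder", "MSH2", "M", 5.9, 2),
    ("urinary_bladder", "MSH2", "F", 4.7, 1),
    ("urinary_bladder", "MSH6", "M", 3.0, 1),
    ("urinary_bladder", "MSH6", "F", 1.8, 1),
    ("urinary_bladder", "PMS2", "M", 0.0, 0),
    ("urinary_bladder", "PMS2", "F", 0.0, 0),
    ("prostate", "MLH1", "M", 5.3, 1),
    ("prostate", "MSH2", "M", 10.6, 3),
    ("prostate", "MSH6", "M", 3.0, 1),
    ("prostate", "PMS2", "M", 3.3, 1),
    ("brain", "MLH1", "M", 0.0, 0),
    ("brain", "MLH1", "F", 0.9, 1),
    ("brain", "MSH2", "M", 3.3, 2),
    ("brain", "MSH2", "F", 1.4, 1),
    ("brain", "MSH6", "M", 0.8, 1),
    ("brain", "MSH6", "F", 1.2, 1),
    ("brain", "PMS2", "M", 0.0, 0),
    ("brain", "PMS2", "F", 7.3, 5),
]

#: Published deaths by cancer type and gene: (organ, gene, n cancers,
#: n deaths among those carriers).
DEATH_COUNTS: list[tuple[str, str, int, int]] = [
    ("colon", "MLH1", 241, 26),
    ("colon", "MSH2", 165, 20),
    ("colon", "MSH6", 22, 3),
    ("colon", "PMS2", 3, 1),
    ("endometrium", "MLH1", 93, 11),
    ("endometrium", "MSH2", 82, 11),
    ("endometrium", "MSH6", 36, 2),
    ("endometrium", "PMS2", 5, 0),
    ("rectum", "MLH1", 36, 8),
    ("rectum", "MSH2", 59, 15),
    ("rectum", "MSH6", 12, 3),
    ("rectum", "PMS2", 1, 0),
    ("ovary", "MLH1", 23, 2),
    ("ovary", "MSH2", 25, 5),
    ("ovary", "MSH6", 3, 0),
    ("ovary", "PMS2", 1, 0),
    ("ureter_kidney", "MLH1", 14, 5),
    ("ureter_kidney", "MSH2", 64, 11),
    ("ureter_kidney", "MSH6", 7, 0),
    ("ureter_kidney", "PMS2", 0, 0),
    ("urinary_bladder", "MLH1", 15, 3),
    ("urinary_bladder", "MSH2", 32, 8),
    ("urinary_bladder", "MSH6", 7, 0),
    ("urinary_bladder", "PMS2", 0, 0),
    ("prostate", "MLH1", 15, 3),
    ("prostate", "MSH2", 30, 6),
    ("prostate", "MSH6", 4, 0),
    ("prostate", "PMS2", 1, 0),
    ("stomach", "MLH1", 17, 10),
    ("stomach", "MSH2", 21, 5),
    ("stomach", "MSH6", 2, 1),
    ("stomach", "PMS2", 1, 0),
    ("small_intestine", "MLH1", 25, 7),
    ("small_intestine", "MSH2", 24, 5),
    ("small_intestine", "MSH6", 2, 0),
    ("small_intestine", "PMS2", 2, 0),
    ("bile_duct", "MLH1", 15, 9),
    ("bile_duct", "MSH2", 6, 2),
    ("bile_duct", "MSH6", 0, 0),
    ("bile_duct", "PMS2", 0, 0),
    ("pancreas", "MLH1", 11, 10),
    ("pancreas", "MSH2", 8, 4),
    ("pancreas", "MSH6", 1, 0),
    ("pancreas", "PMS2", 0, 0),
    ("brain", "MLH1", 4, 2),
    ("brain", "MSH2", 13, 9),
    ("brain", "MSH6", 3, 1),
    ("brain", "PMS2", 1, 1),
]

#: Cumulative incidence at 75 in female MLH1 carriers (percent): the
#: published illustration of overlap between single-organ and group curves.
FEMALE_MLH1_Q75 = {"colon": 46.2, "rectum": 7.4, "colorectum": 48.3}

#: Published cohort-level counts.
COHORT_COUNTS = {
    "n_carriers": 8500,
    "observation_years": 71713,
    "first_prospective_cancers": 1853,
    "ls_cancers": 1436,
    "colon_cancers": 481,
}
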