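"""Published group-level summary statistics of the reference SSRI cohort.

The raw EEG of the 41-patient MDD cohort this package models was never
deposited, but the study's printed group summaries (means ± SD, counts) are
sufficient inputs to recompute every group-level statistic it reports.
They are stored here as plain numbers: (n, mean, sd) triples per group per
variable, and the contingency counts of the stratifications.

All LDAEP values are Cz N1/P2 slopes in µV/dB; BDI is the Beck Depression
Inventory (integer score); 'reduction' is percent BDI change from baseline.
"""

from __future__ import annotations

#: Responder (>50% BDI reduction) vs nonresponder groups.
RESPONSE_GROUPS: dict = {
    "nonresponder": {
        "n": 16,
        "age": (16, 43.0, 17.8),
        "sex_mf": (4, 12),
        "episode_first_recurrent": (3, 13),
        "nonsmoker_smoker": (10, 6),
        "pretreatment_ldaep": {
            "N1": (16, -0.37, 0.53),
            "P2": (16, 0.58, 0.40),
            "N1P2": (16, 0.95, 0.59),
        },
        "posttreatment_ldaep": {
            "N1": (16, -0.44, 0.35),
            "P2": (16, 0.63, 0.73),
            "N1P2": (16, 1.07, 0.73),
        },
        "bdi_pre": (16, 28.9, 9.8),
        "bdi_post": (16, 25.6, 9.5),
    },
    "responder": {
        "n": 25,
        "age": (25, 38.4, 13.4),
        "sex_mf": (3, 22),
        "episode_first_recurrent": (12, 13),
        "nonsmoker_smoker": (21, 4),
        "pretreatment_ldaep": {
            "N1": (25, -0.41, 0.53),
            "P2": (25, 1.06, 0.82),
            "N1P2": (25, 1.47, 0.83),
        },
        "posttreatment_ldaep": {
            "N1": (25, -0.57, 0.67),
            "P2": (25, 0.90, 0.95),
            "N1P2": (25, 1.47, 0.95),
        },
        "bdi_pre": (25, 32.4, 13.8),
        "bdi_post": (25, 5.5, 4.8),
    },
}

#: Low vs high pretreatment N1/P2 LDAEP (median split) groups.
LDAEP_GROUPS: dict = {
    "low": {
        "n": 20,
        "age": (20, 44.2, 14.6),
        "sex_mf": (3, 17),
        "episode_first_recurrent": (5, 15),
        "nonsmoker_smoker": (12, 8),
        "pretreatment_ldaep": {
            "N1": (20, -0.18, 0.42),
            "P2": (20, 0.44, 0.44),
            "N1P2": (20, 0.62, 0.36),
        },
        "posttreatment_ldaep": {
            "N1": (20, -0.35, 0.58),
            "P2": (20, 0.39, 0.68),
            "N1P2": (20, 0.74, 0.68),
        },
        "bdi_pre": (20, 28.6, 10.6),
        "bdi_post": (20, 17.9, 13.0),
        "bdi_change_pct": (20, 37.2, 40.9),
        "responder_nonresponder": (9, 11),
    },
    "high": {
        "n": 21,
        "age": (21, 36.4, 15.1),
        "sex_mf": (4, 17),
        "episode_first_recurrent": (10, 11),
        "nonsmoker_smoker": (19, 2),
        "pretreatment_ldaep": {
            "N1": (21, -0.61, 0.54),
            "P2": (21, 1.28, 0.70),
            "N1P2": (21, 1.89, 0.52),
        },
        "posttreatment_ldaep": {
            "N1": (21, -0.68, 0.53),
            "P2": (21, 1.19, 0.86),
            "N1P2": (21, 1.87, 0.69),
        },
        "bdi_pre": (21, 33.4, 13.7),
        "bdi_post": (21, 9.1, 9.6),
        "bdi_change_pct": (21, 70.2, 36.2),
        "responder_nonresponder": (16, 5),
    },
}

#: Whole-cohort descriptives.
COHORT = {
    "n": 41,
    "sex_mf": (7, 34),
    "age": (41, 40.2, 15.2),
    "episode_first_recurrent": (15, 26),
    "smokers": 10,
    "hypnotics": 21,
}

#: Subgroup LDAEP summaries (sex / episode / hypnotics / smoking strata).
SUBGROUP_LDAEP = {
    "sex": {
        "male": {"n": 7, "pre": {"N1": (7, -0.42, 0.70), "P2": (7, 0.65, 0.63),
                                  "N1P2": (7, 1.06, 1.09)}},
        "female": {"n": 34, "pre": {"N1": (34, -0.39, 0.50), "P2": (34, 0.92, 0.74),
                                     "N1P2": (34, 1.31, 0.72)}},
    },
}


def response_counts_by_ldaep_group() -> list[list[int]]:
    """2x2 responder/nonresponder counts for the low and high LDAEP groups."""
    return [
        list(LDAEP_GROUPS["low"]["responder_nonresponder"]),
        list(LDAEP_GROUPS["high"]["responder_nonresponder"]),
    ]
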