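"""Worked-example datasets, as printed in the source reviews.

Three small tables ship with the package so every estimator can be
exercised against published numbers:

- ``table1``: 26 Pearson correlations (with 95% CIs and variances) from a
  psychotherapy preference-matching review; conventionally split into two
  sub-meta-analyses of studies 1-12 and 13-26.
- ``table2``: the same 26 studies re-expressed as a mixed-type dataset —
  studies 1-9 as standardized mean differences, 10-17 as log odds ratios,
  18-26 kept as correlations — each with 95% CIs.
- ``acl_odds_ratios``: summary odds ratios (with 95% CIs) of graft failure
  from two meta-analyses of anterior cruciate ligament reconstruction,
  comparing hamstring with bone-patellar-tendon-bone autografts.
"""

from __future__ import annotations

from .types import EffectEstimate, StudyTable

__all__ = ["table1", "table2", "acl_odds_ratios", "TABLE1_SPLIT"]

# study number, r, LL, UL, var(r)
_TABLE1 = [
    (1, 0.25, 0.04, 0.44, 0.0104),
    (2, 0.21, -0.02, 0.43, 0.0132),
    (3, 0.18, 0.00, 0.35, 0.0080),
    (4, 0.05, -0.15, 0.24, 0.0099),
    (5, 0.17, 0.00, 0.33, 0.0071),
    (6, 0.33, 0.09, 0.53, 0.0126),
    (7, 0.26, 0.02, 0.47, 0.0132),
    (8, 0.51, 0.24, 0.71, 0.0144),
    (9, 0.25, 0.03, 0.45, 0.0115),
    (10, -0.26, -0.45, -0.04, 0.0109),
    (11, 0.23, -0.04, 0.48, 0.0176),
    (12, 0.04, -0.24, 0.32, 0.0204),
    (13, 0.50, 0.25, 0.69, 0.0126),
    (14, 0.11, -0.28, 0.47, 0.0366),
    (15, 0.15, -0.04, 0.33, 0.0089),
    (16, 0.10, 0.00, 0.21, 0.0029),
    (17, 0.04, -0.19, 0.27, 0.0138),
    (18, 0.04, -0.12, 0.21, 0.0071),
    (19, 0.12, -0.03, 0.27, 0.0059),
    (20, 0.55, 0.15, 0.80, 0.0275),
    (21, -0.07, -0.31, 0.19, 0.0163),
    (22, 0.18, -0.26, 0.56, 0.0438),
    (23, 0.23, 0.00, 0.44, 0.0126),
    (24, 0.11, -0.14, 0.34, 0.0150),
    (25, 0.21, -0.14, 0.52, 0.0283),
    (26, -0.04, -0.15, 0.07, 0.0031),
]

#: The conventional split of table 1 into two sub-meta-analyses.
TABLE1_SPLIT = {"meta_1": range(1, 13), "meta_2": range(13, 27)}

# mixed-type re-expression: (study number, effect_type, estimate, LL, UL)
_TABLE2 = [
    (1, "smd", 0.52, 0.08, 0.98),
    (2, "smd", 0.43, -0.04, 0.95),
    (3, "smd", 0.37, 0.00, 0.75),
    (4, "smd", 0.10, -0.30, 0.49),
    (5, "smd", 0.35, 0.00, 0.70),
    (6, "smd", 0.70, 0.18, 1.25),
    (7, "smd", 0.54, 0.04, 1.06),
    (8, "smd", 1.19, 0.49, 2.02),
    (9, "smd", 0.52, 0.06, 1.01),
    (10, "log_or", -0.97, -1.82, -0.14),
    (11, "log_or", 0.86, -0.14, 1.98),
    (12, "log_or", 0.14, -0.89, 1.22),
    (13, "log_or", 2.09, 0.93, 3.45),
    (14, "log_or", 0.40, -1.06, 1.93),
    (15, "log_or", 0.55, -0.14, 1.27),
    (16, "log_or", 0.36, 0.00, 0.78),
    (17, "log_or", 0.14, -0.70, 1.02),
    (18, "r", 0.04, -0.12, 0.21),
    (19, "r", 0.12, -0.03, 0.27),
    (20, "r", 0.55, 0.15, 0.80),
    (21, "r", -0.07, -0.31, 0.19),
    (22, "r", 0.18, -0.26, 0.56),
    (23, "r", 0.23, 0.00, 0.44),
    (24, "r", 0.11, -0.14, 0.34),
    (25, "r", 0.21, -0.14, 0.52),
    (26, "r", -0.04, -0.15, 0.07),
]

# (meta label, OR, LL, UL)
_ACL = [
    ("biau_2006", 1.33, 0.73, 2.44),
    ("forster_2005", 1.09, 0.40, 2.96),
]


def table1(split: bool = False) -> StudyTable:
    """The 26-study correlation table.

    With ``split=True`` the records carry the conventional two-group
    labelling (studies 1-12 as ``meta_1``, 13-26 as ``meta_2``); otherwise
    all records share one group.
    """
    records = []
    for num, r, lo, up, var in _TABLE1:
        if split:
            meta_id = "meta_1" if num in TABLE1_SPLIT["meta_1"] else "meta_2"
        else:
            meta_id = "all"
        records.append(
            EffectEstimate(
                study_id=str(num),
                meta_id=meta_id,
                effect_type="r",
                estimate=r,
                variance=var,
                ci_lower=lo,
                ci_upper=up,
            )
        )
    return StudyTable(records)


def table2() -> StudyTable:
    """The mixed-type table: three groups reporting SMDs, log-ORs, and r.

    Variances are not tabulated; they derive from the printed 95% limits
    as (UL - LL)^2 / (2 x 1.96)^2 on ingestion.
    """
    group = {"smd": "smd_group", "log_or": "or_group", "r": "r_group"}
    return StudyTable(
        [
            EffectEstimate(
                study_id=str(num),
                meta_id=group[etype],
                effect_type=etype,
                estimate=est,
                ci_lower=lo,
                ci_upper=up,
            )
            for num, etype, est, lo, up in _TABLE2
        ]
    )


def acl_odds_ratios() -> list[tuple[str, float, float, float]]:
    """Summary (label, OR, LL, UL) of the two ACL-reconstruction meta-analyses."""
    return list(_ACL)
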