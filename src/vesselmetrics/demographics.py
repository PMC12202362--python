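"""Published baseline-characteristics tables used as statistics worked examples.

The clinical study this pipeline was built around compared healthy controls
against type 1 diabetics without retinopathy (NDR) and with non-proliferative
retinopathy (NPDR), and further split the NDR patients by disease duration
(< 5 years vs >= 5 years).  Its baseline tables print group sizes, age and
disease-duration summaries (mean ± SD, person counts) and sex/laterality
counts (sex in persons, laterality in eyes) together with the p-values of the
comparisons.  Since only the summaries were published — not the raw
measurements — these tables exercise :func:`vesselmetrics.stats.anova_from_summary`
and :func:`vesselmetrics.stats.chi_square_table`, and recomputing their
p-values is the statistics module's worked-example surface.
"""

from __future__ import annotations

import pandas as pd

from .stats import SummaryGroup, anova_from_summary, chi_square_table

# ---- main three-group comparison (control / NDR / NPDR) -------------------

#: age summaries in persons: (n, mean, SD); printed comparison p = 0.12
AGE_BY_GROUP = {
    "control": SummaryGroup(40, 25.00, 8.249),
    "NDR": SummaryGroup(51, 23.63, 9.556),
    "NPDR": SummaryGroup(12, 29.92, 12.362),
}

#: diabetes duration (years) in persons, NDR vs NPDR; printed p = 0.002
DURATION_BY_GROUP = {
    "NDR": SummaryGroup(51, 5.479, 5.427),
    "NPDR": SummaryGroup(12, 11.458, 6.747),
}

#: male/female person counts per group; printed chi-square p = 0.424
SEX_COUNTS = pd.DataFrame(
    {"male": [16, 26, 7], "female": [24, 25, 5]},
    index=["control", "NDR", "NPDR"],
)

#: left/right eye counts per group; printed chi-square p = 0.955
LATERALITY_COUNTS = pd.DataFrame(
    {"OS": [37, 46, 10], "OD": [33, 45, 9]},
    index=["control", "NDR", "NPDR"],
)

# ---- duration-subgroup comparison (control / <5 y / >=5 y) ----------------

#: printed comparison p = 0.105
AGE_BY_SUBGROUP = {
    "control": SummaryGroup(40, 25.00, 8.249),
    "lt5y": SummaryGroup(28, 21.36, 9.056),
    "ge5y": SummaryGroup(23, 26.39, 9.609),
}

#: printed chi-square p = 0.534
SEX_COUNTS_SUBGROUPS = pd.DataFrame(
    {"male": [16, 15, 11], "female": [24, 13, 12]},
    index=["control", "lt5y", "ge5y"],
)

#: printed chi-square p = 0.954
LATERALITY_COUNTS_SUBGROUPS = pd.DataFrame(
    {"OS": [37, 25, 21], "OD": [33, 24, 21]},
    index=["control", "lt5y", "ge5y"],
)


def baseline_worked_examples() -> pd.DataFrame:
    """Recompute every baseline-table comparison from its printed inputs.

    Returns one row per comparison with the test, statistic and p-value, all
    computed at call time from the summary data above.
    """
    rows = []
    f, d1, d2, p = anova_from_summary(list(AGE_BY_GROUP.values()))
    rows.append(("age_main_groups", "anova_from_summary", f, p))
    f, d1, d2, p = anova_from_summary(list(AGE_BY_SUBGROUP.values()))
    rows.append(("age_duration_subgroups", "anova_from_summary", f, p))
    f, d1, d2, p = anova_from_summary(list(DURATION_BY_GROUP.values()))
    rows.append(("duration_ndr_vs_npdr", "pooled_two_group", f, p))
    for name, counts in (
        ("sex_main_groups", SEX_COUNTS),
        ("laterality_main_groups", LATERALITY_COUNTS),
        ("sex_duration_subgroups", SEX_COUNTS_SUBGROUPS),
        ("laterality_duration_subgroups", LATERALITY_COUNTS_SUBGROUPS),
    ):
        chi2, dof, p = chi_square_table(counts.to_numpy())
        rows.append((name, "chi_square", chi2, p))
    return pd.DataFrame(rows, columns=["comparison", "test", "statistic", "p"])
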