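"""Cohort statistics: King's-stage odds ratios and survival ANOVA.

The 2x2 tables cross "being in King's stage s" with "being in survival
class c"; Woolf 95% intervals flag associations whose CI excludes 1.  The
first block reproduces the emulated cohort's published anchors directly from
its printed counts; the second recomputes everything on a synthetic cohort.
"""

from petsurv import generate_cohort, odds_ratio, one_way_anova, stage_class_or_table

# King's-1 row (88, 62, 20) against class sizes (255, 124, 39)
for cls, table in [(1, (88, 82, 167, 81)), (2, (62, 108, 62, 186))]:
    res = odds_ratio(table)
    print(
        f"King's 1 vs class {cls}: OR {res['or_']:.2f} "
        f"(95% CI {res['ci_low']:.2f}-{res['ci_high']:.2f})"
    )

cohort = generate_cohort("marginal", n=418, seed=0)
print("\nstage x class odds ratios on a synthetic cohort:")
table = stage_class_or_table(cohort)
print(
    table[["stage", "class", "odds_ratio", "ci_low", "ci_high", "significant"]]
    .round(2)
    .to_string(index=False)
)

f, p = one_way_anova(cohort["survival_years"], cohort["sex"])
print(f"\nsurvival-by-sex ANOVA: F = {f:.2f}, p = {p:.4f}")
# OR < 1 for (stage 1, class 1) means King's-1 patients are under-represented
# in the short-survival profile; the ANOVA detects the configured female
# survival advantage.
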