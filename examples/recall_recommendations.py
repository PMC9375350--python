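"""Turn significance patterns into risk-based recall intervals.

Feeds the rule engine the adjusted-p pattern of the published
increment comparisons: at the cavitated (3-6) cutoff only the
high-risk stratum shows significant increments (from 6 months on);
under A-6 the low- and high-risk strata do but the medium-risk
stratum does not.  The recommendation is the earliest significant
interval, or the 18-month horizon when none is.
"""

from carietrack import recommendation_table

pattern = {
    ("LOW", "3-6"): {6: 1.0, 12: 1.0, 18: 1.0},
    ("MEDIUM", "3-6"): {6: 0.5, 12: 0.24, 18: 0.05},
    ("HIGH", "3-6"): {6: 0.01, 12: 0.01, 18: 0.01},
    ("LOW", "A-6"): {6: 0.01, 12: 0.006, 18: 0.01},
    ("MEDIUM", "A-6"): {6: 0.5, 12: 0.84, 18: 0.98},
    ("HIGH", "A-6"): {6: 0.01, 12: 0.01, 18: 0.01},
}

table = recommendation_table(pattern)
print("Evidence-based recommendations:")
print(table[["cutoff", "risk", "months", "trigger"]].to_string(index=False))

print("\nWith the published-table override (A-6 capped at 6 months for all")
print("strata, including the non-significant medium-risk cell):")
table = recommendation_table(pattern, published_a6_override=True)
print(table[["cutoff", "risk", "months", "override"]].to_string(index=False))
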