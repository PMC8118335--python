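"""Genotype-level statistics: penetrance, Fisher's exact test, combined p.

Recomputes the two-locus penetrance table from printed genotype-class
counts, tests a candidate variant's case/control genotype split, and
combines association p-values across two breed cohorts.
"""

from breedrisk import combine_pvalues, fisher_exact
from breedrisk.stats import format_penetrance, penetrance_percent

# penetrance from published class counts (cases, controls)
classes = {
    "AaBb": (11, 17),
    "AaBB": (83, 21),
    "AABb": (11, 6),
    "AABB": (54, 12),
    "Aabb": (0, 5),
}
print("two-locus penetrance from genotype-class counts:")
for cls, (cases, controls) in classes.items():
    pen = format_penetrance(penetrance_percent(cases, controls))
    print(f"  {cls}: {cases:3d} cases / {controls:3d} controls -> {pen}%")
print("heterozygous at A, homozygous at B reaches 80% penetrance; "
      "heterozygous at both stays at 39%.\n")

# candidate-variant association: allele counts in 79 cases vs 69 controls
res = fisher_exact([[96, 62], [62, 76]])
print("candidate variant (allelic 2x2):")
print(f"  Fisher two-sided p = {res.p_value:.2e}")
print(f"  OR = {res.odds_ratio:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})\n")

# cross-cohort combination of the shared-interval association
p_breed1, p_breed2 = 3.43e-7, 2.00e-4
print(f"cohort p-values {p_breed1:.2e} and {p_breed2:.2e}:")
print(f"  Fisher combined  p = {combine_pvalues([p_breed1, p_breed2]):.2e}")
print(f"  Stouffer combined p = {combine_pvalues([p_breed1, p_breed2], 'stouffer'):.2e}")
print("both methods treat the cohorts as independent evidence for the "
      "same shared risk interval.")
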