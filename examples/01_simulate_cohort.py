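"""Simulate a breed cohort with an embedded two-locus cancer-risk architecture.

Generates genotypes for 177 cases and 132 controls at desk scale (2,000
SNPs over 4 chromosomes), with a contiguous risk haplotype at locus A, a
risk allele at locus B, and case status drawn from the two-locus
penetrance table. Writes the standard files a real study would start from
and prints the realised genotype-class structure.
"""

from pathlib import Path

from breedrisk import penetrance_table
from breedrisk.stats import format_penetrance
from breedrisk.synthetic import CohortConfig, simulate_genotypes, write_cohort

cfg = CohortConfig.desk_scale(
    n_snps=2000, n_chromosomes=4, n_cases=177, n_controls=132, seed=7
)
genotypes, truth = simulate_genotypes(cfg)

outdir = Path("scratch/example_cohort")
write_cohort(genotypes, truth, outdir)
print(f"wrote VCF/dosages/phenotypes/truth to {outdir}/")

s = truth.samples
print(f"\ncohort: {genotypes.n_samples} dogs x {genotypes.n_snps} SNPs; "
      f"{(s['phenotype'] == 1).sum()} cases / {(s['phenotype'] == 0).sum()} controls")
print(f"embedded risk haplotype: {truth.haplotype.chromosome}:"
      f"{truth.haplotype.span_1based[0]}-{truth.haplotype.span_1based[1]} "
      f"({truth.haplotype.interval.length_mb} Mb), lead SNP {truth.haplotype.lead_snp_id}")
print(f"locus B lead SNP: {truth.locus_b_snp}")

tab = penetrance_table(s["a_dosage"], s["b_dosage"], s["phenotype"])
tab["penetrance"] = tab["penetrance_pct"].map(format_penetrance)
print("\nrealised two-locus genotype classes (A = risk haplotype, B = risk allele):")
print(tab[["cases", "controls", "penetrance"]].to_string())
print("\npenetrance = percent of dogs in each class who are cases; the "
      "AaBB and AABB classes carry the configured ~80% risk.")
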