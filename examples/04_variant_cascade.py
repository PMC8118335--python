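"""Filter WGS variants down to regulatory candidates on the risk haplotype.

Three steps: segregation with each genome's known haplotype dosage, a
strict panel allele-frequency cutoff (AF < 0.5 in other breeds), and
overlap with promoter/enhancer/open-chromatin intervals. Run on the
simulated WGS layer of a desk-scale cohort.
"""

from breedrisk import run_cascade
from breedrisk.synthetic import CohortConfig, simulate_genotypes, simulate_wgs_panel

cfg = CohortConfig.desk_scale(
    n_snps=2000, n_chromosomes=4, n_cases=177, n_controls=132, seed=7
)
genotypes, truth = simulate_genotypes(cfg)
panel = simulate_wgs_panel(cfg, truth)

print("WGS design (sample: expected risk-haplotype dosage):")
for sp in panel.spec:
    print(f"  {sp.sample_id}: {sp.expected_dosage}")

report = run_cascade(panel.variants, panel.spec, panel.panel_af,
                     panel.regulatory, max_af=0.5)
print(f"\ninput variants             : {report.n_input}")
print(f"segregating with haplotype : {report.n_segregating}")
print(f"panel AF < 0.5             : {report.n_rare}")
print(f"in regulatory intervals    : {report.n_regulatory}")
print("\nsurviving candidates with their regulatory sources:")
print(report.variants[["position", "ref", "alt", "panel_af",
                       "regulatory_sources"]].head(8).to_string(index=False))
print("\neach survivor rides the risk haplotype in every genome, is rare "
      "across other breeds, and sits in regulatory DNA — the shortlist for "
      "binding-site analysis.")
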