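import numpy as np
import pandas as pd
import pytest

import breedrisk as br
from breedrisk.expression import ase_test
from breedrisk.stats import penetrance_table
from breedrisk.synthetic import (
    CohortConfig,
    PenetranceInfeasibleError,
    SyntheticTruth,
    simulate_expression,
    simulate_genotypes,
    simulate_wgs_panel,
    write_cohort,
)


class TestGenotypeSimulation:
    def test_same_seed_identical_output(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        gm2, truth2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(gm.dosages, gm2.dosages)
        pd.testing.assert_frame_equal(truth.samples, truth2.samples)

    def test_different_seed_differs(self, desk_cohort):
        cfg, gm, _ = desk_cohort
        cfg2 = CohortConfig.desk_scale(
            n_snps=800, n_chromosomes=4, n_cases=60, n_controls=50, seed=43
        )
        gm2, _ = simulate_genotypes(cfg2)
        assert not np.array_equal(gm.dosages, gm2.dosages)

    def test_quotas_and_dosage_domain(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        assert (truth.samples["phenotype"] == 1).sum() == cfg.n_cases
        assert (truth.samples["phenotype"] == 0).sum() == cfg.n_controls
        assert np.isin(gm.dosages, [0.0, 1.0, 2.0]).all()

    def test_control_ages_respect_minimum(self, desk_cohort):
        cfg, _, truth = desk_cohort
        controls = truth.samples[truth.samples["phenotype"] == 0]
        assert (controls["age"] >= cfg.control_min_age).all()

    def test_haplotype_dosage_recoverable_from_truth(self, desk_cohort):
        _, gm, truth = desk_cohort
        hd = br.haplotype_dosage(gm, truth.haplotype)
        np.testing.assert_array_equal(hd, truth.samples["a_dosage"].to_numpy())

    def test_infeasible_penetrance_raises(self):
        cfg = CohortConfig.desk_scale(
            n_snps=200,
            n_chromosomes=2,
            n_cases=50,
            n_controls=5,
            penetrance={k: 0.0 for k in br.synthetic.DEFAULT_PENETRANCE},
            max_draw_factor=5,
            seed=1,
        )
        with pytest.raises(PenetranceInfeasibleError):
            simulate_genotypes(cfg)

    def test_empirical_penetrance_within_binomial_ci(self):
        cfg = CohortConfig.desk_scale(n_snps=100, n_chromosomes=2, seed=7)
        _, truth = simulate_genotypes(cfg, unconditional_n=10_000)
        tab = penetrance_table(
            truth.samples["a_dosage"],
            truth.samples["b_dosage"],
            truth.samples["phenotype"],
        )
        # 3-SE binomial bounds: testing several classes at once against a
        # 95% band would fail ~20% of seeds by construction
        for cls in ["AaBB", "AaBb", "AABB", "aaBB"]:
            n = int(tab.loc[cls, "cases"] + tab.loc[cls, "controls"])
            k = int(tab.loc[cls, "cases"])
            p0 = cfg.penetrance[cls]
            tol = 3 * np.sqrt(n * p0 * (1 - p0))
            assert abs(k - n * p0) <= tol, (
                f"{cls}: {k}/{n} vs configured {p0}"
            )

    def test_allele_frequencies_converge(self):
        cfg = CohortConfig.desk_scale(n_snps=120, n_chromosomes=2, seed=3)
        gm, truth = simulate_genotypes(cfg, unconditional_n=10_000)
        # generative SE combines founder-pool sampling and cohort sampling
        p_anc = truth.ancestral_freqs
        emp = gm.dosages.mean(axis=0) / 2.0
        pq = p_anc * (1 - p_anc)
        # two subpops, each with its own pool: total variance adds the
        # Balding-Nichols between-subpop term F*pq/2 as well
        se = np.sqrt(
            pq / (2 * cfg.n_founder_haplotypes)
            + cfg.fst * pq / 2
            + pq / (2 * 10_000)
        )
        inside = np.abs(emp - p_anc) <= 3 * se
        # exclude SNPs overwritten by the embedded loci
        chrom_a = cfg.risk_locus_a.chromosome
        a_mask = (
            (gm.chromosomes == chrom_a)
            & (gm.positions >= cfg.risk_locus_a.start)
            & (gm.positions <= cfg.risk_locus_a.end)
        )
        b_mask = np.array(
            [sid == f"snp_{cfg.risk_locus_b.chromosome}_{cfg.risk_locus_b.start}"
             for sid in gm.snp_ids]
        )
        free = ~(a_mask | b_mask)
        assert inside[free].mean() > 0.98

    def test_null_penetrance_gives_uniform_gwas(self):
        flat = {k: 0.3 for k in br.synthetic.DEFAULT_PENETRANCE}
        cfg = CohortConfig.desk_scale(
            n_snps=600, n_chromosomes=3, n_cases=80, n_controls=80,
            penetrance=flat, seed=9,
        )
        gm, truth = simulate_genotypes(cfg)
        y = truth.samples["phenotype"].to_numpy(dtype=float)
        res = br.lmm_wald(gm, y)
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.02 <= frac <= 0.09
        assert 0.8 <= res.lambda_gc <= 1.2

    def test_embedded_association_detected(self, desk_cohort):
        _, gm, truth = desk_cohort
        y = truth.samples["phenotype"].to_numpy(dtype=float)
        res = br.lmm_wald(gm, y)
        top = res.top_hit()
        # strongest signal lands at one of the embedded loci
        s1, e1 = truth.haplotype.span_1based
        on_a = (
            top["chromosome"] == truth.haplotype.chromosome
            and s1 <= top["position"] <= e1
        )
        on_b = top["snp_id"] == truth.locus_b_snp
        assert on_a or on_b


class TestExpressionSimulation:
    def test_fold_change_recovered_at_scale(self):
        cfg = CohortConfig.desk_scale(
            n_snps=200, n_chromosomes=2, n_cases=300, n_controls=300,
            n_rna_cases=50, n_rna_controls=50, n_genes=400, seed=21,
        )
        gm, truth = simulate_genotypes(cfg)
        es = simulate_expression(cfg, truth)
        hom = es.groups[es.groups == "hom_risk"].index
        het = es.groups[es.groups == "het_risk"].index
        sf = es.size_factors
        norm = es.counts.div(sf, axis=1)
        ratio = norm.loc[truth.de_gene, hom].mean() / norm.loc[truth.de_gene, het].mean()
        # 2x the sampling error of the group-mean ratio at n=50/group
        se_ln = np.sqrt(2 * cfg.nb_dispersion / 50)
        assert abs(np.log(ratio) - np.log(10.9)) < 2 * se_ln * 3

    def test_null_ase_ratio_type_one_rate(self):
        cfg = CohortConfig.desk_scale(
            n_snps=200, n_chromosomes=2, n_cases=60, n_controls=60,
            ase_ratio=0.5, n_ase_variants=20, seed=22,
        )
        gm, truth = simulate_genotypes(cfg)
        es = simulate_expression(cfg, truth)
        rec, _ = ase_test(es.allele_counts)
        frac = rec.loc[rec["tested"], "significant"].mean()
        assert frac < 0.12  # near the nominal 5% type-I rate

    def test_strong_ase_detected_with_power(self):
        # allelic ratio 0.9 at depth 100: chi-square significant in >95%
        rng = np.random.default_rng(23)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            alt = rng.binomial(100, 0.9)
            rec = pd.DataFrame(
                {"variant": ["v"], "sample": ["s"],
                 "ref_count": [100 - alt], "alt_count": [alt]}
            )
            out, _ = ase_test(rec)
            hits += int(out["p"].iloc[0] <= 0.05)
        assert hits / n_rep > 0.95

    def test_negative_fold_change_rejected(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        bad = CohortConfig.desk_scale(
            n_snps=800, n_chromosomes=4, n_cases=60, n_controls=50,
            seed=42, de_fold_change=-1.0,
        )
        with pytest.raises(ValueError, match="positive"):
            simulate_expression(bad, truth)


class TestWgsSimulation:
    def test_cascade_recovers_constructed_structure(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        panel = simulate_wgs_panel(cfg, truth)
        report = br.run_cascade(panel.variants, panel.spec, panel.panel_af,
                                panel.regulatory)
        # all concordant variants survive segregation; discordant decoys do not
        assert report.n_segregating == cfg.n_haplotype_variants
        assert report.n_rare < report.n_segregating
        assert report.n_regulatory < report.n_rare

    def test_zero_haplotype_variants_empty_cascade(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        cfg0 = CohortConfig.desk_scale(
            n_snps=800, n_chromosomes=4, n_cases=60, n_controls=50,
            seed=42, n_haplotype_variants=0, n_off_haplotype_variants=10,
        )
        panel = simulate_wgs_panel(cfg0, truth)
        report = br.run_cascade(panel.variants, panel.spec, panel.panel_af,
                                panel.regulatory)
        assert report.counts == (0, 0, 0)

    def test_motif_variant_creates_consensus_site(self, desk_cohort):
        cfg, gm, truth = desk_cohort
        panel = simulate_wgs_panel(cfg, truth)
        assert truth.causal_variants
        chrom, pos, alleles = truth.causal_variants[0]["variant"].split(":")
        ref, alt = alleles.split(">")
        pair = br.make_allele_windows(panel.reference, chrom, int(pos), ref, alt)
        calls = br.consensus_call(pair, panel.motifs)
        assert calls[0].consensus
        assert calls[0].preferred_allele == "risk"


class TestRoundTrips:
    def test_cohort_files_round_trip(self, desk_cohort, tmp_path):
        cfg, gm, truth = desk_cohort
        panel = simulate_wgs_panel(cfg, truth)
        write_cohort(gm, truth, tmp_path, panel)
        back_vcf = br.read_genotypes(tmp_path / "genotypes.vcf")
        np.testing.assert_array_equal(back_vcf.dosages, gm.dosages)
        back_dos = br.read_genotypes(tmp_path / "dosages.tsv")
        np.testing.assert_array_equal(back_dos.dosages, gm.dosages)
        pheno = br.read_phenotypes(tmp_path / "phenotypes.tsv")
        assert (pheno["phenotype"] == truth.samples["phenotype"]).all()
        t2 = SyntheticTruth.from_yaml(tmp_path / "truth.yaml")
        assert t2.haplotype.span_1based == truth.haplotype.span_1based
        assert t2.locus_b_snp == truth.locus_b_snp
        motifs = br.read_meme_motifs(tmp_path / "motifs.meme")
        assert motifs[0]["id"] == panel.motifs[0].motif_id
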