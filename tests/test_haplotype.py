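import numpy as np
import pytest

from breedrisk.haplotype import (
    RiskHaplotype,
    block_uniqueness,
    compare_haplotypes,
    delineate_risk_haplotype,
    haplotype_dosage,
    ld_r2,
    sharing_profile,
)
from breedrisk.io import Interval
from breedrisk.synthetic import delineation_fixture
from conftest import make_genotype_matrix


class TestDelineation:
    def test_recovers_embedded_interval_exactly(self):
        gm, y, lead, risk, expected = delineation_fixture(n_recombinants=3)
        hap = delineate_risk_haplotype(gm, y, lead, risk)
        assert hap.span_1based == expected.to_1based()[1:]

    @pytest.mark.parametrize("n_recomb", [0, 2])
    def test_below_threshold_losses_extend_to_chromosome_ends(self, n_recomb):
        gm, y, lead, risk, _ = delineation_fixture(n_recombinants=n_recomb)
        hap = delineate_risk_haplotype(gm, y, lead, risk, loss_threshold=3)
        assert hap.span_1based == (int(gm.positions.min()), int(gm.positions.max()))

    def test_interval_never_extends_past_first_qualifying_loss(self):
        # recombination on one side only
        gm, y, lead, risk, expected = delineation_fixture(
            n_recombinants=4, seed=3
        )
        hap = delineate_risk_haplotype(gm, y, lead, risk)
        s1, e1 = expected.to_1based()[1:]
        assert hap.span_1based[0] >= s1
        assert hap.span_1based[1] <= e1

    def test_absent_lead_snp_rejected(self):
        gm, y, _, risk, _ = delineation_fixture()
        with pytest.raises(KeyError):
            delineate_risk_haplotype(gm, y, "nope", risk)

    def test_no_carriers_rejected(self):
        # every case homozygous alt at the lead; asking for the ref allele
        # leaves no case carrier
        dos = np.array([[2, 1], [2, 0], [0, 1.0]])
        gm = make_genotype_matrix(dos)
        y = np.array([1, 1, 0])
        with pytest.raises(ValueError, match="no case carries"):
            delineate_risk_haplotype(gm, y, "snp0", "A")

    def test_wrong_allele_label_rejected(self):
        gm, y, lead, _, _ = delineation_fixture()
        with pytest.raises(ValueError, match="neither ref nor alt"):
            delineate_risk_haplotype(gm, y, lead, "T")


class TestSharingProfile:
    def test_lead_retaining_fraction_is_one_and_nonincreasing(self):
        gm, y, lead, risk, _ = delineation_fixture()
        hap = delineate_risk_haplotype(gm, y, lead, risk)
        prof = sharing_profile(gm, y, hap)
        t = prof.table
        lead_row = t[t["snp_id"] == lead]
        assert lead_row["case_retaining"].iloc[0] == 1.0
        # non-increasing away from the lead on both sides
        k = t.index[t["snp_id"] == lead][0]
        right = t["case_retaining"].iloc[k:].to_numpy()
        left = t["case_retaining"].iloc[k::-1].to_numpy()
        assert (np.diff(right) <= 1e-12).all()
        assert (np.diff(left) <= 1e-12).all()

    def test_engineered_recombination_steps_to_half(self):
        # 8 homozygous case carriers plus 2 non-carrier controls; half the
        # carriers recombine just right of SNP 5
        n_snps = 10
        dos = np.vstack([np.full((8, n_snps), 2.0), np.zeros((2, n_snps))])
        dos[:4, 6:] = 0.0
        gm = make_genotype_matrix(dos)
        y = np.array([1] * 8 + [0] * 2)
        hap = delineate_risk_haplotype(gm, y, "snp3", "G", loss_threshold=99)
        prof = sharing_profile(gm, y, hap)
        ret = prof.table["case_retaining"].to_numpy()
        np.testing.assert_allclose(ret[:6], 1.0)
        np.testing.assert_allclose(ret[6:], 0.5)

    def test_empty_control_group_flagged_not_zero(self):
        gm, y, lead, risk, _ = delineation_fixture(n_controls=5)
        # make all controls non-carriers at the lead
        lead_j = gm.snp_index(lead)
        gm.dosages[y == 0, lead_j] = 0.0
        hap = delineate_risk_haplotype(gm, y, lead, risk)
        prof = sharing_profile(gm, y, hap)
        assert prof.control_group_empty
        assert prof.table["control_retaining"].isna().all()


class TestLd:
    def test_identical_vectors_r2_one(self):
        gm = make_genotype_matrix(np.array([[0, 0], [1, 1], [2, 2], [0, 0.0]]))
        assert ld_r2(gm, "snp0", "snp1") == pytest.approx(1.0)

    def test_perfect_negative_correlation_r2_one(self):
        gm = make_genotype_matrix(np.array([[0, 2], [1, 1], [2, 0], [0, 2.0]]))
        assert ld_r2(gm, "snp0", "snp1") == pytest.approx(1.0)

    def test_orthogonal_vectors_r2_zero(self):
        gm = make_genotype_matrix(np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]]))
        assert ld_r2(gm, "snp0", "snp1") == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_allele_reflection_invariance(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(40, 2)).astype(float)
        gm = make_genotype_matrix(dos)
        r_ab = ld_r2(gm, "snp0", "snp1")
        r_ba = ld_r2(gm, "snp1", "snp0")
        gm_ref = make_genotype_matrix(np.column_stack([2 - dos[:, 0], dos[:, 1]]))
        assert r_ab == pytest.approx(r_ba)
        assert r_ab == pytest.approx(ld_r2(gm_ref, "snp0", "snp1"))

    def test_monomorphic_snp_flagged_nan(self):
        gm = make_genotype_matrix(np.array([[1, 0], [1, 1], [1, 2.0]]))
        with pytest.warns(UserWarning, match="monomorphic"):
            assert np.isnan(ld_r2(gm, "snp0", "snp1"))


def _hap(chrom, start, end, lead_pos, positions=None, alleles=None):
    positions = positions if positions is not None else [start, lead_pos, end]
    alleles = alleles if alleles is not None else [1] * len(positions)
    return RiskHaplotype(
        chromosome=chrom,
        lead_snp_id="lead",
        lead_position=lead_pos,
        risk_allele="G",
        risk_allele_is_alt=True,
        interval=Interval.from_1based(chrom, start, end),
        snp_ids=[f"m{i}" for i in range(len(positions))],
        positions=np.asarray(positions),
        case_alleles=np.asarray(alleles),
    )


class TestCompareHaplotypes:
    def test_study_coordinates_shared_631kb(self):
        fcr = _hap("chr5", 32389061, 33633274, 33001550)
        gr = _hap("chr5", 33001663, 34362236, 34117726)
        overlap = compare_haplotypes(fcr, gr)
        assert overlap.length_kb == 631

    def test_different_chromosomes_empty_with_warning(self):
        h1 = _hap("chr5", 100, 200, 150)
        h2 = _hap("chr19", 100, 200, 150)
        with pytest.warns(UserWarning):
            overlap = compare_haplotypes(h1, h2)
        assert overlap.shared.is_empty

    def test_allele_agreement_on_shared_span(self):
        h1 = _hap("chr1", 100, 300, 200, positions=[100, 200, 300], alleles=[1, 1, 0])
        h2 = _hap("chr1", 150, 400, 200, positions=[200, 300, 400], alleles=[1, 0, 1])
        assert compare_haplotypes(h1, h2).alleles_agree is True
        h3 = _hap("chr1", 150, 400, 200, positions=[200, 300, 400], alleles=[0, 0, 1])
        assert compare_haplotypes(h1, h3).alleles_agree is False


class TestHaplotypeDosage:
    def test_dosage_classes(self):
        # 3 interval SNPs, case alleles all alt
        dos = np.array(
            [
                [2, 2, 2],   # hom throughout -> 2
                [1, 2, 1],   # carrier everywhere, not hom -> 1
                [2, 0, 2],   # breaks in the middle -> 0
                [0, 0, 0],   # non-carrier -> 0
            ],
            dtype=float,
        )
        gm = make_genotype_matrix(dos)
        hap = RiskHaplotype(
            chromosome="chr1",
            lead_snp_id="snp1",
            lead_position=2000,
            risk_allele="G",
            risk_allele_is_alt=True,
            interval=Interval.from_1based("chr1", 1000, 3000),
            snp_ids=["snp0", "snp1", "snp2"],
            positions=np.array([1000, 2000, 3000]),
            case_alleles=np.array([1, 1, 1]),
        )
        np.testing.assert_array_equal(haplotype_dosage(gm, hap), [2, 1, 0, 0])


class TestBlockUniqueness:
    def test_target_identical_to_background_no_blocks(self):
        t = np.array([[0, 1, 0, 1]])
        b = np.array([[0, 1, 0, 1], [1, 1, 1, 1]])
        assert block_uniqueness(t, b) == []

    def test_three_variant_private_run(self):
        # target's alleles at sites 2-4 form a combination absent from all
        # backgrounds, but every 2-site sub-window occurs in a background
        t = np.array([[0, 0, 1, 1, 1, 0]])
        b = np.array(
            [
                [0, 0, 1, 1, 0, 0],
                [0, 0, 0, 1, 1, 0],
                [1, 0, 1, 0, 1, 0],
            ]
        )
        blocks = block_uniqueness(t, b)
        assert [(bl.start_site, bl.end_site) for bl in blocks] == [(2, 4)]

    def test_single_private_variant_is_length_one_block(self):
        t = np.array([[1, 0]])
        b = np.array([[0, 0], [0, 0]])
        blocks = block_uniqueness(t, b)
        assert [(bl.start_site, bl.end_site) for bl in blocks] == [(0, 0)]
        assert blocks[0].n_sites == 1
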