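"""Synthetic breed-cohort generator.

Emulates the statistical structure of a two-subpopulation breed cohort
segregating a contiguous risk haplotype at one locus (A) and a risk
allele at a second locus (B), with case/control status drawn from a
two-locus penetrance table. Downstream stages — mixed-model GWAS,
haplotype delineation, the variant filter cascade, expression and
motif-binding analyses — can all be exercised against the recorded truth
without any external data.

Defaults mirror the study conditions wherever the study prints them:
177 cases / 132 controls genotyped at ~108k SNPs on 38 autosomes; the
two-locus penetrance table (unobserved classes at a 5% background risk);
risk-allele frequencies 0.403 (haplotype A) and 0.786 (lead SNP B)
recomputed from the printed control genotype counts; a >=10-year minimum
control age. Haplotype structure follows a founder-pool block-copying
model — a breed-bottleneck analogue with configurable block length —
and the two subpopulations differ by a Balding-Nichols F_ST of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    GenotypeMatrix,
    Interval,
    IntervalSet,
    write_bed,
    write_dosage_matrix,
    write_fasta,
    write_meme_motifs,
    write_phenotypes,
    write_vcf_genotypes,
)
from .haplotype import RiskHaplotype
from .motif import MotifModel
from .prioritize import SampleSpec

#: Two-locus penetrance: proportion of dogs in each genotype class who are
#: cases. Observed classes use the printed table; classes never observed
#: in the cohort default to a 5% background risk (unobserved != impossible).
DEFAULT_PENETRANCE: dict[str, float] = {
    "aabb": 0.05,
    "aaBb": 0.30,
    "aaBB": 0.33,
    "Aabb": 0.05,
    "AaBb": 0.39,
    "AaBB": 0.80,
    "AAbb": 0.05,
    "AABb": 0.65,
    "AABB": 0.82,
}


@dataclass(frozen=True)
class LocusConfig:
    """A risk locus: an interval (locus A) or a single lead SNP (locus B,
    start == end) with the risk-allele/haplotype frequency."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    allele_freq: float

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele frequency must be in (0, 1)")
        if self.start > self.end:
            raise ValueError("locus start after end")


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_cases: int = 177
    n_controls: int = 132
    n_snps: int = 108_084
    n_chromosomes: int = 38
    snp_spacing_bp: int = 20_000
    subpop_fraction: float = 0.5
    fst: float = 0.05
    ld_block_length: int = 500_000
    n_founder_haplotypes: int = 16
    risk_locus_a: LocusConfig = field(
        default_factory=lambda: LocusConfig("chr5", 32_389_061, 33_633_274, 0.403)
    )
    risk_locus_b: LocusConfig = field(
        default_factory=lambda: LocusConfig("chr19", 52_487_724, 52_487_724, 0.786)
    )
    penetrance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PENETRANCE)
    )
    control_min_age: float = 10.0
    control_age_span: float = 4.0
    case_age_range: tuple[float, float] = (4.0, 12.0)
    max_draw_factor: int = 1000
    seed: int = 0
    # expression block
    n_genes: int = 2000
    n_rna_cases: int = 4        # homozygous-B cases in the DE contrast
    n_rna_controls: int = 7     # heterozygous-B samples in the DE contrast
    de_fold_change: float = 10.9
    nb_dispersion: float = 0.1
    n_ase_variants: int = 6
    ase_ratio: float = 0.7
    ase_depth: int = 60
    # WGS block
    n_haplotype_variants: int = 284
    n_off_haplotype_variants: int = 60
    frac_rare: float = 218.0 / 284.0        # panel AF < 0.5 among concordant
    frac_regulatory: float = 98.0 / 218.0   # regulatory overlap among rare

    def __post_init__(self) -> None:
        for cls, pen in self.penetrance.items():
            if not 0.0 <= pen <= 1.0:
                raise ValueError(f"penetrance[{cls}] outside [0, 1]")
        if not 0.0 <= self.subpop_fraction <= 1.0:
            raise ValueError("subpop_fraction must be in [0, 1]")
        if self.n_cases < 0 or self.n_controls < 0 or self.n_snps < 1:
            raise ValueError("cohort sizes must be positive")

    @classmethod
    def desk_scale(cls, n_snps: int = 2000, n_chromosomes: int = 4,
                   **overrides) -> "CohortConfig":
        """A small, internally-consistent configuration for simulations.

        Places locus A across the middle fifth of the first chromosome and
        locus B mid-way along the last one, with the same frequencies and
        penetrances as the full-scale default.
        """
        spacing = overrides.pop("snp_spacing_bp", 20_000)
        per_chrom = n_snps // n_chromosomes
        chrom_len = per_chrom * spacing
        a = LocusConfig("chr1", int(chrom_len * 0.4), int(chrom_len * 0.6), 0.403)
        b_pos = (per_chrom // 2) * spacing
        b = LocusConfig(f"chr{n_chromosomes}", b_pos, b_pos, 0.786)
        return cls(
            n_snps=n_snps,
            n_chromosomes=n_chromosomes,
            snp_spacing_bp=spacing,
            risk_locus_a=overrides.pop("risk_locus_a", a),
            risk_locus_b=overrides.pop("risk_locus_b", b),
            **overrides,
        )


@dataclass
class SyntheticTruth:
    """Everything embedded in a simulated cohort, for downstream checks."""

    haplotype: RiskHaplotype
    locus_b_snp: str
    penetrance: dict[str, float]
    samples: pd.DataFrame  # sample_id, subpop, a_dosage, b_dosage, phenotype, age
    de_gene: str | None = None
    de_fold_change: float | None = None
    ase_variants: list[dict] = field(default_factory=list)
    causal_variants: list[dict] = field(default_factory=list)
    true_pve_per_region: dict[str, float] = field(default_factory=dict)
    ancestral_freqs: np.ndarray | None = None  # per-SNP, not serialised

    def to_yaml(self, path: str | Path) -> None:
        h = self.haplotype
        doc = {
            "haplotype": {
                "chromosome": h.chromosome,
                "lead_snp_id": h.lead_snp_id,
                "lead_position": int(h.lead_position),
                "risk_allele": h.risk_allele,
                "interval_1based": list(h.span_1based),
                "snp_ids": list(h.snp_ids),
                "positions": [int(p) for p in h.positions],
                "case_alleles": [int(a) for a in h.case_alleles],
            },
            "locus_b_snp": self.locus_b_snp,
            "penetrance": {k: float(v) for k, v in self.penetrance.items()},
            "samples": self.samples.to_dict(orient="list"),
            "de_gene": self.de_gene,
            "de_fold_change": self.de_fold_change,
            "ase_variants": self.ase_variants,
            "causal_variants": self.causal_variants,
            "true_pve_per_region": self.true_pve_per_region,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        h = doc["haplotype"]
        s1, e1 = h["interval_1based"]
        hap = RiskHaplotype(
            chromosome=h["chromosome"],
            lead_snp_id=h["lead_snp_id"],
            lead_position=h["lead_position"],
            risk_allele=h["risk_allele"],
            risk_allele_is_alt=True,
            interval=Interval.from_1based(h["chromosome"], s1, e1),
            snp_ids=h["snp_ids"],
            positions=np.asarray(h["positions"], dtype=np.int64),
            case_alleles=np.asarray(h["case_alleles"], dtype=int),
        )
        return cls(
            haplotype=hap,
            locus_b_snp=doc["locus_b_snp"],
            penetrance=doc["penetrance"],
            samples=pd.DataFrame(doc["samples"]),
            de_gene=doc.get("de_gene"),
            de_fold_change=doc.get("de_fold_change"),
            ase_variants=doc.get("ase_variants", []),
            causal_variants=doc.get("causal_variants", []),
            true_pve_per_region=doc.get("true_pve_per_region", {}),
        )


class PenetranceInfeasibleError(RuntimeError):
    """The penetrance table cannot produce the requested case count."""


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def _snp_map(config: CohortConfig):
    per_chrom = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_snps % config.n_chromosomes):
        per_chrom[i] += 1
    chroms, poss = [], []
    for c, m in enumerate(per_chrom, start=1):
        chroms.extend([f"chr{c}"] * m)
        poss.extend(config.snp_spacing_bp * (np.arange(m) + 1))
    return np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)


def _nearest_snp(chroms, poss, chrom: str, position: int) -> int:
    idx = np.flatnonzero(chroms == chrom)
    if idx.size == 0:
        raise ValueError(f"no SNPs on {chrom}; configure loci inside the map")
    return int(idx[np.argmin(np.abs(poss[idx] - position))])


def _hwe_dosage(rng, freq: float, size: int) -> np.ndarray:
    return rng.binomial(2, freq, size=size)


def simulate_genotypes(
    config: CohortConfig,
    unconditional_n: int | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate the genotyped cohort and its ground truth.

    Haplotypes are copied in LD blocks from subpopulation-specific founder
    pools (Balding-Nichols differentiated); individuals carrying d copies
    of the risk haplotype have d of their two chromatids overwritten with
    the case-associated allele string across the locus-A interval, and the
    locus-B lead-SNP genotype is drawn from its configured frequency.
    Case/control status is Bernoulli per the two-locus penetrance; drawing
    stops when both quotas are filled or after
    ``max_draw_factor * (n_cases + n_controls)`` attempts
    (:class:`PenetranceInfeasibleError`).

    With ``unconditional_n`` the case/control quotas are ignored and
    exactly that many individuals are drawn with their natural case
    status — the sampling design for checking empirical penetrance and
    allele frequencies, which quota-filling would condition (and hence
    bias) away from the configured values.
    """
    rng = np.random.default_rng(config.seed)
    chroms, poss = _snp_map(config)
    n_snps = len(chroms)

    a = config.risk_locus_a
    b = config.risk_locus_b
    a_sites = np.flatnonzero(
        (chroms == a.chromosome) & (poss >= a.start) & (poss <= a.end)
    )
    if a_sites.size < 2:
        raise ValueError("risk locus A spans fewer than 2 SNPs")
    b_site = _nearest_snp(chroms, poss, b.chromosome, b.start)
    lead_site = int(a_sites[len(a_sites) // 2])

    # per-SNP ancestral and subpopulation frequencies (Balding-Nichols)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    F = config.fst
    if F > 0:
        shape1 = p_anc * (1 - F) / F
        shape2 = (1 - p_anc) * (1 - F) / F
        p_sub = np.stack([rng.beta(shape1, shape2), rng.beta(shape1, shape2)])
        p_sub = np.clip(p_sub, 0.01, 0.99)
    else:
        p_sub = np.stack([p_anc, p_anc])

    # founder haplotype pools per subpopulation
    n_f = config.n_founder_haplotypes
    founders = (
        rng.random((2, n_f, n_snps)) < p_sub[:, None, :]
    ).astype(np.int8)

    # block index per SNP (per chromosome, by physical position)
    block_id = np.zeros(n_snps, dtype=int)
    next_block = 0
    for c in pd.unique(chroms):
        sel = chroms == c
        blk = poss[sel] // config.ld_block_length
        _, local = np.unique(blk, return_inverse=True)
        block_id[sel] = local + next_block
        next_block = block_id[sel].max() + 1
    n_blocks = next_block

    n_target = (
        unconditional_n if unconditional_n is not None
        else config.n_cases + config.n_controls
    )
    max_draws = config.max_draw_factor * max(n_target, 1)

    rows = []
    meta = []
    n_case = n_ctrl = 0
    draws = 0
    while (
        len(rows) < unconditional_n
        if unconditional_n is not None
        else (n_case < config.n_cases or n_ctrl < config.n_controls)
    ):
        if draws >= max_draws:
            raise PenetranceInfeasibleError(
                f"penetrance table produced {n_case}/{config.n_cases} cases and "
                f"{n_ctrl}/{config.n_controls} controls in {draws} draws"
            )
        draws += 1
        subpop = int(rng.random() < config.subpop_fraction)
        hap_idx = rng.integers(0, n_f, size=(2, n_blocks))
        # gather: founder row per block for every SNP
        h1 = founders[subpop][hap_idx[0][block_id], np.arange(n_snps)]
        h2 = founders[subpop][hap_idx[1][block_id], np.arange(n_snps)]
        a_dosage = int(_hwe_dosage(rng, a.allele_freq, 1)[0])
        b_dosage = int(_hwe_dosage(rng, b.allele_freq, 1)[0])
        for k, h in enumerate((h1, h2)):
            if k < a_dosage:
                h[a_sites] = 1  # risk haplotype carries the alt-allele string
            h[b_site] = 1 if k < b_dosage else 0
        cls = _genotype_class(a_dosage, b_dosage)
        pen = config.penetrance.get(cls, 0.05)
        is_case = bool(rng.random() < pen)
        if unconditional_n is None:
            if is_case and n_case >= config.n_cases:
                continue
            if not is_case and n_ctrl >= config.n_controls:
                continue
        if is_case:
            n_case += 1
            age = float(rng.uniform(*config.case_age_range))
        else:
            n_ctrl += 1
            age = float(
                rng.uniform(
                    config.control_min_age,
                    config.control_min_age + config.control_age_span,
                )
            )
        rows.append(h1 + h2)
        meta.append((subpop, a_dosage, b_dosage, int(is_case), age))

    dosages = np.array(rows, dtype=float)
    sample_ids = [f"dog{i:04d}" for i in range(len(rows))]
    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chroms, poss)]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=poss,
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["G"] * n_snps, dtype=object),
        dosages=dosages,
    )
    samples = pd.DataFrame(
        meta, columns=["subpop", "a_dosage", "b_dosage", "phenotype", "age"]
    )
    samples.insert(0, "sample_id", sample_ids)

    hap = RiskHaplotype(
        chromosome=a.chromosome,
        lead_snp_id=snp_ids[lead_site],
        lead_position=int(poss[lead_site]),
        risk_allele="G",
        risk_allele_is_alt=True,
        interval=Interval.from_1based(
            a.chromosome, int(poss[a_sites[0]]), int(poss[a_sites[-1]])
        ),
        snp_ids=[snp_ids[j] for j in a_sites],
        positions=poss[a_sites],
        case_alleles=np.ones(a_sites.size, dtype=int),
    )
    truth = SyntheticTruth(
        haplotype=hap,
        locus_b_snp=snp_ids[b_site],
        penetrance=dict(config.penetrance),
        samples=samples,
        ancestral_freqs=p_anc,
    )
    return gm, truth


def _genotype_class(a_dosage: int, b_dosage: int) -> str:
    a = {0: "aa", 1: "Aa", 2: "AA"}[a_dosage]
    b = {0: "bb", 1: "Bb", 2: "BB"}[b_dosage]
    return a + b


# ---------------------------------------------------------------------------
# Quantitative phenotypes with known regional PVE
# ---------------------------------------------------------------------------

def simulate_polygenic_phenotype(
    genotypes: GenotypeMatrix,
    regions: dict[str, tuple[Interval, float]],
    seed: int = 0,
) -> np.ndarray:
    """A phenotype whose realised per-region variance fractions are exact.

    Each region contributes ``sum_j x_cj u_j`` with Gaussian SNP effects,
    rescaled so the empirical variance of the regional genetic value
    equals the requested PVE; residual noise fills the remainder. Total
    requested PVE must be <= 1.
    """
    rng = np.random.default_rng(seed)
    total_pve = sum(p for _, p in regions.values())
    if total_pve > 1.0:
        raise ValueError("total PVE exceeds 1")
    n = genotypes.n_samples
    y = np.zeros(n)
    for name, (region, pve) in regions.items():
        if pve == 0:
            continue
        chrom, s1, e1 = region.to_1based()
        sel = (
            (genotypes.chromosomes == chrom)
            & (genotypes.positions >= s1)
            & (genotypes.positions <= e1)
        )
        X = genotypes.dosages[:, sel]
        Xc = X - np.nanmean(X, axis=0)
        Xc = np.where(np.isnan(Xc), 0.0, Xc)
        g = Xc @ rng.normal(size=Xc.shape[1])
        sd = g.std()
        if sd == 0:
            raise ValueError(f"region {name} has no genetic variance")
        y += g / sd * np.sqrt(pve)
    e = rng.normal(size=n)
    e = (e - e.mean()) / e.std() * np.sqrt(max(1.0 - total_pve, 0.0))
    return y + e


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(config: CohortConfig, truth: SyntheticTruth):
    """Simulate RNA-seq gene counts and allelic counts tied to genotype.

    The DE contrast mirrors the study design: samples homozygous for the
    locus-B risk allele (cases preferred) against heterozygous samples,
    with one gene up-regulated by ``de_fold_change`` in the homozygous
    group. ASE variants show allelic imbalance (``ase_ratio``) in samples
    heterozygous for the risk haplotype and balanced counts elsewhere.

    Returns an :class:`breedrisk.expression.ExpressionSet`; the truth
    object is updated in place with the DE gene and ASE variants.
    """
    from .expression import ExpressionSet

    if config.de_fold_change <= 0:
        raise ValueError("fold change must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    s = truth.samples
    hom = s[(s["b_dosage"] == 2)].sort_values("phenotype", ascending=False)
    het = s[(s["b_dosage"] == 1)]
    n_hom = min(config.n_rna_cases, len(hom))
    n_het = min(config.n_rna_controls, len(het))
    if n_hom < 2 or n_het < 2:
        raise ValueError("not enough homozygous/heterozygous samples for RNA-seq")
    rna_samples = list(hom["sample_id"].iloc[:n_hom]) + list(het["sample_id"].iloc[:n_het])
    groups = pd.Series(
        ["hom_risk"] * n_hom + ["het_risk"] * n_het, index=rna_samples
    )

    n_genes = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    base_mean = rng.lognormal(mean=np.log(200.0), sigma=1.2, size=n_genes)
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes), index=gene_ids, name="length"
    )
    de_idx = int(rng.integers(0, n_genes))
    de_gene = gene_ids[de_idx]
    sf = rng.lognormal(mean=0.0, sigma=0.15, size=len(rna_samples))

    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    counts = np.empty((n_genes, len(rna_samples)), dtype=np.int64)
    for j, samp in enumerate(rna_samples):
        mu = base_mean * sf[j]
        if groups[samp] == "hom_risk":
            mu = mu.copy()
            mu[de_idx] *= config.de_fold_change
        p_nb = nb_n / (nb_n + mu)
        counts[:, j] = rng.negative_binomial(nb_n, p_nb)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=rna_samples)

    # allele-specific counts at heterozygous-haplotype samples
    a_dos = s.set_index("sample_id")["a_dosage"]
    ase_rows = []
    chrom = truth.haplotype.chromosome
    s1, e1 = truth.haplotype.span_1based
    positions = np.linspace(s1, e1, num=config.n_ase_variants + 2)[1:-1].astype(int)
    for v, pos in enumerate(positions):
        vid = f"{chrom}:{int(pos)}"
        for samp in rna_samples:
            depth = int(rng.poisson(config.ase_depth))
            if depth == 0:
                continue
            ratio = config.ase_ratio if a_dos[samp] == 1 else 0.5
            alt = int(rng.binomial(depth, ratio))
            ase_rows.append((vid, samp, depth - alt, alt))
    ase_df = pd.DataFrame(
        ase_rows, columns=["variant", "sample", "ref_count", "alt_count"]
    )

    truth.de_gene = de_gene
    truth.de_fold_change = float(config.de_fold_change)
    truth.ase_variants = [
        {"variant": f"{chrom}:{int(p)}", "ratio": float(config.ase_ratio)}
        for p in positions
    ]
    return ExpressionSet(
        counts=counts_df, gene_lengths=lengths, groups=groups, allele_counts=ase_df
    )


# ---------------------------------------------------------------------------
# WGS panel simulation
# ---------------------------------------------------------------------------

@dataclass
class WgsPanel:
    variants: pd.DataFrame
    spec: list[SampleSpec]
    panel_af: pd.Series
    regulatory: dict[str, IntervalSet]
    motifs: list[MotifModel]
    reference: dict[str, str]


_SP1_PFM = np.array(
    # GC-box consensus GGGGCGGGG
    [[0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.85, 0.05, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05],
     [0.05, 0.05, 0.85, 0.05]]
)


def simulate_wgs_panel(
    config: CohortConfig,
    truth: SyntheticTruth,
    n_wgs_het: int = 6,
    n_wgs_hom: int = 1,
    n_wgs_noncarrier: int = 1,
) -> WgsPanel:
    """Simulate the WGS layer: variants, breed panel AFs, regulatory
    intervals, a motif set and a reference sequence.

    Concordant variants ride the risk haplotype (per-sample genotype equals
    haplotype dosage); their panel allele frequencies fall below 0.5 with
    probability ``frac_rare`` and a ``frac_regulatory`` share of the rare
    ones sits inside regulatory intervals, emulating the shape of the
    study's filter cascade. One regulatory concordant variant creates a
    GC-box (SP1-type) motif match on the risk allele.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    s = truth.samples
    chrom = truth.haplotype.chromosome
    s1, e1 = truth.haplotype.span_1based

    def pick(mask, k):
        ids = s.loc[mask, "sample_id"].tolist()
        if len(ids) < k:
            raise ValueError("cohort lacks samples for the requested WGS design")
        return ids[:k]

    spec = (
        [SampleSpec(x, 1) for x in pick(s["a_dosage"] == 1, n_wgs_het)]
        + [SampleSpec(x, 2) for x in pick(s["a_dosage"] == 2, n_wgs_hom)]
        + [SampleSpec(x, 0) for x in pick(s["a_dosage"] == 0, n_wgs_noncarrier)]
    )
    dosage_of = {sp.sample_id: sp.expected_dosage for sp in spec}

    n_on = config.n_haplotype_variants
    n_off = config.n_off_haplotype_variants
    on_pos = np.sort(rng.choice(np.arange(s1 + 1, e1, 3), size=n_on, replace=False))
    span = e1 - s1
    off_lo = np.arange(max(s1 - span, 1000), s1 - 200)
    off_pos = np.sort(rng.choice(off_lo, size=n_off, replace=False))

    bases = np.array(list("ACGT"))
    rows = []
    af_keys, af_vals = [], []
    rare_flags = rng.random(n_on) < config.frac_rare
    for i, pos in enumerate(on_pos):
        ref, alt = rng.choice(bases, size=2, replace=False)
        row = {"chromosome": chrom, "position": int(pos), "ref": ref, "alt": alt}
        for sp in spec:
            row[f"gt_{sp.sample_id}"] = float(sp.expected_dosage)
        rows.append(row)
        af = rng.uniform(0.01, 0.499) if rare_flags[i] else rng.uniform(0.5, 0.95)
        af_keys.append(f"{chrom}:{int(pos)}:{ref}>{alt}")
        af_vals.append(round(float(af), 4))
    for pos in off_pos:
        ref, alt = rng.choice(bases, size=2, replace=False)
        row = {"chromosome": chrom, "position": int(pos), "ref": ref, "alt": alt}
        for sp in spec:
            row[f"gt_{sp.sample_id}"] = float(rng.binomial(2, 0.4))
        # force at least one discordance so the variant cannot ride along
        victim = spec[int(rng.integers(len(spec)))]
        row[f"gt_{victim.sample_id}"] = float((victim.expected_dosage + 1) % 3)
        rows.append(row)
        af_keys.append(f"{chrom}:{int(pos)}:{ref}>{alt}")
        af_vals.append(round(float(rng.uniform(0.01, 0.95)), 4))
    variants = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    panel_af = pd.Series(af_vals, index=af_keys, name="panel_af")

    # regulatory intervals over a frac_regulatory share of the rare
    # concordant variants, tagged with alternating assay sources
    rare_on = [int(p) for p, r in zip(on_pos, rare_flags) if r]
    n_reg = int(round(config.frac_regulatory * len(rare_on)))
    reg_positions = sorted(rng.choice(rare_on, size=n_reg, replace=False).tolist())
    sources = ["H3K4me1", "H3K4me3", "ATAC"]
    reg: dict[str, list] = {src: [] for src in sources}
    for k, pos in enumerate(reg_positions):
        src = sources[k % len(sources)]
        reg[src].append(Interval(chrom, pos - 50, pos + 150, src))
    regulatory = {src: IntervalSet(ivs).merge() for src, ivs in reg.items() if ivs}

    # reference sequence around the interval; one regulatory variant is
    # rewritten so its alt (risk) allele completes the GC-box consensus
    ref_start = max(s1 - 500, 0)
    seq = rng.choice(bases, size=e1 + 500 - ref_start).tolist()
    motif_variant = None
    if reg_positions:
        motif_variant = int(reg_positions[0])
        site0 = motif_variant - 1 - ref_start  # 0-based within generated seq
        consensus = "GGGGCGGGG"
        for k, base in enumerate(consensus):
            seq[site0 - 4 + k] = base
        seq[site0] = "A"  # reference breaks the core C
        idx = variants.index[variants["position"] == motif_variant][0]
        variants.loc[idx, ["ref", "alt"]] = ["A", "C"]
        key_old = panel_af.index[
            panel_af.index.str.startswith(f"{chrom}:{motif_variant}:")
        ][0]
        panel_af = panel_af.rename(
            index={key_old: f"{chrom}:{motif_variant}:A>C"}
        )
    reference = {chrom: "N" * ref_start + "".join(seq)}
    motifs = [MotifModel("SP1_GCBOX", _SP1_PFM, pseudocount=0.01)]

    truth.causal_variants = (
        [{"variant": f"{chrom}:{motif_variant}:A>C", "effect": "creates SP1 GC-box on risk allele"}]
        if motif_variant
        else []
    )
    return WgsPanel(variants, spec, panel_af, regulatory, motifs, reference)


# ---------------------------------------------------------------------------
# Hand-constructed fixtures
# ---------------------------------------------------------------------------

def filter_demo() -> tuple[pd.DataFrame, list[SampleSpec], pd.Series, dict[str, IntervalSet], tuple[int, int, int]]:
    """Deterministic cascade fixture: 12 concordant variants, 5 of them
    with panel AF < 0.5, 3 of those inside regulatory intervals, plus 4
    discordant decoys. Expected cascade counts: (12, 5, 3)."""
    spec = [
        SampleSpec("wgs_het1", 1),
        SampleSpec("wgs_het2", 1),
        SampleSpec("wgs_hom", 2),
        SampleSpec("wgs_ctrl", 0),
    ]
    rows = []
    afs = {}
    chrom = "chr5"
    # 12 concordant: positions 10_000 + 100*i
    rare_idx = {0, 2, 5, 8, 11}           # 5 rare
    reg_idx = {0, 5, 11}                  # 3 of the rare in regulatory DNA
    for i in range(12):
        pos = 10_000 + 100 * i
        row = {
            "chromosome": chrom, "position": pos, "ref": "A", "alt": "T",
            "gt_wgs_het1": 1.0, "gt_wgs_het2": 1.0,
            "gt_wgs_hom": 2.0, "gt_wgs_ctrl": 0.0,
        }
        rows.append(row)
        afs[f"{chrom}:{pos}:A>T"] = 0.10 if i in rare_idx else 0.80
    # 4 discordant decoys
    for i, gts in enumerate(
        [(0, 1, 2, 0), (1, 1, 1, 0), (1, 1, 2, 2), (2, 1, 2, 0)]
    ):
        pos = 20_000 + 100 * i
        rows.append(
            {
                "chromosome": chrom, "position": pos, "ref": "G", "alt": "C",
                "gt_wgs_het1": float(gts[0]), "gt_wgs_het2": float(gts[1]),
                "gt_wgs_hom": float(gts[2]), "gt_wgs_ctrl": float(gts[3]),
            }
        )
        afs[f"{chrom}:{pos}:G>C"] = 0.05
    variants = pd.DataFrame(rows)
    regulatory = {
        "H3K4me1": IntervalSet(
            [Interval(chrom, 10_000 - 10, 10_000 + 1, "H3K4me1")]  # covers i=0
        ),
        "ATAC": IntervalSet(
            [
                Interval(chrom, 10_499, 10_510, "ATAC"),   # covers i=5 (10500)
                Interval(chrom, 11_099, 11_101, "ATAC"),   # covers i=11 (11100)
            ]
        ),
    }
    return variants, spec, pd.Series(afs), regulatory, (12, 5, 3)


def delineation_fixture(
    n_cases: int = 40,
    n_controls: int = 30,
    n_snps: int = 120,
    interval_snps: tuple[int, int] = (40, 79),
    n_recombinants: int = 3,
    seed: int = 0,
):
    """A cohort with an embedded haplotype and engineered recombinants.

    All case carriers share the alternate allele across the embedded
    interval; exactly ``n_recombinants`` carriers lose sharing at the
    first SNP outside each boundary, so delineation with loss threshold
    <= n_recombinants recovers the embedded interval exactly.

    Returns (genotypes, phenotype, lead_snp_id, risk_allele,
    expected_interval).
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    spacing = 10_000
    poss = spacing * (np.arange(n_snps) + 1)
    lo, hi = interval_snps
    lead = (lo + hi) // 2

    dos = rng.binomial(2, 0.35, size=(n, n_snps)).astype(float)
    phenotype = np.array([1] * n_cases + [0] * n_controls)
    carriers = np.arange(0, n_cases)  # all cases carry
    # carriers share >=1 alt allele everywhere; an even het/hom mix keeps
    # the majority-among-carriers allele unambiguously alt at every SNP
    dos[carriers] = 1.0 + rng.binomial(1, 0.5, size=(n_cases, n_snps))
    recomb = carriers[:n_recombinants]
    dos[np.ix_(recomb, np.concatenate([np.arange(0, lo), np.arange(hi + 1, n_snps)]))] = 0.0
    chroms = np.array(["chr1"] * n_snps, dtype=object)
    snp_ids = [f"s{j}" for j in range(n_snps)]
    gm = GenotypeMatrix(
        sample_ids=[f"d{i}" for i in range(n)],
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=poss,
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["G"] * n_snps, dtype=object),
        dosages=dos,
    )
    expected = Interval.from_1based("chr1", int(poss[lo]), int(poss[hi]))
    return gm, phenotype, snp_ids[lead], "G", expected


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_cohort(
    gm: GenotypeMatrix,
    truth: SyntheticTruth,
    outdir: str | Path,
    panel: WgsPanel | None = None,
) -> None:
    """Serialise a simulated cohort: VCF + dosage matrix + phenotype table
    + truth YAML, and (when given) the WGS layer's BED/MEME/FASTA files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf_genotypes(gm, outdir / "genotypes.vcf")
    write_dosage_matrix(gm, outdir / "dosages.tsv")
    pheno = truth.samples[["sample_id", "phenotype", "age", "subpop"]]
    write_phenotypes(pheno, outdir / "phenotypes.tsv")
    truth.to_yaml(outdir / "truth.yaml")
    if panel is not None:
        for src, ivs in panel.regulatory.items():
            write_bed(ivs, outdir / f"regulatory_{src}.bed")
        write_meme_motifs(
            [{"id": m.motif_id, "matrix": m.pfm, "background": m.background}
             for m in panel.motifs],
            outdir / "motifs.meme",
        )
        write_fasta(panel.reference, outdir / "reference.fa")
        panel.variants.to_csv(outdir / "wgs_variants.tsv", sep="\t", index=False)
        panel.panel_af.rename_axis("variant").reset_index().to_csv(
            outdir / "panel_af.tsv", sep="\t", index=False
        )
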