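"""Risk-haplotype delineation, sharing decay, LD and cross-breed comparison.

A risk haplotype is the contiguous run of case-associated alleles around a
lead GWAS SNP shared by affected carriers. Boundaries follow the
loss-count rule: walking outward from the lead, the haplotype ends at the
last SNP before the first position at which at least ``loss_threshold``
case carriers have (cumulatively) lost continuous sharing of the
case-associated allele, with the loss persisting for at least
``persistence_bp`` beyond that position.

Array genotypes are unphased, so carrier status uses the >=1-copy rule and
the per-SNP case-associated allele is taken as the majority allele among
case carriers (ties broken toward the allele in higher LD with the lead
risk allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .io import GenotypeMatrix, Interval, IntervalSet, intersect_intervals


@dataclass
class RiskHaplotype:
    """A delineated risk haplotype.

    ``case_alleles`` holds, for each SNP inside the interval (in map
    order), 1 if the case-associated allele is the alternate allele and 0
    if it is the reference allele.
    """

    chromosome: str
    lead_snp_id: str
    lead_position: int
    risk_allele: str
    risk_allele_is_alt: bool
    interval: Interval
    snp_ids: list[str]
    positions: np.ndarray
    case_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.case_alleles = np.asarray(self.case_alleles, dtype=int)
        chrom, s1, e1 = self.interval.to_1based()
        if not (s1 <= self.lead_position <= e1):
            raise ValueError("lead SNP position outside haplotype interval")
        if len(self.snp_ids) != len(self.case_alleles):
            raise ValueError("one case-associated allele required per SNP")

    @property
    def span_1based(self) -> tuple[int, int]:
        _, s1, e1 = self.interval.to_1based()
        return s1, e1


def _allele_dosage(dosages: np.ndarray, allele_is_alt) -> np.ndarray:
    """Copies of the chosen allele from alt-allele dosages (NaN passes through)."""
    if np.ndim(allele_is_alt) == 0:
        return dosages if allele_is_alt else 2.0 - dosages
    return np.where(np.asarray(allele_is_alt, dtype=bool), dosages, 2.0 - dosages)


def _chromosome_view(genotypes: GenotypeMatrix, chrom: str):
    idx = np.flatnonzero(genotypes.chromosomes == chrom)
    order = idx[np.argsort(genotypes.positions[idx], kind="stable")]
    return order


def _case_associated_alleles(
    dosages: np.ndarray,
    carrier_rows: np.ndarray,
    lead_col: int,
    risk_is_alt: bool,
) -> np.ndarray:
    """Majority allele among case carriers per SNP column; 1 = alt.

    Ties break toward the allele whose dosage correlates positively with
    the lead risk-allele dosage across all samples.
    """
    carr = dosages[carrier_rows]
    alt_count = np.nansum(carr, axis=0)
    called = np.sum(~np.isnan(carr), axis=0)
    ref_count = 2.0 * called - alt_count
    alleles = (alt_count > ref_count).astype(int)
    ties = np.flatnonzero(alt_count == ref_count)
    if ties.size:
        lead_dos = dosages[:, lead_col]
        lead_risk = lead_dos if risk_is_alt else 2.0 - lead_dos
        for j in ties:
            x = dosages[:, j]
            ok = ~np.isnan(x) & ~np.isnan(lead_risk)
            if ok.sum() > 1 and np.ptp(x[ok]) > 0 and np.ptp(lead_risk[ok]) > 0:
                r = np.corrcoef(x[ok], lead_risk[ok])[0, 1]
                alleles[j] = 1 if r >= 0 else 0
            else:
                alleles[j] = 1
    return alleles


def _loss_walk(
    dosages: np.ndarray,
    carrier_rows: np.ndarray,
    cols: np.ndarray,
    case_alleles: np.ndarray,
) -> np.ndarray:
    """Cumulative count of carriers whose continuous sharing has broken,
    walking along ``cols`` (which start at the lead). Missing genotypes do
    not break sharing (no evidence of loss)."""
    lost = np.zeros(len(carrier_rows), dtype=bool)
    cum = np.zeros(len(cols), dtype=int)
    for k, j in enumerate(cols):
        d = dosages[carrier_rows, j]
        share = _allele_dosage(d, bool(case_alleles[k]))
        lost |= ~np.isnan(share) & (share < 1)
        cum[k] = int(lost.sum())
    return cum


def _boundary_index(
    cum_losses: np.ndarray,
    positions: np.ndarray,
    loss_threshold: int,
    persistence_bp: int,
) -> int:
    """Index (into the walk) of the last SNP before the first qualifying
    loss position; len-1 when the threshold is never met with persistence."""
    qualifying = None
    for k in range(1, len(cum_losses)):
        if cum_losses[k] < loss_threshold:
            continue
        # persistence: count must stay >= threshold at every SNP within
        # persistence_bp beyond this position (cumulative counts are
        # monotone, so this is a direct check)
        limit = abs(int(positions[k])) + persistence_bp
        persists = True
        for k2 in range(k + 1, len(cum_losses)):
            if abs(int(positions[k2])) > limit:
                break
            if cum_losses[k2] < loss_threshold:
                persists = False
                break
        if persists:
            qualifying = k
            break
    if qualifying is None:
        return len(cum_losses) - 1
    return qualifying - 1


def delineate_risk_haplotype(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    lead_snp: str,
    risk_allele: str,
    loss_threshold: int = 3,
    persistence_bp: int = 1000,
) -> RiskHaplotype:
    """Delineate the risk haplotype around a lead SNP by the loss-count rule.

    Parameters
    ----------
    lead_snp : str
        SNP id of the lead association; must be polymorphic.
    risk_allele : str
        The case-associated allele at the lead SNP (must equal its ref or
        alt label).
    loss_threshold : int
        Number of case carriers that must lose continuous sharing before a
        boundary is declared (study rule: 3).
    persistence_bp : int
        The loss must extend for at least this many bp beyond the boundary
        (study rule: 1 kb).
    """
    y = np.asarray(phenotype, dtype=int)
    lead = genotypes.snp_index(lead_snp)
    chrom = genotypes.chromosomes[lead]
    if risk_allele == genotypes.alt[lead]:
        risk_is_alt = True
    elif risk_allele == genotypes.ref[lead]:
        risk_is_alt = False
    else:
        raise ValueError(
            f"risk allele {risk_allele!r} is neither ref nor alt of {lead_snp}"
        )
    lead_dos = genotypes.dosages[:, lead]
    if np.ptp(lead_dos[~np.isnan(lead_dos)]) == 0:
        raise ValueError(f"lead SNP {lead_snp} is monomorphic")
    risk_dos = _allele_dosage(lead_dos, risk_is_alt)
    carriers = np.flatnonzero((y == 1) & (risk_dos >= 1))
    if carriers.size == 0:
        raise ValueError("no case carries the risk allele at the lead SNP")

    order = _chromosome_view(genotypes, chrom)
    lead_k = int(np.flatnonzero(order == lead)[0])
    alleles_chrom = _case_associated_alleles(
        genotypes.dosages[:, order], carriers, lead_k, risk_is_alt
    )
    pos_chrom = genotypes.positions[order]

    # walk telomeric (increasing position) and centromeric (decreasing)
    right_cols = order[lead_k:]
    left_cols = order[lead_k::-1]
    cum_right = _loss_walk(genotypes.dosages, carriers,
                           right_cols, alleles_chrom[lead_k:])
    cum_left = _loss_walk(genotypes.dosages, carriers,
                          left_cols, alleles_chrom[lead_k::-1])
    b_right = _boundary_index(cum_right, pos_chrom[lead_k:],
                              loss_threshold, persistence_bp)
    b_left = _boundary_index(cum_left, -pos_chrom[lead_k::-1],
                             loss_threshold, persistence_bp)
    end_k = lead_k + b_right
    start_k = lead_k - b_left
    start_pos = int(pos_chrom[start_k])
    end_pos = int(pos_chrom[end_k])
    inside = slice(start_k, end_k + 1)
    return RiskHaplotype(
        chromosome=str(chrom),
        lead_snp_id=lead_snp,
        lead_position=int(genotypes.positions[lead]),
        risk_allele=risk_allele,
        risk_allele_is_alt=risk_is_alt,
        interval=Interval.from_1based(str(chrom), start_pos, end_pos),
        snp_ids=[genotypes.snp_ids[j] for j in order[inside]],
        positions=pos_chrom[inside],
        case_alleles=alleles_chrom[inside],
    )


# ---------------------------------------------------------------------------
# Sharing profiles
# ---------------------------------------------------------------------------

@dataclass
class SharingProfile:
    """Per-SNP haplotype-sharing fractions among case and control carriers.

    ``retaining`` is the fraction still in continuous sharing from the
    lead; ``regain`` the fraction matching the case-associated allele
    after an interruption. Groups without carriers are flagged empty (NaN
    columns), not zero.
    """

    table: pd.DataFrame
    n_case_carriers: int
    n_control_carriers: int

    @property
    def case_group_empty(self) -> bool:
        return self.n_case_carriers == 0

    @property
    def control_group_empty(self) -> bool:
        return self.n_control_carriers == 0


def _profile_group(dosages, rows, cols, case_alleles):
    """(retaining, regain) fractions per SNP along the walk for one group."""
    if rows.size == 0:
        return np.full(len(cols), np.nan), np.full(len(cols), np.nan)
    lost = np.zeros(rows.size, dtype=bool)
    retaining = np.empty(len(cols))
    regain = np.empty(len(cols))
    for k, j in enumerate(cols):
        d = dosages[rows, j]
        share = _allele_dosage(d, bool(case_alleles[k]))
        has_allele = np.isnan(share) | (share >= 1)  # missing: benefit of doubt
        lost |= ~has_allele
        retaining[k] = float((~lost).sum()) / rows.size
        regain[k] = float((lost & has_allele).sum()) / rows.size
    return retaining, regain


def sharing_profile(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    haplotype: RiskHaplotype,
) -> SharingProfile:
    """Haplotype-sharing decay outward from the lead SNP, per group."""
    y = np.asarray(phenotype, dtype=int)
    chrom = haplotype.chromosome
    order = _chromosome_view(genotypes, chrom)
    lead = genotypes.snp_index(haplotype.lead_snp_id)
    lead_k = int(np.flatnonzero(order == lead)[0])
    lead_dos = genotypes.dosages[:, lead]
    risk_dos = _allele_dosage(lead_dos, haplotype.risk_allele_is_alt)
    case_rows = np.flatnonzero((y == 1) & (risk_dos >= 1))
    ctrl_rows = np.flatnonzero((y == 0) & (risk_dos >= 1))
    alleles_chrom = _case_associated_alleles(
        genotypes.dosages[:, order], case_rows, lead_k, haplotype.risk_allele_is_alt
    )

    n_chrom = len(order)
    case_ret = np.empty(n_chrom)
    case_reg = np.empty(n_chrom)
    ctrl_ret = np.empty(n_chrom)
    ctrl_reg = np.empty(n_chrom)
    for cols_k, sl in (
        (np.arange(lead_k, n_chrom), slice(lead_k, n_chrom)),
        (np.arange(lead_k, -1, -1), slice(lead_k, None, -1)),
    ):
        cr, cg = _profile_group(genotypes.dosages, case_rows,
                                order[cols_k], alleles_chrom[cols_k])
        tr, tg = _profile_group(genotypes.dosages, ctrl_rows,
                                order[cols_k], alleles_chrom[cols_k])
        case_ret[sl], case_reg[sl] = cr, cg
        ctrl_ret[sl], ctrl_reg[sl] = tr, tg

    table = pd.DataFrame(
        {
            "snp_id": [genotypes.snp_ids[j] for j in order],
            "position": genotypes.positions[order],
            "case_retaining": case_ret,
            "case_regain": case_reg,
            "control_retaining": ctrl_ret,
            "control_regain": ctrl_reg,
        }
    )
    return SharingProfile(table, int(case_rows.size), int(ctrl_rows.size))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of unphased dosages.

    Missing pairs are excluded. Returns NaN (with a warning) when either
    SNP is monomorphic in the analysed samples.
    """
    a = genotypes.dosages[:, genotypes.snp_index(snp_a)]
    b = genotypes.dosages[:, genotypes.snp_index(snp_b)]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(f"r2({snp_a}, {snp_b}) undefined: monomorphic in analysed samples")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Cross-breed haplotype comparison
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeOverlap:
    shared: IntervalSet
    alleles_agree: bool | None  # None when no SNP is shared with both defined

    @property
    def length_bp(self) -> int:
        return self.shared.total_bp()

    @property
    def length_kb(self) -> int:
        return self.length_bp // 1000


def compare_haplotypes(h1: RiskHaplotype, h2: RiskHaplotype) -> HaplotypeOverlap:
    """Shared span of two risk haplotypes and allele agreement on it."""
    if h1.chromosome != h2.chromosome:
        warnings.warn(
            f"haplotypes on different chromosomes ({h1.chromosome} vs {h2.chromosome})"
        )
        return HaplotypeOverlap(IntervalSet(), None)
    shared = intersect_intervals(IntervalSet([h1.interval]), IntervalSet([h2.interval]))
    if shared.is_empty:
        return HaplotypeOverlap(shared, None)
    pos2allele = dict(zip(h2.positions.tolist(), h2.case_alleles.tolist()))
    agree: bool | None = None
    for p, a in zip(h1.positions.tolist(), h1.case_alleles.tolist()):
        if not shared.contains_position(h1.chromosome, p):
            continue
        if p in pos2allele:
            same = pos2allele[p] == a
            agree = same if agree is None else (agree and same)
    return HaplotypeOverlap(shared, agree)


# ---------------------------------------------------------------------------
# Table-2-style haplotype dosage
# ---------------------------------------------------------------------------

def haplotype_dosage(genotypes: GenotypeMatrix, haplotype: RiskHaplotype) -> np.ndarray:
    """Per-sample risk-haplotype dosage in {0, 1, 2} on unphased data.

    2: homozygous for the case-associated allele at every interval SNP.
    1: carries >=1 copy at every interval SNP, but not homozygous
       throughout. 0: otherwise. Missing genotypes do not veto carriage.
    """
    cols = [genotypes.snp_index(s) for s in haplotype.snp_ids]
    D = genotypes.dosages[:, cols]
    is_alt = haplotype.case_alleles.astype(bool)
    share = np.where(is_alt[None, :], D, 2.0 - D)
    with np.errstate(invalid="ignore"):
        carrier_all = np.all(np.isnan(share) | (share >= 1), axis=1)
        hom_all = np.all(np.isnan(share) | (share == 2), axis=1)
    return np.where(hom_all, 2, np.where(carrier_all, 1, 0)).astype(int)


# ---------------------------------------------------------------------------
# Phased block uniqueness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniqueBlock:
    target_haplotype: int
    start_site: int  # inclusive site index
    end_site: int    # inclusive site index

    @property
    def n_sites(self) -> int:
        return self.end_site - self.start_site + 1


def block_uniqueness(
    target_haplotypes: np.ndarray,
    background_haplotypes: np.ndarray,
) -> list[UniqueBlock]:
    """Minimal private allele-configuration blocks of target haplotypes.

    Both inputs are (haplotypes x sites) allele matrices over the same
    ordered variant sites (phased data). For each target haplotype, a
    block [i, j] is *unique* when no background haplotype carries the same
    allele string across sites i..j; reported blocks are the minimal such
    windows (every proper sub-window occurs in the background). An empty
    list means no variant combination is private to the target group.
    """
    T = np.atleast_2d(np.asarray(target_haplotypes))
    B = np.atleast_2d(np.asarray(background_haplotypes))
    if T.shape[1] != B.shape[1]:
        raise ValueError("target and background must cover the same sites")
    m = T.shape[1]
    blocks: list[UniqueBlock] = []
    for ti in range(T.shape[0]):
        match = B == T[ti][None, :]  # (k, m)
        # reach[b, i]: last site of the contiguous match run covering i
        reach = np.full((B.shape[0], m), -1, dtype=int)
        for b in range(B.shape[0]):
            j = m - 1
            run_end = -1
            for i in range(m - 1, -1, -1):
                if match[b, i]:
                    if run_end < i:
                        run_end = i
                        j = i
                        while j + 1 < m and match[b, j + 1]:
                            j += 1
                        run_end = j
                    reach[b, i] = run_end
                else:
                    run_end = -1
                    reach[b, i] = i - 1
        R = reach.max(axis=0) if B.shape[0] else np.full(m, -1, dtype=int)
        # the minimal unique window starting at i is [i, R(i)+1]; when
        # R(i) < i the single site i is already private
        windows = []
        for i in range(m):
            if R[i] < i:
                windows.append((i, i))
            elif R[i] + 1 <= m - 1:
                windows.append((i, int(R[i]) + 1))
        minimal = [
            (s, e)
            for (s, e) in windows
            if not any(
                (s2 >= s and e2 <= e and (s2, e2) != (s, e)) for (s2, e2) in windows
            )
        ]
        blocks.extend(UniqueBlock(ti, s, e) for s, e in sorted(set(minimal)))
    return blocks


def phased_haplotypes_from_vcf(path: str) -> tuple[np.ndarray, list[str], list[int]]:
    """Load phased biallelic genotypes as a (2*n_samples x n_sites) matrix.

    Raises on any unphased genotype: block uniqueness needs true
    haplotypes, so provide a phased VCF.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns = []
        positions = []
        for rec in vcf:
            hap_col = []
            for s in samples:
                sm = rec.samples[s]
                gt = sm.get("GT", (None, None))
                if None in gt:
                    raise ValueError(f"missing genotype at {rec.chrom}:{rec.pos}")
                if len(gt) == 2 and not sm.phased:
                    raise ValueError(
                        f"unphased genotype at {rec.chrom}:{rec.pos}; "
                        "provide a phased VCF"
                    )
                hap_col.extend(gt)
            columns.append(hap_col)
            positions.append(rec.pos)
    H = np.array(columns, dtype=int).T
    hap_ids = [f"{s}_h{k}" for s in samples for k in (1, 2)]
    return H, hap_ids, positions
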