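"""Expression analyses: TPM, differential expression, outlier z-scores,
allele-specific expression, and the small-sample rank-sum test.

The differential-expression stage is a deliberately compact
negative-binomial Wald test — median-of-ratios size factors, per-gene
method-of-moments dispersion with a small floor, Benjamini-Hochberg
adjustment — not a re-implementation of any particular DE package. Genes
are called significantly over/under-expressed at adjusted P < 0.05 and
|log2 fold-change| >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSet:
    """Gene-level counts with lengths, groups and derived matrices."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    gene_lengths: pd.Series       # bp per gene
    groups: pd.Series             # sample -> group label
    allele_counts: pd.DataFrame | None = None  # variant, sample, ref_count, alt_count

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if not self.gene_lengths.index.equals(self.counts.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a length")

    @property
    def tpm(self) -> pd.DataFrame:
        return compute_tpm(self.counts, self.gene_lengths)

    @property
    def size_factors(self) -> pd.Series:
        return median_of_ratios(self.counts)

    @property
    def vst(self) -> pd.DataFrame:
        return variance_stabilize(self.counts, self.size_factors)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalised rates scaled to 1e6/sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes expressed in all samples."""
    logc = np.log(counts.where(counts > 0))
    log_gmean = logc.mean(axis=1)  # NaN for genes with any zero
    ratios = logc.sub(log_gmean, axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    if sf.isna().any():
        raise ValueError("cannot compute size factors: no gene expressed in all samples")
    return sf


def variance_stabilize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilising transform: log2(normalised count + 1)."""
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    counts: pd.DataFrame,
    group_labels,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    dispersion_floor: float = 1e-8,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test per gene.

    Per-gene method-of-moments dispersions are squeezed toward the
    genome-wide median with ``prior_df`` prior degrees of freedom
    (empirical-Bayes moderation in the limma style), and the Wald
    statistic is referred to a t distribution with
    ``prior_df + n_A + n_B - 2`` df — per-gene moment dispersions at
    small n are too noisy for a plain normal reference.

    Returns a genes-indexed frame with ``baseMean``, ``log2FoldChange``
    (second group over first, in sorted label order), ``se``, ``p``,
    ``padj`` and ``significant``. Genes with all-zero counts in either
    group's union are reported untested (``tested`` = False, NaN stats).
    """
    labels = pd.Series(np.asarray(group_labels), index=counts.columns)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    ia = labels == uniq[0]
    ib = labels == uniq[1]
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    sf = median_of_ratios(counts)
    norm = counts.div(sf, axis=1)
    na, nb = int(ia.sum()), int(ib.sum())

    qa = norm.loc[:, ia.values].mean(axis=1)
    qb = norm.loc[:, ib.values].mean(axis=1)
    base_mean = norm.mean(axis=1)
    tested = (qa + qb) > 0

    # method-of-moments dispersion pooled within groups on the normalised
    # scale: Var(c) ~ mu + disp * mu^2
    var_w = (
        norm.loc[:, ia.values].var(axis=1, ddof=1) * (na - 1)
        + norm.loc[:, ib.values].var(axis=1, ddof=1) * (nb - 1)
    ) / (na + nb - 2)
    mu_w = (qa * na + qb * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_w - mu_w) / mu_w**2
    disp = disp.clip(lower=dispersion_floor).fillna(dispersion_floor)
    informative = disp[disp > 1e-6]
    disp_prior = float(informative.median()) if len(informative) else 1e-2
    df_gene = na + nb - 2
    disp = (prior_df * disp_prior + df_gene * disp) / (prior_df + df_gene)

    # Wald on log2 fold change via the delta method; NB variance of each
    # group mean of normalised counts
    mean_inv_sf_a = float((1.0 / sf[ia.values]).mean())
    mean_inv_sf_b = float((1.0 / sf[ib.values]).mean())
    pseudo = 0.5  # stabilises the log for group means near zero
    qa_s = qa + pseudo * mean_inv_sf_a / na
    qb_s = qb + pseudo * mean_inv_sf_b / nb
    lfc = np.log2(qb_s / qa_s)
    var_qa = (qa * mean_inv_sf_a + disp * qa**2) / na
    var_qb = (qb * mean_inv_sf_b + disp * qb**2) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(var_qa / qa_s**2 + var_qb / qb_s**2)
    se = se_ln / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    p = 2.0 * sps.t.sf(np.abs(wald), df=prior_df + na + nb - 2)
    p = pd.Series(p, index=counts.index).where(tested)

    padj = pd.Series(np.nan, index=counts.index)
    mask = p.notna()
    if mask.any():
        padj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc.where(tested),
            "se": se.where(tested),
            "p": p,
            "padj": padj,
            "tested": tested,
        }
    )
    out["significant"] = (out["padj"] < alpha) & (out["log2FoldChange"].abs() >= lfc_threshold)
    return out


# ---------------------------------------------------------------------------
# Individual (outlier) expression z-scores
# ---------------------------------------------------------------------------

def individual_zscore(
    vst_matrix: pd.DataFrame,
    control_samples: list[str],
    query_sample: str,
    z_threshold: float = 2.5,
) -> pd.DataFrame:
    """Per-gene expression-outlier z-scores for one sample.

    z = (x - mean(controls)) / sd(controls) on the variance-stabilised
    scale, with the sample (n-1) standard deviation. |z| >= 2.5 flags a
    significant individual expression change; genes with zero control
    variance are flagged undefined rather than scored.
    """
    if query_sample in control_samples:
        raise ValueError("query sample must not be in the control set")
    if len(control_samples) < 3:
        raise ValueError("need at least 3 control samples")
    ctrl = vst_matrix[control_samples]
    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    x = vst_matrix[query_sample]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z = z.where(sd > 0)
    return pd.DataFrame(
        {
            "z": z,
            "undefined": sd == 0,
            "significant": z.abs() >= z_threshold,
        }
    )


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------

def ase_test(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_recurrence: int = 2,
    min_depth: int = 10,
    expected_ratio: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chi-square allelic-imbalance test with the recurrence rule.

    ``records`` has columns variant, sample, ref_count, alt_count. Each
    record is tested against the balanced (or configured) expectation by a
    1-df chi-square goodness-of-fit; a variant is prioritised when it is
    significant (p <= alpha) in at least ``min_recurrence`` individuals.
    Records below ``min_depth`` total reads are skipped (zero-depth
    records are logged and dropped).

    Returns (per-record results, per-variant summary with ``prioritized``).
    """
    req = {"variant", "sample", "ref_count", "alt_count"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    rec = records.copy()
    total = rec["ref_count"] + rec["alt_count"]
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-depth ASE record(s) skipped")
    rec = rec[total > 0].copy()
    total = total[total > 0]
    rec["depth"] = total
    rec["tested"] = rec["depth"] >= min_depth

    e_ref = total * expected_ratio
    e_alt = total * (1 - expected_ratio)
    chi2 = (rec["ref_count"] - e_ref) ** 2 / e_ref + (rec["alt_count"] - e_alt) ** 2 / e_alt
    rec["chi2"] = chi2
    rec["p"] = sps.chi2.sf(chi2, df=1)
    rec.loc[~rec["tested"], ["chi2", "p"]] = np.nan
    rec["significant"] = rec["p"] <= alpha

    summary = (
        rec.groupby("variant")
        .agg(
            n_tested=("tested", "sum"),
            n_significant=("significant", "sum"),
        )
        .assign(prioritized=lambda df: df["n_significant"] >= min_recurrence)
    )
    return rec, summary


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_exact_p(ranks2: np.ndarray, n_a: int, w_obs2: int) -> float:
    """Two-sided exact rank-sum p by subset-sum DP over doubled ranks.

    ``ranks2`` are tie-aware midranks doubled to integers; ``w_obs2`` the
    doubled observed rank-sum of group A. Two-sided p doubles the smaller
    tail (capped at 1), the convention under which complete separation of
    4 vs 7 gives 2/C(11,4).
    """
    total = int(ranks2.sum())
    # dp[k][s]: number of k-subsets of ranks with doubled-sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):  # descending: 0/1-knapsack update
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n_a]
    n_total = dist.sum()
    lo = dist[: w_obs2 + 1].sum() / n_total
    hi = dist[w_obs2:].sum() / n_total
    return float(min(1.0, 2.0 * min(lo, hi)))


def ranksum_test(group_a, group_b, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full enumeration over rank assignments, tie-aware) when the
    total sample size is at most ``exact_max_n``; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_a = float(ranks[:n].sum())
    if n + m <= exact_max_n:
        ranks2 = np.round(ranks * 2).astype(int)
        return _ranksum_exact_p(ranks2, n, int(round(w_a * 2)))
    # normal approximation with tie correction
    N = n + m
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    diff = w_a - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
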