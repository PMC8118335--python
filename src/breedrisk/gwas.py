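"""Mixed-model association testing and variance-component estimation.

The association model is the standard exact linear mixed model

    y = W a + x b + u + e,   u ~ N(0, s2_g K),  e ~ N(0, s2_e I)

with ``K`` a centered genetic relatedness matrix. The variance ratio
``delta = s2_g / s2_e`` is profiled per SNP by restricted maximum
likelihood on the eigenbasis of ``K``; the per-SNP Wald statistic is
``(b / se(b))^2`` referred to an F(1, n-c) null (equivalently a t-test).
Case/control status is analysed on the observed 0/1 scale, matching how
the study reports effect sizes and variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .io import GenotypeMatrix, Interval

_CHI2_1_MEDIAN = sps.chi2.isf(0.5, df=1)  # 0.4549...


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric pairwise relatedness matrix (centered cross-product form)."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())

    @classmethod
    def identity(cls, sample_ids: list[str]) -> "KinshipMatrix":
        return cls(sample_ids, np.eye(len(sample_ids)))


def compute_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Centered relatedness matrix: K = Xc Xc' / p over polymorphic SNPs.

    Columns are mean-centered; missing dosages contribute the SNP mean
    (i.e. zero after centering). Monomorphic SNPs are excluded from the
    computation. Requires at least two samples, and every sample must have
    at least one called genotype.
    """
    X = genotypes.dosages
    if X.shape[0] < 2:
        raise ValueError("kinship needs at least 2 samples")
    if np.isnan(X).all(axis=1).any():
        bad = np.array(genotypes.sample_ids)[np.isnan(X).all(axis=1)]
        raise ValueError(f"samples with no called genotypes: {list(bad)}")
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - mu)
    poly = np.nanvar(X, axis=0) > 0
    p = int(poly.sum())
    if p == 0:
        return KinshipMatrix(list(genotypes.sample_ids), np.zeros((X.shape[0],) * 2))
    Xp = Xc[:, poly]
    return KinshipMatrix(list(genotypes.sample_ids), Xp @ Xp.T / p)


# ---------------------------------------------------------------------------
# REML machinery (single random component, eigenbasis)
# ---------------------------------------------------------------------------

def _reml_nll(log_delta: float, yt: np.ndarray, Xt: np.ndarray, S: np.ndarray):
    """Negative restricted log-likelihood profiled over the variance scale.

    Works on the eigenbasis of K: weights are 1/(delta*S + 1).
    Returns (nll, beta, A_inv, sigma2_e, rss).
    """
    n, c = Xt.shape
    delta = np.exp(log_delta)
    w = 1.0 / (delta * S + 1.0)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    rhs = Xw.T @ yt
    try:
        L = np.linalg.cholesky(A)
        beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return np.inf, None, None, np.nan, np.nan
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return np.inf, beta, None, 0.0, rss
    logdet_D = float(-np.sum(np.log(w)))
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2 = rss / (n - c)
    nll = 0.5 * ((n - c) * np.log(rss) + logdet_D + logdet_A)
    A_inv = np.linalg.inv(A)
    return nll, beta, A_inv, sigma2, rss


def _fit_single_snp(yt, Xt, S, bounds=(-12.0, 12.0), xatol=1e-8):
    """Profile log(delta) by bounded Brent; return the fitted quantities."""
    res = optimize.minimize_scalar(
        lambda ld: _reml_nll(ld, yt, Xt, S)[0],
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    nll, beta, A_inv, sigma2, _ = _reml_nll(res.x, yt, Xt, S)
    return res.x, nll, beta, A_inv, sigma2


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Per-SNP mixed-model Wald scan plus genome-wide diagnostics."""

    table: pd.DataFrame  # snp_id, chromosome, position, beta, se, wald, p
    n_samples: int
    n_tests: int
    lambda_gc: float
    alpha: float = 0.05

    @property
    def bonferroni(self) -> "BonferroniThreshold":
        return bonferroni_threshold(self.alpha, self.n_tests)

    def top_hit(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]


def lmm_wald(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    kinship: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """Per-SNP Wald tests under the exact mixed model.

    Parameters
    ----------
    phenotype : (n,) array
        Case/control 0/1 (or any non-constant quantitative trait), aligned
        with ``genotypes.sample_ids``.
    kinship : KinshipMatrix, optional
        Computed from all SNPs when omitted.
    covariates : (n, q) array, optional
        Fixed covariates in addition to the intercept; conditioning on a
        lead-SNP genotype is done by passing its dosage vector here.

    Monomorphic SNPs yield NaN rows rather than errors. SNPs with missing
    genotypes are tested on the subset of called samples (pairwise
    exclusion; the kinship sub-matrix is re-factorised for those SNPs).
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length does not match sample count")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if kinship is None:
        kinship = compute_kinship(genotypes)
    if list(kinship.sample_ids) != list(genotypes.sample_ids):
        raise ValueError("kinship sample ids are not aligned with genotypes")

    W = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        W = np.hstack([W, C])

    S, U = np.linalg.eigh(kinship.values)
    S = np.clip(S, 0.0, None)
    yt_all = U.T @ y
    Wt_all = U.T @ W

    X = genotypes.dosages
    out = np.full((genotypes.n_snps, 4), np.nan)  # beta, se, wald, p
    for j in range(X.shape[1]):
        x = X[:, j]
        miss = np.isnan(x)
        if not miss.any():
            # a SNP numerically in the span of the covariates (e.g.
            # conditioning on its own dosage) adds no information: its
            # conditional association is null by construction
            coef, *_ = np.linalg.lstsq(W, x, rcond=None)
            resid = x - W @ coef
            if np.var(resid) <= 1e-12 * max(np.var(x), 1e-12):
                if np.ptp(x) > 0:
                    out[j] = (0.0, np.nan, 0.0, 1.0)
                continue
        if miss.any():
            keep = ~miss
            if keep.sum() < W.shape[1] + 2 or np.ptp(y[keep]) == 0:
                continue
            if np.ptp(x[keep]) == 0:
                continue
            Sk, Uk = np.linalg.eigh(kinship.values[np.ix_(keep, keep)])
            Sk = np.clip(Sk, 0.0, None)
            yt = Uk.T @ y[keep]
            Xt = Uk.T @ np.column_stack([W[keep], x[keep]])
            nk = int(keep.sum())
            Sj = Sk
        else:
            if np.ptp(x) == 0:
                continue
            yt = yt_all
            Xt = np.column_stack([Wt_all, U.T @ x])
            nk = n
            Sj = S
        _, _, beta, A_inv, sigma2 = _fit_single_snp(yt, Xt, Sj)
        if beta is None or A_inv is None:
            continue
        c = Xt.shape[1]
        b = beta[-1]
        se = float(np.sqrt(sigma2 * A_inv[-1, -1]))
        if se == 0 or not np.isfinite(se):
            continue
        tstat = b / se
        p = 2.0 * sps.t.sf(abs(tstat), df=nk - c)
        out[j] = (b, se, tstat**2, p)

    table = genotypes.snp_map()[["snp_id", "chromosome", "position"]].copy()
    table[["beta", "se", "wald", "p"]] = out
    valid = table["p"].dropna()
    lam = genomic_inflation(valid.to_numpy()) if len(valid) else np.nan
    return AssociationResult(
        table=table,
        n_samples=n,
        n_tests=int(len(valid)),
        lambda_gc=lam,
    )


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile / 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    chi = sps.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


@dataclass(frozen=True)
class BonferroniThreshold:
    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    @property
    def neg_log10(self) -> float:
        return float(-np.log10(self.threshold))


def bonferroni_threshold(alpha: float, n_tests: int) -> BonferroniThreshold:
    """Family-wise significance cutoff alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return BonferroniThreshold(alpha, int(n_tests))


# ---------------------------------------------------------------------------
# Permutation (max-statistic) threshold
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    empirical_p: float          # for the observed genome-wide minimum p
    threshold: float            # alpha-quantile of the permutation min-p null
    observed_min_p: float
    perm_min_p: np.ndarray
    snp_empirical_p: pd.DataFrame  # max-T adjusted per-SNP empirical p


def permutation_threshold(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    kinship: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Genome-wide empirical significance by phenotype permutation.

    Phenotype labels are permuted jointly against the (withheld) genotype
    and covariate rows; for each permutation the genome-wide minimum Wald p
    is recorded. The empirical p of the observed minimum is (r+1)/(n_perm+1)
    and the genome-wide threshold is the alpha-quantile of the min-p null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if kinship is None:
        kinship = compute_kinship(genotypes)
    observed = lmm_wald(genotypes, phenotype, kinship, covariates)
    obs_min = float(np.nanmin(observed.table["p"].to_numpy()))
    obs_p = observed.table["p"].to_numpy()

    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    mins = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        res = lmm_wald(genotypes, y[perm], kinship, covariates)
        mins[b] = np.nanmin(res.table["p"].to_numpy())
    r = int((mins <= obs_min).sum())
    emp = (r + 1) / (n_perm + 1)
    thr = float(np.quantile(mins, alpha, method="inverted_cdf"))
    snp_emp = (np.sum(mins[None, :] <= obs_p[:, None], axis=1) + 1) / (n_perm + 1)
    snp_df = observed.table[["snp_id", "p"]].copy()
    snp_df["empirical_p"] = np.where(np.isnan(obs_p), np.nan, snp_emp)
    return PermutationResult(
        empirical_p=float(emp),
        threshold=thr,
        observed_min_p=obs_min,
        perm_min_p=mins,
        snp_empirical_p=snp_df,
    )


# ---------------------------------------------------------------------------
# Variance explained (PVE) per region
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    region: str
    pve: float
    se: float
    p_lrt: float
    sigma2_g: float | np.ndarray
    sigma2_e: float
    n_snps: int
    converged: bool = True
    message: str = ""


def _region_grm(genotypes: GenotypeMatrix, region: Interval) -> tuple[np.ndarray, int]:
    chrom, start1, end1 = region.to_1based()
    in_region = (genotypes.chromosomes == chrom) & (
        (genotypes.positions >= start1) & (genotypes.positions <= end1)
    )
    m = int(in_region.sum())
    if m < 2:
        raise ValueError(f"region {region} contains {m} SNP(s); need >= 2")
    X = genotypes.dosages[:, in_region]
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - mu)
    poly = np.nanvar(X, axis=0) > 0
    Xc = Xc[:, poly]
    K = Xc @ Xc.T / max(int(poly.sum()), 1)
    d = float(np.mean(np.diag(K)))
    if d <= 0:
        raise ValueError(f"region {region}: no polymorphic SNPs")
    return K / d, m  # normalized so mean diagonal = 1


def _reml_vc_nll(vg: float, ve: float, yt, Xt, S) -> float:
    """Negative restricted log-likelihood at explicit variances (eigenbasis)."""
    n, c = Xt.shape
    d = vg * S + ve
    if np.any(d <= 0):
        return np.inf
    w = 1.0 / d
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - Xt @ beta
    quad = float(np.sum(w * resid**2))
    return 0.5 * (float(np.sum(np.log(d))) + logdet_A + quad)


def pve_single_region(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    region: Interval,
    label: str | None = None,
) -> VarianceComponents:
    """REML variance-component fit from one region's SNPs.

    The region GRM is normalised to unit mean diagonal, so PVE =
    s2_g / (s2_g + s2_e). The SE comes from the inverse numerical Hessian
    of the restricted likelihood via the delta method; P_LRT tests
    s2_g = 0 against the 0.5*chi2(1) boundary mixture.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    K, m = _region_grm(genotypes, region)
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ np.ones((len(y), 1))
    n, c = Xt.shape

    ld_star, nll, _, _, sigma2_e = _fit_single_snp(yt, Xt, S, bounds=(-18.0, 18.0))
    converged, message = True, ""
    if not np.isfinite(nll):
        converged, message = False, "REML profile did not converge"
    delta = float(np.exp(ld_star))
    vg = delta * sigma2_e
    ve = sigma2_e
    pve = vg / (vg + ve)

    # SE via numerical Hessian in (vg, ve), delta method for vg/(vg+ve)
    se = np.nan
    try:
        h = 1e-4 * max(vg + ve, 1e-8)
        H = np.zeros((2, 2))
        f0 = _reml_vc_nll(vg, ve, yt, Xt, S)

        def f(dg, de):
            return _reml_vc_nll(max(vg + dg, 1e-12), max(ve + de, 1e-12), yt, Xt, S)

        H[0, 0] = (f(h, 0) - 2 * f0 + f(-h, 0)) / h**2
        H[1, 1] = (f(0, h) - 2 * f0 + f(0, -h)) / h**2
        H[0, 1] = H[1, 0] = (
            f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)
        ) / (4 * h**2)
        cov = np.linalg.inv(H)
        tot = (vg + ve) ** 2
        grad = np.array([ve / tot, -vg / tot])
        var_pve = float(grad @ cov @ grad)
        se = float(np.sqrt(var_pve)) if var_pve > 0 else np.nan
    except np.linalg.LinAlgError:
        converged, message = False, "information matrix not invertible"

    # LRT against the no-genetic-component null (plain regression REML)
    nll_null = _reml_nll(-300.0, yt, Xt, np.zeros_like(S))[0]
    # _reml_nll profiles the scale; recompute both on the profiled form
    nll_full = _reml_nll(ld_star, yt, Xt, S)[0]
    lrt = max(0.0, 2.0 * (nll_null - nll_full))
    p_lrt = float(0.5 * sps.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

    return VarianceComponents(
        region=label or f"{region.chromosome}:{region.to_1based()[1]}-{region.to_1based()[2]}",
        pve=float(pve),
        se=se,
        p_lrt=p_lrt,
        sigma2_g=float(vg),
        sigma2_e=float(ve),
        n_snps=m,
        converged=converged,
        message=message,
    )


def pve_joint(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    regions: dict[str, Interval],
    include_genome_component: bool = True,
) -> VarianceComponents:
    """Joint multi-component REML: one GRM per region (plus, optionally, a
    whole-genome GRM from the remaining SNPs). Joint PVE is the summed
    regional genetic variance over total variance."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    Ks = []
    labels = []
    used = np.zeros(genotypes.n_snps, dtype=bool)
    for name, region in regions.items():
        K, _ = _region_grm(genotypes, region)
        Ks.append(K)
        labels.append(name)
        chrom, s1, e1 = region.to_1based()
        used |= (genotypes.chromosomes == chrom) & (
            (genotypes.positions >= s1) & (genotypes.positions <= e1)
        )
    if include_genome_component and (~used).sum() >= 2:
        X = genotypes.dosages[:, ~used]
        mu = np.nanmean(X, axis=0)
        Xc = np.where(np.isnan(X), 0.0, X - mu)
        poly = np.nanvar(X, axis=0) > 0
        if poly.sum() >= 2:
            Kg = Xc[:, poly] @ Xc[:, poly].T / int(poly.sum())
            d = float(np.mean(np.diag(Kg)))
            if d > 0:
                Ks.append(Kg / d)
                labels.append("genome")
    X1 = np.ones((n, 1))
    vy = float(np.var(y))

    def nll(log_v):
        v = np.exp(log_v)
        V = v[-1] * np.eye(n)
        for vi, Ki in zip(v[:-1], Ks):
            V = V + vi * Ki
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X1)
        A = X1.T @ Vi_X
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, X1.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        return 0.5 * (logdet_V + logdet_A + float(y @ Py))

    x0 = np.log(np.full(len(Ks) + 1, vy / (len(Ks) + 1)))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    v = np.exp(res.x)
    vg_regions = v[: len(regions)]
    total = float(v.sum())
    pve = float(vg_regions.sum() / total)

    # LRT against no regional components (genome + residual only)
    def nll_null(log_v):
        return nll(np.concatenate([np.full(len(regions), -30.0), log_v]))

    k_rest = len(Ks) + 1 - len(regions)
    res0 = optimize.minimize(
        nll_null, np.log(np.full(k_rest, vy / max(k_rest, 1))),
        method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    lrt = max(0.0, 2.0 * (res0.fun - res.fun))
    df = len(regions)
    p_lrt = float(0.5 * sps.chi2.sf(lrt, df=df)) if lrt > 0 else 0.5
    return VarianceComponents(
        region="+".join(regions),
        pve=pve,
        se=np.nan,
        p_lrt=p_lrt,
        sigma2_g=vg_regions,
        sigma2_e=float(v[-1]),
        n_snps=int(used.sum()),
        converged=bool(res.success),
        message="" if res.success else res.message,
    )


def pve_region(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    regions: dict[str, Interval],
    joint: bool = True,
) -> list[VarianceComponents]:
    """PVE per region, plus a joint multi-component fit when requested."""
    out = [
        pve_single_region(genotypes, phenotype, region, label=name)
        for name, region in regions.items()
    ]
    if joint and len(regions) > 1:
        out.append(pve_joint(genotypes, phenotype, regions))
    return out


# ---------------------------------------------------------------------------
# Conditioned-cohort construction
# ---------------------------------------------------------------------------

def subset_conditioned_cohort(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    ages: np.ndarray,
    haplotype_dosages: np.ndarray,
    zygosity_filter: str = "het",
    min_control_age: float = 0.0,
):
    """Cohort subset for a conditioned follow-up scan.

    Retains samples with the requested risk-haplotype zygosity (``het``,
    ``hom``, ``carrier`` or ``any``) and drops controls younger than
    ``min_control_age`` at collection. Returns (genotypes, phenotype, counts).
    """
    y = np.asarray(phenotype, dtype=int)
    ages = np.asarray(ages, dtype=float)
    hd = np.asarray(haplotype_dosages, dtype=int)
    if zygosity_filter == "het":
        zyg = hd == 1
    elif zygosity_filter == "hom":
        zyg = hd == 2
    elif zygosity_filter == "carrier":
        zyg = hd >= 1
    elif zygosity_filter == "any":
        zyg = np.ones_like(hd, dtype=bool)
    else:
        raise ValueError(f"unknown zygosity filter {zygosity_filter!r}")
    age_ok = (y == 1) | (ages >= min_control_age)
    keep = zyg & age_ok
    if not keep.any():
        raise ValueError("conditioned subset is empty")
    counts = {
        "n_cases": int((y[keep] == 1).sum()),
        "n_controls": int((y[keep] == 0).sum()),
        "dropped_zygosity": int((~zyg).sum()),
        "dropped_age": int((zyg & ~age_ok).sum()),
    }
    return genotypes.subset_samples(keep), y[keep], counts
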