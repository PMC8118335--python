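"""Genotype-level epidemiological statistics.

Two-locus penetrance tables (risk-haplotype dosage x lead-SNP genotype),
Fisher's exact test with odds ratios and Woolf confidence intervals, and
cross-cohort p-value combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Two-locus genotype class labels: lower-case = non-risk allele.
#: "A" is the risk haplotype at the first locus, "B" the risk allele at the
#: second locus' lead SNP.
GENOTYPE_CLASSES = [
    "aabb", "aaBb", "aaBB",
    "Aabb", "AaBb", "AaBB",
    "AAbb", "AABb", "AABB",
]

def genotype_class(dosage_a: int, dosage_b: int) -> str:
    """Label a two-locus genotype, e.g. (1, 2) -> 'AaBB'."""
    a = {0: "aa", 1: "Aa", 2: "AA"}[int(dosage_a)]
    b = {0: "bb", 1: "Bb", 2: "BB"}[int(dosage_b)]
    return a + b


def penetrance_table(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    phenotype: np.ndarray,
) -> pd.DataFrame:
    """Nine-class two-locus penetrance table.

    Parameters
    ----------
    dosage_a : array of {0,1,2}
        Risk-haplotype dosage at the first locus per sample.
    dosage_b : array of {0,1,2}
        Risk-allele dosage at the second locus' lead SNP per sample.
    phenotype : array of {0,1}
        1 = case.

    Returns
    -------
    DataFrame indexed by genotype class with columns ``cases``,
    ``controls`` and ``penetrance_pct`` (rounded percent of samples in the
    class who are cases; NA — reported "-" — where the class is empty).
    """
    dosage_a = np.asarray(dosage_a, dtype=int)
    dosage_b = np.asarray(dosage_b, dtype=int)
    phenotype = np.asarray(phenotype, dtype=int)
    rows = []
    for cls in GENOTYPE_CLASSES:
        da = {"aa": 0, "Aa": 1, "AA": 2}[cls[:2]]
        db = {"bb": 0, "Bb": 1, "BB": 2}[cls[2:]]
        mask = (dosage_a == da) & (dosage_b == db)
        cases = int((phenotype[mask] == 1).sum())
        controls = int((phenotype[mask] == 0).sum())
        rows.append((cls, cases, controls, penetrance_percent(cases, controls)))
    df = pd.DataFrame(rows, columns=["genotype", "cases", "controls", "penetrance_pct"])
    return df.set_index("genotype")


def penetrance_percent(cases: int, controls: int) -> float:
    """round(100 * cases / (cases + controls)); NaN when the class is empty."""
    total = cases + controls
    if total == 0:
        return float("nan")
    return float(round(100.0 * cases / total))


def format_penetrance(value: float) -> str:
    """Render a penetrance percent, using '-' for empty classes."""
    return "-" if np.isnan(value) else f"{value:.0f}"


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test with OR and Woolf 95% CI.

    ``table`` is [[exposed-case, exposed-control], [unexposed-case,
    unexposed-control]]. The two-sided p sums hypergeometric outcome
    probabilities no larger than the observed one (minimum-likelihood rule).
    The OR is ad/bc; its CI uses Woolf's log method with the
    Haldane–Anscombe 0.5 correction applied to every cell when any cell is
    zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b = t[0]
    c, d = t[1]
    if t.sum() == 0:
        raise ValueError("all-zero table")
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    if b * c == 0 or a * d == 0:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = a, b, c, d
    or_point = (a * d / (b * c)) if b * c > 0 else (ah * dh / (bh * ch))
    log_or = np.log(ah * dh / (bh * ch))
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    z = sps.norm.ppf(0.975)
    return FisherResult(
        p_value=p,
        odds_ratio=float(or_point),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        table=((int(a), int(b)), (int(c), int(d))),
    )


# ---------------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------------

def combine_pvalues(
    p_values,
    method: str = "fisher",
    weights=None,
    signs=None,
) -> float:
    """Combine two-sided p-values across cohorts.

    Fisher: -2 sum(ln p) referred to chi-square with 2k df. Stouffer: the
    two-sided inputs are halved, z_i = Phi^-1(1 - p_i/2) carries each
    cohort's effect direction (``signs``, +-1; all taken concordant when
    omitted, the usual meta-analysis of a shared risk allele), and the
    weighted combined z is doubled back to a two-sided p. Stouffer is only
    calibrated under the null when true effect directions are supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        tiny = np.finfo(float).tiny
        warnings.warn("p = 0 clamped to smallest representable positive value")
        p = np.clip(p, tiny, None)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "fisher":
        stat = -2.0 * np.sum(np.log(p))
        return float(sps.chi2.sf(stat, df=2 * p.size))
    if method == "stouffer":
        w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != p.shape or (w <= 0).any():
            raise ValueError("weights must be positive and match p-values")
        s = np.ones_like(p) if signs is None else np.sign(np.asarray(signs, dtype=float))
        if s.shape != p.shape or (s == 0).any():
            raise ValueError("signs must be +-1 and match p-values")
        z = s * sps.norm.isf(p / 2.0)
        zc = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
        return float(min(1.0, 2.0 * sps.norm.sf(abs(zc))))
    raise ValueError(f"unknown method {method!r}")
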