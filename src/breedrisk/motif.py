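"""Differential transcription-factor-binding assessment of risk alleles.

Two scoring paths per variant and motif, mirroring the two-program
consensus design:

* a log-odds PWM scan (best site over both strands, log2 scale) with an
  exact p-value from dynamic programming over the discretised per-column
  score distribution under the background model, and BH q-values across
  motifs per window;
* a biophysical affinity in the TRAP formulation — per-site mismatch
  energy E = (1/lambda) * sum_j ln(w_max,j / w_base,j), site occupancy
  R0 e^-E / (1 + R0 e^-E) with ln R0 = slope * motif_length + intercept,
  summed over all positions and both strands.

A consensus call requires the scan path significant (adjusted p below
``scan_alpha``) and an affinity log-ratio between alleles of at least
``affinity_log_ratio_min`` in magnitude for the same motif.

Scores are discretised to a fixed bin width before scanning, so the
reported best score and its p-value refer to the same (binned) score
scale and the DP p-value is exact for that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: log2-score discretisation for the exact p-value DP
SCORE_BIN = 1e-3


@dataclass
class MotifModel:
    """A position frequency matrix with pseudocount and background.

    ``pfm`` is (w, 4) over A,C,G,T. Probabilities are
    (pfm + pseudocount * background) / (1 + pseudocount), so each column
    (row of the matrix) sums to one after pseudocount normalisation; any
    remaining zero entries are floored at 1e-9 to keep log scores finite.
    """

    motif_id: str
    pfm: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError("pfm must be (w, 4) over A,C,G,T")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def length(self) -> int:
        return self.pfm.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        p = (self.pfm + self.pseudocount * self.background[None, :]) / (
            1.0 + self.pseudocount
        )
        p = np.clip(p, 1e-9, None)
        return p / p.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """Per-column log2(motif/background), discretised to SCORE_BIN."""
        lo = np.log2(self.probabilities / self.background[None, :])
        return np.round(lo / SCORE_BIN) * SCORE_BIN

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            motif_id=self.motif_id,
            pfm=self.pfm[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )

    @classmethod
    def from_meme_dict(cls, d: dict, pseudocount: float = 0.0) -> "MotifModel":
        return cls(d["id"], d["matrix"], pseudocount, d.get("background"))


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; ambiguous bases -> -1 (scored as background)."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Allele windows
# ---------------------------------------------------------------------------

@dataclass
class AlleleWindowPair:
    """Risk/non-risk sequences around a variant (flank bp each side)."""

    variant_id: str
    risk_sequence: str
    nonrisk_sequence: str
    flank: int


def make_allele_windows(
    reference,
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    flank: int = 30,
    risk_allele: str = "alt",
    variant_id: str | None = None,
) -> AlleleWindowPair:
    """Build the risk/non-risk sequence pair around one variant.

    ``reference`` is a mapping of contig name to sequence (a dict or a
    ``pyfaidx.Fasta``); ``position`` is 1-based. Substitutions, insertions
    and deletions are applied literally, so indel windows differ in length
    by the net allele-length difference. Windows overrunning a contig end
    are truncated with a warning.
    """
    contig = reference[chromosome]
    seq = (contig if isinstance(contig, str) else str(contig[:])).upper()
    pos0 = position - 1
    if pos0 < 0 or pos0 + len(ref) > len(seq):
        raise ValueError(f"variant {chromosome}:{position} outside reference bounds")
    found = seq[pos0 : pos0 + len(ref)]
    if found != ref.upper():
        raise ValueError(
            f"reference mismatch at {chromosome}:{position}: expected {ref}, found {found}"
        )
    left_start = pos0 - flank
    if left_start < 0:
        warnings.warn(
            f"{chromosome}:{position}: left flank truncated to {pos0} bp"
        )
        left_start = 0
    right_end = pos0 + len(ref) + flank
    if right_end > len(seq):
        warnings.warn(
            f"{chromosome}:{position}: right flank truncated to {len(seq) - pos0 - len(ref)} bp"
        )
        right_end = len(seq)
    left = seq[left_start:pos0]
    right = seq[pos0 + len(ref) : right_end]
    with_ref = left + ref.upper() + right
    with_alt = left + alt.upper() + right
    vid = variant_id or f"{chromosome}:{position}:{ref}>{alt}"
    if risk_allele == "alt":
        return AlleleWindowPair(vid, with_alt, with_ref, flank)
    if risk_allele == "ref":
        return AlleleWindowPair(vid, with_ref, with_alt, flank)
    raise ValueError("risk_allele must be 'ref' or 'alt'")


# ---------------------------------------------------------------------------
# Log-odds scan with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    motif_id: str
    best_score: float
    best_position: int    # 0-based offset of the best site
    best_strand: str      # '+' or '-'
    p_value: float
    q_value: float = float("nan")


def _site_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every site of one strand; ambiguous bases contribute 0."""
    w = lo.shape[0]
    n_sites = len(codes) - w + 1
    if n_sites <= 0:
        return np.empty(0)
    out = np.zeros(n_sites)
    for j in range(w):
        col = codes[j : j + n_sites]
        contrib = np.where(col >= 0, lo[j, np.clip(col, 0, 3)], 0.0)
        out += contrib
    return out


def exact_score_pvalue(motif: MotifModel, score: float) -> float:
    """P(site score >= ``score``) for one site under the background model.

    Exact dynamic programming over the discretised per-column score
    distribution: column scores are integers on the SCORE_BIN grid, so the
    convolution is exact and the result equals exhaustive k-mer
    enumeration on the same grid.
    """
    lo_int = np.round(motif.log_odds / SCORE_BIN).astype(np.int64)
    bg = motif.background
    offset = -int(lo_int.min(axis=1).sum())
    size = int(lo_int.max(axis=1).sum()) + offset + 1
    dist = np.zeros(size)
    dist[offset] = 1.0
    for j in range(motif.length):
        new = np.zeros(size)
        for b in range(4):
            shift = int(lo_int[j, b])
            if shift >= 0:
                new[shift:] += bg[b] * dist[: size - shift] if shift else bg[b] * dist
            else:
                new[:shift] += bg[b] * dist[-shift:]
        dist = new
    score_int = int(round(score / SCORE_BIN)) + offset
    if score_int <= 0:
        return 1.0
    if score_int >= size:
        return 0.0
    return float(dist[score_int:].sum())


def pwm_scan(window: str, motif: MotifModel) -> ScanResult:
    """Best log-odds site over both strands with its exact p-value."""
    if len(window) < motif.length:
        raise ValueError(
            f"window ({len(window)} bp) shorter than motif ({motif.length} bp)"
        )
    codes = encode_sequence(window)
    lo = motif.log_odds
    fwd = _site_scores(codes, lo)
    rev = _site_scores(encode_sequence(reverse_complement(window)), lo)
    best_f = int(np.argmax(fwd))
    best_r = int(np.argmax(rev))
    if rev.size and (not fwd.size or rev[best_r] > fwd[best_f]):
        best_score = float(rev[best_r])
        strand = "-"
        best_pos = len(window) - motif.length - best_r
    else:
        best_score = float(fwd[best_f])
        strand = "+"
        best_pos = best_f
    p = exact_score_pvalue(motif, best_score)
    return ScanResult(motif.motif_id, best_score, best_pos, strand, p)


def scan_motifs(window: str, motifs: list[MotifModel]) -> list[ScanResult]:
    """Scan all motifs against one window; BH q-values across motifs."""
    results = [pwm_scan(window, m) for m in motifs]
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


# ---------------------------------------------------------------------------
# TRAP-style biophysical affinity
# ---------------------------------------------------------------------------

def affinity_score(
    window: str,
    motif: MotifModel,
    lambda_scale: float = 0.7,
    r0_slope: float = 0.584,
    r0_intercept: float = -5.66,
) -> float:
    """Expected occupancy summed over all sites and both strands.

    Mismatch energy per site: E = (1/lambda) * sum_j ln(w_max,j / w_j(base));
    ambiguous bases contribute the column mean energy. R0 follows
    ln R0 = r0_slope * motif_length + r0_intercept.
    """
    if len(window) < motif.length:
        raise ValueError("window shorter than motif")
    probs = motif.probabilities
    w_max = probs.max(axis=1)
    # per-column mismatch energies (ln scale)
    energy = np.log(w_max[:, None] / probs) / lambda_scale  # (w, 4)
    mean_col = energy.mean(axis=1)
    ln_r0 = r0_slope * motif.length + r0_intercept
    r0 = np.exp(ln_r0)

    total = 0.0
    for seq in (window, reverse_complement(window)):
        codes = encode_sequence(seq)
        n_sites = len(codes) - motif.length + 1
        e_sites = np.zeros(n_sites)
        for j in range(motif.length):
            col = codes[j : j + n_sites]
            e_sites += np.where(col >= 0, energy[j, np.clip(col, 0, 3)], mean_col[j])
        x = r0 * np.exp(-e_sites)
        total += float(np.sum(x / (1.0 + x)))
    return total


# ---------------------------------------------------------------------------
# Consensus calls
# ---------------------------------------------------------------------------

@dataclass
class BindingCall:
    variant_id: str
    motif_id: str
    scan_risk: ScanResult
    scan_nonrisk: ScanResult
    affinity_risk: float
    affinity_nonrisk: float
    affinity_log_ratio: float
    scan_significant: bool
    affinity_significant: bool
    consensus: bool
    preferred_allele: str  # 'risk', 'non-risk' or 'none'


def consensus_call(
    pair: AlleleWindowPair,
    motifs: list[MotifModel],
    scan_alpha: float = 0.05,
    affinity_log_ratio_min: float = 0.5,
    lambda_scale: float = 0.7,
    r0_slope: float = 0.584,
    r0_intercept: float = -5.66,
) -> list[BindingCall]:
    """Two-path differential-binding assessment of one variant.

    A motif earns a consensus flag only when it is significant in the scan
    path (BH-adjusted p < ``scan_alpha`` in either allele window) *and*
    the affinity path shows |log10 ratio| >= ``affinity_log_ratio_min``
    between alleles. The preferred-binding allele is the one with higher
    summed occupancy. Identical allele sequences produce no call.
    """
    calls: list[BindingCall] = []
    if pair.risk_sequence == pair.nonrisk_sequence:
        return calls
    scans_risk = scan_motifs(pair.risk_sequence, motifs)
    scans_non = scan_motifs(pair.nonrisk_sequence, motifs)
    for m, sr, sn in zip(motifs, scans_risk, scans_non):
        ar = affinity_score(pair.risk_sequence, m, lambda_scale, r0_slope, r0_intercept)
        an = affinity_score(pair.nonrisk_sequence, m, lambda_scale, r0_slope, r0_intercept)
        log_ratio = float(np.log10(max(ar, 1e-300) / max(an, 1e-300)))
        scan_sig = min(sr.q_value, sn.q_value) < scan_alpha
        aff_sig = abs(log_ratio) >= affinity_log_ratio_min
        if ar > an:
            preferred = "risk"
        elif an > ar:
            preferred = "non-risk"
        else:
            preferred = "none"
        calls.append(
            BindingCall(
                variant_id=pair.variant_id,
                motif_id=m.motif_id,
                scan_risk=sr,
                scan_nonrisk=sn,
                affinity_risk=ar,
                affinity_nonrisk=an,
                affinity_log_ratio=log_ratio,
                scan_significant=bool(scan_sig),
                affinity_significant=bool(aff_sig),
                consensus=bool(scan_sig and aff_sig),
                preferred_allele=preferred,
            )
        )
    return calls
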