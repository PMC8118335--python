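"""The candidate-variant filter cascade.

Whole-genome-sequence variants inside the risk interval are reduced in
three steps: (1) segregation — every WGS sample's alternate-allele dosage
must equal that sample's known risk-haplotype dosage; (2) panel allele
frequency — the variant must be rarer than a cutoff (strictly below, per
the AF<50% rule) in a multi-breed panel that excludes the focal breeds;
(3) regulatory overlap — the position must fall in at least one
promoter/enhancer/open-chromatin interval (OR across sources). Stage
flags are monotone: a variant passing stage k passed all earlier stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalSet

logger = logging.getLogger(__name__)

#: required columns of a variant table; per-sample genotype columns are
#: ``gt_<sample>`` holding alternate-allele dosage 0/1/2 (NaN = no call)
VARIANT_COLUMNS = ["chromosome", "position", "ref", "alt"]


@dataclass(frozen=True)
class SampleSpec:
    """One WGS sample and its expected risk-haplotype dosage."""

    sample_id: str
    expected_dosage: int

    def __post_init__(self) -> None:
        if self.expected_dosage not in (0, 1, 2):
            raise ValueError("expected dosage must be 0, 1 or 2")


@dataclass
class CascadeReport:
    """Survivor table and per-stage counts of the three-step cascade."""

    variants: pd.DataFrame
    n_input: int
    n_segregating: int
    n_rare: int
    n_regulatory: int

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_segregating, self.n_rare, self.n_regulatory)


def _genotype_columns(variants: pd.DataFrame, spec: list[SampleSpec]) -> list[str]:
    cols = []
    for s in spec:
        col = f"gt_{s.sample_id}"
        if col not in variants.columns:
            raise ValueError(f"spec sample {s.sample_id!r} absent from variant table")
        cols.append(col)
    return cols


def segregation_filter(
    variants: pd.DataFrame,
    spec: list[SampleSpec],
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Retain variants concordant with every sample's haplotype dosage.

    A heterozygous-haplotype sample must be 0/1 (dosage exactly 1), a
    homozygous sample 1/1, and a non-carrier 0/0 — a variant riding the
    shared haplotype must appear on exactly that copy number. Missing
    genotypes exclude the variant unless ``allow_missing``.
    """
    if {s.sample_id for s in spec} and len({s.sample_id for s in spec}) != len(spec):
        raise ValueError("every WGS sample must be listed exactly once")
    cols = _genotype_columns(variants, spec)
    if variants.empty:
        return variants.copy()
    keep = np.ones(len(variants), dtype=bool)
    for s, col in zip(spec, cols):
        g = variants[col].to_numpy(dtype=float)
        match = g == float(s.expected_dosage)
        if allow_missing:
            match |= np.isnan(g)
        keep &= match
    return variants[keep].copy()


def allele_frequency_filter(
    variants: pd.DataFrame,
    panel_af: pd.Series | dict | None = None,
    max_af: float = 0.5,
) -> pd.DataFrame:
    """Retain variants with panel allele frequency strictly below ``max_af``.

    ``panel_af`` maps "chromosome:position:ref>alt" keys (or matches a
    ``panel_af`` column already present) to frequencies computed over
    called alleles in the breed panel, which must exclude the focal
    breeds. Variants absent from the panel are treated as frequency 0 and
    logged.
    """
    v = variants.copy()
    if panel_af is not None:
        keys = variant_keys(v)
        af = pd.Series(panel_af)
        mapped = keys.map(af)
        missing = mapped.isna()
        if missing.any():
            for k in keys[missing]:
                logger.info("variant %s absent from panel; AF treated as 0", k)
        v["panel_af"] = mapped.fillna(0.0).to_numpy()
    elif "panel_af" not in v.columns:
        raise ValueError("no panel_af column and no panel provided")
    return v[v["panel_af"] < max_af].copy()


def variant_keys(variants: pd.DataFrame) -> pd.Series:
    return (
        variants["chromosome"].astype(str)
        + ":"
        + variants["position"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ">"
        + variants["alt"].astype(str)
    )


def regulatory_overlap_filter(
    variants: pd.DataFrame,
    regulatory: dict[str, IntervalSet] | IntervalSet,
) -> pd.DataFrame:
    """Retain variants overlapping >=1 regulatory interval; label sources.

    ``regulatory`` maps a source tag (H3K4me1, H3K4me3, ATAC, ...) to its
    merged interval set; a bare IntervalSet is treated as one unnamed
    source. Overlap is positional (1-based variant position against
    0-based half-open intervals), OR semantics across sources; the
    ``regulatory_sources`` column records which sources overlap.
    """
    if isinstance(regulatory, IntervalSet):
        regulatory = {"regulatory": regulatory}
    merged = {src: ivs.merge() for src, ivs in regulatory.items()}
    v = variants.copy()
    labels = []
    for _, row in v.iterrows():
        hits = [
            src
            for src, ivs in merged.items()
            if ivs.contains_position(str(row["chromosome"]), int(row["position"]))
        ]
        labels.append(",".join(hits))
    v["regulatory_sources"] = labels
    return v[v["regulatory_sources"] != ""].copy()


def run_cascade(
    variants: pd.DataFrame,
    spec: list[SampleSpec],
    panel_af: pd.Series | dict | None = None,
    regulatory: dict[str, IntervalSet] | IntervalSet | None = None,
    max_af: float = 0.5,
    allow_missing: bool = False,
) -> CascadeReport:
    """Apply segregation, allele-frequency and regulatory filters in order."""
    for col in VARIANT_COLUMNS:
        if col not in variants.columns:
            raise ValueError(f"variant table missing column {col!r}")
    stage1 = segregation_filter(variants, spec, allow_missing=allow_missing)
    stage2 = allele_frequency_filter(stage1, panel_af, max_af=max_af) if len(stage1) else stage1
    if regulatory is None:
        regulatory = IntervalSet()
    stage3 = regulatory_overlap_filter(stage2, regulatory) if len(stage2) else stage2
    flag_anomalous_genotypes(stage3, spec)
    return CascadeReport(
        variants=stage3,
        n_input=int(len(variants)),
        n_segregating=int(len(stage1)),
        n_rare=int(len(stage2)),
        n_regulatory=int(len(stage3)),
    )


def flag_anomalous_genotypes(variants: pd.DataFrame, spec: list[SampleSpec]) -> None:
    """Log variants whose genotype pattern hints at a structural artefact
    (stand-in hook for visual read-level inspection, which is out of band)."""
    if variants.empty:
        return
    cols = [f"gt_{s.sample_id}" for s in spec if f"gt_{s.sample_id}" in variants.columns]
    if not cols:
        return
    g = variants[cols].to_numpy(dtype=float)
    anomalous = np.isnan(g).sum(axis=1) > len(cols) / 2
    for key in variant_keys(variants[anomalous]):
        logger.warning("variant %s: mostly-missing genotypes; inspect reads", key)


def decompose_multiallelic(variants: pd.DataFrame) -> pd.DataFrame:
    """Split comma-separated ALT records into per-alternate biallelic rows.

    Genotype dosages for each split row count only the focal alternate
    allele; other alternates at the site count as reference there.
    """
    rows = []
    gt_cols = [c for c in variants.columns if c.startswith("gt_")]
    for _, row in variants.iterrows():
        alts = str(row["alt"]).split(",")
        if len(alts) == 1:
            rows.append(row)
            continue
        for k, alt in enumerate(alts, start=1):
            r = row.copy()
            r["alt"] = alt
            for col in gt_cols:
                allele_counts = row[col]
                if isinstance(allele_counts, (list, tuple)):
                    r[col] = float(sum(1 for a in allele_counts if a == k))
            rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)
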