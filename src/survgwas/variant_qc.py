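"""Per-variant summary statistics and QC filters.

Common-variant scan filters (retention side of the printed exclusion rules):
imputation INFO >= 0.3, missing rate <= 0.05, MAF >= 0.1%, and
Hardy-Weinberg exact-test p >= 1e-6.  Rare-variant selection keeps variants
with MAF strictly below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .constants import (
    QC_MAX_MISSING,
    QC_MIN_HWE_P,
    QC_MIN_INFO,
    QC_MIN_MAF,
    RARE_MAF_MAX,
)

MISSING = -1


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotype data.

    ``genotypes`` are hard calls in {0, 1, 2} with -1 for missing;
    ``dosages`` are expected alt-allele counts in [0, 2] (may be None).
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray | None = None
    dosages: np.ndarray | None = None
    info_score: float = 1.0
    alt_depths: np.ndarray | None = None
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based; pos must be >= 1")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.dosages is not None:
            self.dosages = np.asarray(self.dosages, dtype=float)
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValueError(f"dosages outside [0, 2] for {self.variant_id}")

    def hard_calls(self) -> np.ndarray:
        """Hard genotypes, rounding dosages when explicit calls are absent."""
        if self.genotypes is not None:
            return self.genotypes
        if self.dosages is None:
            raise ValueError(f"{self.variant_id} carries neither GT nor DS")
        return np.clip(np.rint(self.dosages), 0, 2).astype(np.int8)


@dataclass
class AlleleStats:
    maf: float
    mac: int
    missing_rate: float
    n_called: int
    alt_freq: float = field(default=np.nan)


def allele_stats(record: VariantRecord) -> AlleleStats:
    """Folded minor-allele frequency/count with missing calls excluded.

    Missing genotypes drop out of both numerator and denominator; MAC is the
    minor-allele count among called genotypes.
    """
    g = record.hard_calls()
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"all genotypes missing for {record.variant_id}")
    alt_count = int(g[called].sum())
    alt_freq = alt_count / (2 * n_called)
    maf = min(alt_freq, 1.0 - alt_freq)
    mac = min(alt_count, 2 * n_called - alt_count)
    missing_rate = 1.0 - n_called / g.size
    return AlleleStats(maf, mac, missing_rate, n_called, alt_freq)


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test on a genotype count triple.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts (same parity) whose conditional probability does not
    exceed that of the observed configuration.
    """
    counts = (hom_ref, het, hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * hom_ref + het         # fold not needed: formula is symmetric
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    hom_r = (n_a - hets) // 2
    hom_a = n - hom_r - hets
    logw = (
        -gammaln(hom_r + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(hom_a + 1.0)
        + hets * np.log(2.0)
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


def filter_variants_gwas(
    records: list[VariantRecord],
    min_info: float = QC_MIN_INFO,
    max_missing: float = QC_MAX_MISSING,
    min_maf: float = QC_MIN_MAF,
    min_hwe_p: float = QC_MIN_HWE_P,
):
    """Apply the common-variant QC filters.

    Retention is inclusive on the keep side (info == 0.3 is retained).
    Returns (retained_records, exclusion_log) where the log rows are
    (variant_id, rule, value) — one row per failed rule.
    """
    retained, log = [], []
    for rec in records:
        st = allele_stats(rec)
        g = rec.hard_calls()
        called = g[g != MISSING]
        hwe_p = hwe_exact_test(
            int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
        )
        failures = []
        if rec.info_score < min_info:
            failures.append(("info_score", rec.info_score))
        if st.missing_rate > max_missing:
            failures.append(("missing_rate", st.missing_rate))
        if st.maf < min_maf:
            failures.append(("maf", st.maf))
        if hwe_p < min_hwe_p:
            failures.append(("hwe_p", hwe_p))
        if failures:
            log.extend((rec.variant_id, rule, val) for rule, val in failures)
        else:
            retained.append(rec)
    return retained, log


def filter_variants_rare(
    records: list[VariantRecord], max_maf: float = RARE_MAF_MAX
) -> list[VariantRecord]:
    """Keep variants with MAF strictly below the rare threshold (1%)."""
    return [rec for rec in records if allele_stats(rec).maf < max_maf]
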