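"""Variant-allele-fraction summaries for clonal-hematopoiesis assessment.

Germline heterozygotes sequence at VAF ~ 0.5; clonally expanded somatic
variants (CHIP) occupy only a fraction of blood cells, so their VAF
distribution is left-shifted below 0.5.  A (gene, class) association is
flagged as CHIP-compatible when the 95% percentile-bootstrap confidence
interval of the mean carrier VAF lies entirely below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GERMLINE_VAF_CENTER, VAF_N_BOOT


@dataclass
class VAFRecord:
    variant_id: str
    subject_id: str
    alt_reads: int
    depth: int

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth


@dataclass
class GeneVAFSummary:
    gene: str
    variant_class: str
    n_carriers: int
    mean_vaf: float
    ci_lo: float
    ci_hi: float
    left_shifted: bool


def carrier_vaf(records: list, subject_ids=None) -> tuple[list, list]:
    """VAF per heterozygous carrier from allelic depths.

    ``records`` are VariantRecord objects carrying genotypes plus AD/DP
    arrays.  Only heterozygous calls (genotype == 1) yield a record;
    zero-depth carriers are skipped and logged.  Returns (vaf_records, log).
    """
    out, log = [], []
    for rec in records:
        if rec.alt_depths is None or rec.depths is None:
            raise ValueError(f"{rec.variant_id}: allelic depth fields are absent")
        g = rec.hard_calls()
        ids = subject_ids if subject_ids is not None else np.arange(g.size).astype(str)
        for i in np.flatnonzero(g == 1):
            depth = int(rec.depths[i])
            if depth == 0:
                log.append((rec.variant_id, str(ids[i]), "zero_depth"))
                continue
            alt = int(rec.alt_depths[i])
            out.append(VAFRecord(rec.variant_id, str(ids[i]), alt, depth))
    return out, log


def gene_vaf_summary(
    records: list,
    gene: str = "",
    variant_class: str = "",
    n_boot: int = VAF_N_BOOT,
    seed: int = 0,
    germline_center: float = GERMLINE_VAF_CENTER,
) -> GeneVAFSummary:
    """Mean carrier VAF with a seeded percentile-bootstrap 95% CI.

    Carrier-level VAFs are pooled across the gene's variants and resampled
    at the carrier level (10,000 replicates by default).
    """
    vafs = np.array([r.vaf for r in records], dtype=float)
    if vafs.size < 2:
        raise ValueError("need at least 2 carrier VAF records for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vafs.size, size=(n_boot, vafs.size))
    boot_means = vafs[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    mean = float(vafs.mean())
    summary = GeneVAFSummary(
        gene, variant_class, int(vafs.size), mean, float(lo), float(hi), False
    )
    summary.left_shifted = classify_shift(summary, germline_center)
    return summary


def classify_shift(
    summary: GeneVAFSummary, germline_center: float = GERMLINE_VAF_CENTER
) -> bool:
    """Left-shifted iff the CI upper bound lies strictly below the center."""
    return bool(summary.ci_hi < germline_center)


def summarize_genes(
    vaf_by_set: dict,
    n_boot: int = VAF_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(gene, class) VAF summaries as a table.

    ``vaf_by_set`` maps (gene, class) -> list of VAFRecord.  Sets with fewer
    than 2 records are skipped.  Bootstrap seeds are derived per set from
    ``seed`` so results do not depend on dict ordering.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for (gene, vclass), recs in sorted(vaf_by_set.items()):
        if len(recs) < 2:
            continue
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        s = gene_vaf_summary(recs, gene, vclass, n_boot=n_boot, seed=child)
        rows.append(s.__dict__)
    return pd.DataFrame(
        rows,
        columns=["gene", "variant_class", "n_carriers", "mean_vaf", "ci_lo", "ci_hi", "left_shifted"],
    )
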