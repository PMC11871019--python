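"""Analysis-wide default thresholds and constants.

Every printed constant the pipeline uses lives in this one table so a run
manifest can record exactly which thresholds were in force.  All values are
overridable through :class:`survgwas.interface.RunConfig`.
"""

from __future__ import annotations

#: Genome-wide significance for the common-variant scan.
GENOME_WIDE_P = 5.0e-8
#: Suggestive threshold for the common-variant scan.
SUGGESTIVE_P = 1.0e-5
#: Gene-wide significance for the rare-variant burden/SKAT-O tests.
GENE_WIDE_P = 7.4e-7

#: Common-variant QC: minimum imputation INFO score (keep if >= this).
QC_MIN_INFO = 0.3
#: Common-variant QC: maximum genotype missing rate (keep if <= this).
QC_MAX_MISSING = 0.05
#: Common-variant QC: minimum minor allele frequency (keep if >= this).
QC_MIN_MAF = 0.001
#: Common-variant QC: minimum Hardy-Weinberg exact-test p (keep if >= this).
QC_MIN_HWE_P = 1.0e-6

#: Rare-variant selection: strict MAF upper bound.
RARE_MAF_MAX = 0.01
#: Minimum carriers for a (gene, class) set to be tested.
MIN_CARRIERS = 10
#: Minimum minor allele count for the per-variant Cox screen.
MAC_MIN = 3

#: Missense pathogenicity thresholds (inclusive).
ALPHAMISSENSE_MIN = 0.7
REVEL_MIN = 0.75

#: Consequence terms classed as loss-of-function.
LOF_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "start_lost",
        "stop_lost",
        "transcript_ablation",
        "feature_elongation",
        "feature_truncation",
    }
)

#: PheWAS: minimum cases (binary) / observations (continuous).
PHEWAS_MIN_CASES = 100

#: Bootstrap replicates for VAF confidence intervals.
VAF_N_BOOT = 10_000
#: Germline heterozygote VAF expectation used for left-shift calls.
GERMLINE_VAF_CENTER = 0.5

#: Family-wise alpha for Bonferroni-style thresholds.
ALPHA = 0.05

#: SKAT-O mixing grid over rho (burden weight).
SKATO_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
#: Variant-weight Beta density parameters applied to MAF.
SKAT_WEIGHT_BETA = (1.0, 25.0)

DEFAULTS = {
    "genome_wide_p": GENOME_WIDE_P,
    "suggestive_p": SUGGESTIVE_P,
    "gene_wide_p": GENE_WIDE_P,
    "qc_min_info": QC_MIN_INFO,
    "qc_max_missing": QC_MAX_MISSING,
    "qc_min_maf": QC_MIN_MAF,
    "qc_min_hwe_p": QC_MIN_HWE_P,
    "rare_maf_max": RARE_MAF_MAX,
    "min_carriers": MIN_CARRIERS,
    "mac_min": MAC_MIN,
    "alphamissense_min": ALPHAMISSENSE_MIN,
    "revel_min": REVEL_MIN,
    "phewas_min_cases": PHEWAS_MIN_CASES,
    "vaf_n_boot": VAF_N_BOOT,
    "germline_vaf_center": GERMLINE_VAF_CENTER,
    "alpha": ALPHA,
    "skato_rho_grid": SKATO_RHO_GRID,
    "skat_weight_beta": SKAT_WEIGHT_BETA,
}
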