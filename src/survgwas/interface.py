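"""Readers/writers for the standard formats and the pipeline driver.

Genotypes travel as VCF v4.2 (FORMAT GT, DS, AD, DP; INFO INFO_SCORE);
subjects, annotations, phenotypes, and results are tab-delimited tables.
Positions are 1-based at the VCF boundary; multiallelic records are split
into biallelic rows with the alt allele as the effect allele.  The pipeline
runs the stages in the published analysis order: QC -> null Cox model and
Martingale residuals -> common-variant scan; annotation -> gene sets ->
burden/SKAT-O -> carrier Cox/KM -> per-variant screen -> VAF -> PheWAS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import chip_vaf, gwas_scan, phewas_lite, rare_variant, variant_qc
from .constants import DEFAULTS
from .survival_core import Cohort, fit_cox_null, kaplan_meier, martingale_residuals
from .variant_qc import MISSING, VariantRecord

GENOTYPE_MODES = ("dosage", "hardcall", "depths")
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(records: list, subject_ids, path) -> Path:
    """Write biallelic records as uncompressed VCF v4.2.

    FORMAT is GT:DS for array-style records and GT:DS:AD:DP when read
    depths are present.  INFO carries the imputation INFO_SCORE.
    """
    path = Path(path)
    subject_ids = list(subject_ids)
    contigs = sorted({str(r.chrom) for r in records})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subject_ids),
    ]
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        g = rec.hard_calls()
        ds = rec.dosages if rec.dosages is not None else g.astype(float)
        has_depth = rec.alt_depths is not None and rec.depths is not None
        fmt = "GT:DS:AD:DP" if has_depth else "GT:DS"
        cells = []
        for i in range(len(subject_ids)):
            cell = f"{_GT_STR[int(g[i])]}:{ds[i]:.6g}"
            if has_depth:
                ref_reads = int(rec.depths[i]) - int(rec.alt_depths[i])
                cell += f":{ref_reads},{int(rec.alt_depths[i])}:{int(rec.depths[i])}"
            cells.append(cell)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
            f"INFO_SCORE={rec.info_score:.4g}\t{fmt}\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_genotypes(path, mode: str = "hardcall", variant_ids=None) -> tuple[list, list]:
    """Read a VCF into VariantRecords; multiallelic sites split per alt.

    ``mode`` selects the required FORMAT fields: ``dosage`` needs DS,
    ``hardcall`` needs GT, ``depths`` needs GT plus AD and DP; a missing
    required field raises naming it.  ``variant_ids`` restricts reading to a
    subset (e.g. depths only for sequenced rare variants).  Returns
    (records, sample_ids).
    """
    if mode not in GENOTYPE_MODES:
        raise ValueError(f"mode must be one of {GENOTYPE_MODES}")
    wanted = set(variant_ids) if variant_ids is not None else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    records = []
    for v in vcf:
        if wanted is not None and v.ID not in wanted:
            continue
        alts = v.ALT
        gts = np.array([gt[:2] for gt in v.genotypes], dtype=int)  # (n, 2)

        def _fmt(field):
            try:
                return v.format(field)
            except KeyError:
                return None

        ds = _fmt("DS")
        ad = _fmt("AD")
        dp = _fmt("DP")
        info = v.INFO.get("INFO_SCORE")
        info = float(info) if info is not None else 1.0
        for k, alt in enumerate(alts, start=1):
            miss = (gts < 0).any(axis=1)
            hard = (gts == k).sum(axis=1).astype(np.int8)
            hard[miss] = MISSING
            vid = v.ID if v.ID and len(alts) == 1 else f"{v.ID or v.CHROM + ':' + str(v.POS)}_{alt}"
            dosages = None
            if mode == "dosage":
                if ds is None:
                    raise ValueError(f"{vid}: FORMAT field DS required for dosage mode")
                dosages = ds[:, 0].astype(float) if len(alts) == 1 else np.where(
                    miss, 0, hard
                ).astype(float)
            alt_depths = depths = None
            if mode == "depths":
                if ad is None:
                    raise ValueError(f"{vid}: FORMAT field AD required for depths mode")
                if dp is None:
                    raise ValueError(f"{vid}: FORMAT field DP required for depths mode")
                alt_depths = ad[:, k].astype(int)
                depths = dp.reshape(n, -1)[:, 0].astype(int)
            records.append(
                VariantRecord(
                    variant_id=vid, chrom=str(v.CHROM), pos=int(v.POS),
                    ref=v.REF, alt=alt, genotypes=hard, dosages=dosages,
                    info_score=info, alt_depths=alt_depths, depths=depths,
                )
            )
    return records, samples


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

_SUBJECT_REQUIRED = ["subject_id", "sex", "entry_age", "exit_age", "status"]


def write_subjects(cohort: Cohort, path) -> Path:
    path = Path(path)
    cols = {
        "subject_id": cohort.subject_id,
        "sex": cohort.sex,
        "entry_age": cohort.entry_age,
        "exit_age": cohort.exit_age,
        "status": cohort.status,
    }
    for j in range(cohort.covariates.shape[1]):
        cols[f"pc{j + 1}"] = cohort.covariates[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_subjects(path) -> Cohort:
    """Subject table -> Cohort; validates columns and numeric ages."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _SUBJECT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing required columns: {missing}")
    if df.empty:
        warnings.warn("subject table is empty (header only)")
    for col in ("entry_age", "exit_age"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, counting the header
            raise ValueError(f"non-numeric {col} at line {line}")
        df[col] = vals
    pc_cols = sorted(
        (c for c in df.columns if c.startswith("pc")),
        key=lambda c: int(c[2:]) if c[2:].isdigit() else 0,
    )
    covs = df[pc_cols].to_numpy(float) if pc_cols else np.empty((len(df), 0))
    return Cohort(
        df["subject_id"].to_numpy(), df["entry_age"].to_numpy(float),
        df["exit_age"].to_numpy(float), df["status"].to_numpy(int),
        df["sex"].to_numpy(int), covs,
    )


def write_annotations(annotations: pd.DataFrame, path) -> Path:
    path = Path(path)
    annotations.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "consequence"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"annotation table is missing required columns: {missing}")
    if df.empty:
        warnings.warn("annotation table is empty (header only)")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, kinds: dict, path) -> Path:
    """Phenotype table with ``#kind=`` comment lines declaring column types."""
    path = Path(path)
    header = [f"#kind={name}:{kind}" for name, kind in kinds.items()]
    body = phenotypes.to_csv(sep="\t", index=False, float_format="%.10g")
    path.write_text("\n".join(header) + ("\n" if header else "") + body)
    return path


def read_phenotypes(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    kinds = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#kind="):
                break
            skip += 1
            name, kind = line.strip()[len("#kind="):].split(":")
            kinds[name] = kind
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"subject_id": str})
    if df.empty:
        warnings.warn("phenotype table is empty (header only)")
    return df, kinds


def write_km_curves(curves: dict, path) -> Path:
    rows = []
    for g, c in curves.items():
        for a, s, r, d in zip(c.ages, c.survival, c.at_risk, c.events):
            rows.append((a, s, r, d, g))
    pd.DataFrame(rows, columns=["age", "survival", "at_risk", "events", "group"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.8g"
    )
    return Path(path)


def write_bundle(bundle, out_dir) -> dict:
    """Write a SyntheticDataset to disk; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(
            list(bundle.common_records) + list(bundle.rare_records),
            bundle.cohort.subject_id, out / "genotypes.vcf",
        ),
        "subjects": write_subjects(bundle.cohort, out / "subjects.tsv"),
        "annotations": write_annotations(bundle.annotations, out / "annotations.tsv"),
        "phenotypes": write_phenotypes(
            bundle.phenotypes.drop(columns=["subject_id"]),
            bundle.phenotypes.attrs.get("kinds", {}), out / "phenotypes.tsv",
        ),
        "truth": out / "truth.tsv",
        "carrier_truth": out / "truth_carriers.tsv",
    }
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    bundle.carrier_truth.to_csv(
        paths["carrier_truth"], sep="\t", index=False, float_format="%.10g"
    )
    return {k: Path(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths, stage toggles, thresholds, and the global seed for one run."""

    vcf: str
    subjects: str
    annotations: str | None = None
    phenotypes: str | None = None
    out_dir: str = "survgwas_out"
    run_gwas: bool = True
    run_rare: bool = True
    run_vaf: bool = True
    run_phewas: bool = True
    run_cv: bool = False
    sex_stratified: bool = False
    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULTS))

    def validate(self) -> None:
        for name in ("vcf", "subjects", "annotations", "phenotypes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _child_seed(base: int, stage: str) -> int:
    ss = np.random.SeedSequence([base, abs(hash(stage)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; write outputs, manifest, and run log."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    log: list[str] = [f"seed={config.seed}"]
    results: dict = {}

    cohort = read_subjects(config.subjects)
    log.append(f"subjects: {len(cohort)} read, {cohort.n_events} events")

    fit = fit_cox_null(cohort, include_sex=True)
    resid = martingale_residuals(cohort, fit)
    log.append(f"null Cox: converged={fit.converged} iter={fit.n_iter}")
    results["null_fit"] = fit
    results["residual_sum"] = float(resid.residuals.sum())

    if not config.run_gwas:
        log.append("gwas: stage skipped (toggled off)")
    if not config.run_rare:
        log.append("rare: stage skipped (toggled off)")
    if config.run_gwas:
        recs, _ = read_genotypes(config.vcf, mode="dosage")
        kept, excl = variant_qc.filter_variants_gwas(
            recs,
            min_info=th["qc_min_info"], max_missing=th["qc_max_missing"],
            min_maf=th["qc_min_maf"], min_hwe_p=th["qc_min_hwe_p"],
        )
        log.append(f"gwas qc: {len(recs)} in = {len(kept)} retained + "
                   f"{len(recs) - len(kept)} excluded")
        pd.DataFrame(excl, columns=["variant_id", "rule", "value"]).to_csv(
            out / "gwas_exclusions.tsv", sep="\t", index=False
        )
        if kept:
            dos = np.column_stack([r.dosages for r in kept])
            scan, skips = gwas_scan.scan_cohort(
                cohort, dos, [r.variant_id for r in kept], min_maf=th["qc_min_maf"]
            )
            meta = {r.variant_id: r for r in kept}
            scan.insert(1, "chr", [meta[v].chrom for v in scan["variant_id"]])
            scan.insert(2, "pos", [meta[v].pos for v in scan["variant_id"]])
            scan.insert(3, "effect_allele", [meta[v].alt for v in scan["variant_id"]])
            scan.insert(4, "other_allele", [meta[v].ref for v in scan["variant_id"]])
            scan.to_csv(out / "gwas_summary.tsv", sep="\t", index=False,
                        float_format="%.6g")
            results["gwas"] = scan
            log.append(f"gwas scan: {len(scan)} tested, {len(skips)} skipped, "
                       f"{int((scan['p'] < th['genome_wide_p']).sum())} genome-wide significant")
        if config.sex_stratified and kept:
            strat = gwas_scan.sex_stratified_scan(
                cohort, dos, [r.variant_id for r in kept], min_maf=th["qc_min_maf"]
            )
            for label, frame in strat.items():
                frame.to_csv(out / f"gwas_summary_{label}.tsv", sep="\t",
                             index=False, float_format="%.6g")
            results["gwas_sex_stratified"] = strat

    gene_sets = []
    if config.run_rare and config.annotations:
        annot = read_annotations(config.annotations)
        classes, unknown = rare_variant.classify_variants(annot)
        recs, _ = read_genotypes(config.vcf, mode="hardcall")
        rare = variant_qc.filter_variants_rare(recs, max_maf=th["rare_maf_max"])
        gene_sets, dropped = rare_variant.build_gene_sets(
            rare, classes, min_carriers=th["min_carriers"]
        )
        log.append(f"rare: {len(rare)} rare variants, {len(gene_sets)} gene sets, "
                   f"{len(dropped)} dropped (<{th['min_carriers']} carriers), "
                   f"{len(unknown)} unknown consequences")
        if gene_sets:
            phen = rare_variant.prepare_phenotype(resid, cohort.design(True))
            gene_results = rare_variant.test_gene_sets(gene_sets, phen)
            gene_results["gene_wide_significant"] = (
                np.minimum(gene_results["burden_p"], gene_results["skato_p"])
                < th["gene_wide_p"]
            )
            gene_results.to_csv(out / "gene_results.tsv", sep="\t", index=False,
                                float_format="%.6g")
            results["gene_results"] = gene_results

            screen, leads = rare_variant.per_variant_cox_screen(
                gene_sets, cohort, mac_min=th["mac_min"], alpha=th["alpha"]
            )
            screen.to_csv(out / "variant_screen.tsv", sep="\t", index=False,
                          float_format="%.6g")
            results["variant_screen"], results["lead_variants"] = screen, leads

            for gs in gene_sets:
                if bool(
                    gene_results.loc[
                        (gene_results.gene == gs.gene)
                        & (gene_results.variant_class == gs.variant_class),
                        "gene_wide_significant",
                    ].any()
                ):
                    curves = kaplan_meier(cohort, gs.carrier)
                    write_km_curves(
                        curves, out / f"km_{gs.gene}_{gs.variant_class}.tsv"
                    )
            if config.run_cv:
                cv = rare_variant.five_fold_cv(
                    cohort, gene_sets, seed=_child_seed(config.seed, "cv"),
                    threshold=th["gene_wide_p"], min_carriers=th["min_carriers"],
                )
                cv.to_csv(out / "cv_report.tsv", sep="\t", index=False)
                results["cv"] = cv

    if config.run_vaf and gene_sets:
        rare_ids = sorted({v for gs in gene_sets for v in gs.variant_ids})
        recs, samples = read_genotypes(config.vcf, mode="depths", variant_ids=rare_ids)
        by_id = {r.variant_id: r for r in recs}
        vaf_by_set = {}
        for gs in gene_sets:
            vrecs = [by_id[v] for v in gs.variant_ids if v in by_id]
            vafs, _ = chip_vaf.carrier_vaf(vrecs, subject_ids=samples)
            vaf_by_set[(gs.gene, gs.variant_class)] = vafs
        vaf_table = chip_vaf.summarize_genes(
            vaf_by_set, n_boot=th["vaf_n_boot"], seed=_child_seed(config.seed, "vaf")
        )
        vaf_table.to_csv(out / "vaf_summary.tsv", sep="\t", index=False,
                         float_format="%.6g")
        results["vaf"] = vaf_table
        log.append(f"vaf: {len(vaf_table)} gene/class summaries, "
                   f"{int(vaf_table['left_shifted'].sum())} left-shifted")

    if config.run_phewas and config.phenotypes and gene_sets:
        pheno, kinds = read_phenotypes(config.phenotypes)
        pheno_cols = pheno[[c for c in pheno.columns if c != "subject_id"]]
        gs = gene_sets[0]
        phw, threshold, drop_log = phewas_lite.run_phewas(
            gs.carrier, pheno_cols, kinds, cohort.entry_age, cohort.sex,
            min_cases=th["phewas_min_cases"], alpha=th["alpha"],
        )
        phw["phenome_wide_significant"] = phw["p"] < threshold["raw"]
        phw.to_csv(out / "phewas_results.tsv", sep="\t", index=False,
                   float_format="%.6g")
        results["phewas"], results["phewas_threshold"] = phw, threshold
        log.append(f"phewas ({gs.gene}/{gs.variant_class}): "
                   f"{threshold['n_tested']} tested + {len(drop_log)} dropped "
                   f"= {len(pheno_cols.columns)} in")

    manifest = {
        "seed": config.seed,
        "thresholds": {k: (list(v) if isinstance(v, tuple) else v) for k, v in th.items()},
        "stages": {
            "gwas": config.run_gwas, "rare": config.run_rare,
            "vaf": config.run_vaf, "phewas": config.run_phewas, "cv": config.run_cv,
        },
        "log": log,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log) + "\n")
    results["log"] = log
    results["manifest"] = manifest
    return results
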