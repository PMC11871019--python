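"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a UK-Biobank-like design: subjects enroll at ages
40-69, are followed to an administrative censoring date roughly 13-17 years
later, and about 9% die during follow-up.  Mortality follows a Weibull
baseline hazard on the age timescale shifted proportionally by covariate and
genotype effects, sampled by inverse transform with delayed entry at the
enrollment age.  Rare-gene carriers receive a known log hazard ratio
(recorded as ground truth), and sequencing read counts distinguish germline
carriers (VAF ~ 0.5) from somatic carriers (left-shifted VAF).

Limitations are deliberate: no linkage disequilibrium, no relatedness, no
X-chromosome dosage special-casing, and imputation error is summarized by a
scalar INFO score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .survival_core import Cohort
from .variant_qc import VariantRecord


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GeneSpec:
    """Truth parameters for one simulated rare-variant gene.

    ``carrier_frequency`` is the per-subject probability of carrying exactly
    one qualifying variant in the gene (carriers are heterozygous, matching
    rare-variant reality).  ``somatic_fraction`` of carriers are somatic with
    per-carrier clonal VAF drawn from a Beta centered at ``somatic_vaf_mean``.
    """

    name: str
    n_variants: int = 10
    carrier_frequency: float = 0.005
    log_hazard_ratio: float = 0.0
    variant_class: str = "LoF"  # LoF | AM-missense | REVEL-missense | benign
    somatic_fraction: float = 0.0
    somatic_vaf_mean: float = 0.3

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError(f"gene {self.name}: n_variants must be >= 1")
        if not 0.0 <= self.carrier_frequency < 0.05:
            raise ConfigError(f"gene {self.name}: carrier_frequency must be in [0, 0.05)")
        if not 0.0 <= self.somatic_fraction <= 1.0:
            raise ConfigError(f"gene {self.name}: somatic_fraction must be in [0, 1]")
        if not 0.0 < self.somatic_vaf_mean < 0.5:
            raise ConfigError(f"gene {self.name}: somatic_vaf_mean must be in (0, 0.5)")


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults emulate the cohort the analysis targets: enrollment ages
    40-69, ~13-17 year staggered follow-up, and a 9% death fraction (the
    Weibull scale is calibrated to hit the target on the realized cohort).
    """

    n_subjects: int = 2000
    death_fraction_target: float | None = 0.09
    baseline_hazard_scale: float = 92.0   # Weibull scale, years
    baseline_hazard_shape: float = 8.0    # Weibull shape (adult mortality-like)
    hazard_onset_age: float = 0.0         # zero hazard below this age
    enroll_age_range: tuple = (40.0, 69.0)
    followup_years_range: tuple = (12.8, 16.8)
    censor_age_max: float | None = None   # administrative age cutoff, optional
    n_pcs: int = 10
    sex_log_hr: float = 0.45              # male excess mortality
    pc_log_hr_sd: float = 0.0
    n_common_variants: int = 200
    common_maf_range: tuple = (0.01, 0.5)
    common_effect_sd: float = 0.0
    genes: list = field(default_factory=list)
    missing_rate: float = 0.0
    depth_mean: float = 30.0
    n_binary_phenotypes: int = 12
    n_continuous_phenotypes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if self.death_fraction_target is not None and not (
            0.0 < self.death_fraction_target < 1.0
        ):
            raise ConfigError("death_fraction_target must be in (0, 1)")
        if self.baseline_hazard_scale <= 0 or self.baseline_hazard_shape <= 0:
            raise ConfigError("Weibull scale and shape must be positive")
        lo, hi = self.common_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("common_maf_range must lie within (0, 0.5]")
        if self.enroll_age_range[0] >= self.enroll_age_range[1]:
            raise ConfigError("enroll_age_range must be increasing")
        if self.n_pcs < 0 or self.n_common_variants < 0:
            raise ConfigError("counts must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Covariates and survival
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimulationConfig, seed=None):
    """Sex ~ Bernoulli(0.5) and ``n_pcs`` standard-normal PC stand-ins."""
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_subjects
    sex = rng.integers(0, 2, size=n)
    Z = rng.standard_normal((n, config.n_pcs))
    return Z, sex


def _weibull_cumhaz(t, scale, shape, onset):
    return (np.maximum(np.asarray(t, float) - onset, 0.0) / scale) ** shape


def simulate_survival(
    Z: np.ndarray,
    effects: np.ndarray,
    config: SimulationConfig,
    seed=None,
    sex: np.ndarray | None = None,
) -> Cohort:
    """Draw entry/exit ages and vital status under the proportional-hazards model.

    Death ages are sampled by inverse transform from the Weibull baseline
    conditional on survival to the enrollment age (delayed entry):
    T = t0 + scale * (H0(entry) + E / exp(eta))^(1/shape), E ~ Exp(1).
    Administrative censoring occurs at entry + follow-up (staggered), capped
    by ``censor_age_max`` when set.  When ``death_fraction_target`` is set the
    Weibull scale is recalibrated by root-finding so the expected event
    fraction on the realized cohort equals the target.
    """
    rng = _rng(config.seed if seed is None else seed)
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    effects = np.asarray(effects, float)
    if effects.size != Z.shape[1]:
        raise ConfigError("effects vector not conformable with covariate matrix")
    eta = Z @ effects
    theta = np.exp(eta - eta.mean())  # center so the baseline carries the level

    entry = rng.uniform(*config.enroll_age_range, size=n)
    censor = entry + rng.uniform(*config.followup_years_range, size=n)
    if config.censor_age_max is not None:
        if config.censor_age_max <= config.enroll_age_range[1]:
            raise ConfigError("censor_age_max must exceed the largest enrollment age")
        censor = np.minimum(censor, config.censor_age_max)

    shape, onset = config.baseline_hazard_shape, config.hazard_onset_age
    scale = config.baseline_hazard_scale
    if config.death_fraction_target is not None:
        # Calibrate to the covariate-free design (entries and censor ages
        # only): tying the scale to the realized linear predictors would
        # couple the baseline to the genetic draws and distort downstream
        # effect-recovery inference.  Expected fraction is monotone in
        # s = scale^(-shape).
        ca = np.maximum(censor - onset, 0.0) ** shape
        ea = np.maximum(entry - onset, 0.0) ** shape
        span = ca - ea

        def gap(log_s):
            return np.mean(1.0 - np.exp(-span * np.exp(log_s))) - config.death_fraction_target

        if span.sum() > 0:
            scale = np.exp(-brentq(gap, -60.0, 60.0) / shape)

    H_entry = _weibull_cumhaz(entry, scale, shape, onset)
    target = H_entry + rng.standard_exponential(n) / theta
    death_age = onset + scale * target ** (1.0 / shape)
    status = (death_age <= censor).astype(int)
    exit_age = np.where(status == 1, death_age, censor)

    ids = np.array([f"S{i:06d}" for i in range(n)])
    if sex is None:
        sex = np.zeros(n, dtype=int)
    cohort = Cohort(ids, entry, exit_age, status, sex, Z)
    cohort.hazard_scale = scale  # realized (possibly calibrated) Weibull scale
    return cohort


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_common_genotypes(n: int, m: int, maf_range: tuple, seed=None):
    """Hardy-Weinberg hard calls for m common variants; dosage == hard call.

    Returns (dosage matrix (n, m), records, mafs).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    geno = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    records = [
        VariantRecord(
            variant_id=f"cv{j:05d}",
            chrom="1",
            pos=10_000 + j,
            ref="A",
            alt="G",
            genotypes=geno[:, j],
            dosages=geno[:, j].astype(float),
            info_score=1.0,
        )
        for j in range(m)
    ]
    return geno.astype(float), records, mafs


def simulate_rare_gene(spec: GeneSpec, n: int, seed=None):
    """Rare-variant submatrix for one gene: each carrier holds one het variant.

    Returns (g (n, k) int8, carrier_idx, variant_of_carrier).  Carriers are
    Bernoulli(carrier_frequency) draws; the carried variant is uniform over
    the gene's k variants, so per-variant MAFs stay far below 1%.
    """
    if spec.n_variants < 1:
        raise ConfigError(f"gene {spec.name}: needs at least one variant")
    rng = _rng(seed)
    k = spec.n_variants
    g = np.zeros((n, k), dtype=np.int8)
    carrier_idx = np.flatnonzero(rng.random(n) < spec.carrier_frequency)
    variant_of_carrier = rng.integers(0, k, size=carrier_idx.size)
    g[carrier_idx, variant_of_carrier] = 1
    return g, carrier_idx, variant_of_carrier


def simulate_read_depths(somatic_flags: np.ndarray, spec: GeneSpec, depth_mean: float, seed=None):
    """Per-carrier (alt_reads, depth, clonal_vaf) under the read-count model.

    Depth is Poisson(depth_mean) resampled away from zero.  Germline carriers
    draw alt reads Binomial(depth, 0.5); somatic carriers first draw a
    clonal heterozygous cell-fraction VAF from Beta centered at
    ``somatic_vaf_mean`` (concentration 50), then Binomial(depth, vaf).
    """
    if depth_mean < 10:
        raise ConfigError("depth_mean must be >= 10")
    rng = _rng(seed)
    somatic_flags = np.asarray(somatic_flags, bool)
    nc = somatic_flags.size
    depth = rng.poisson(depth_mean, size=nc)
    while np.any(depth == 0):
        zero = depth == 0
        depth[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
    conc = 50.0
    m = spec.somatic_vaf_mean
    p = np.full(nc, 0.5)
    n_som = int(somatic_flags.sum())
    if n_som:
        p[somatic_flags] = rng.beta(m * conc, (1 - m) * conc, size=n_som)
    alt = rng.binomial(depth, p)
    return alt, depth, p


# ---------------------------------------------------------------------------
# Full dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory bundle: cohort, genotypes, annotations, phenotypes, truth."""

    config: SimulationConfig
    cohort: Cohort
    common_records: list
    common_dosages: np.ndarray
    rare_records: list
    annotations: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    carrier_truth: pd.DataFrame
    scale_used: float


_CLASS_CONSEQUENCE = {
    "LoF": "stop_gained",
    "AM-missense": "missense_variant",
    "REVEL-missense": "missense_variant",
    "benign": "synonymous_variant",
}


def _inject_missing(geno: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate > 0:
        mask = rng.random(geno.shape) < rate
        geno = geno.copy()
        geno[mask] = -1
    return geno


def simulate_bundle(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for one seeded configuration."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]

    Z, sex = simulate_covariates(config, seed=rngs[0])
    n = config.n_subjects

    common_dos, common_records, mafs = simulate_common_genotypes(
        n, config.n_common_variants, config.common_maf_range, seed=rngs[1]
    )
    common_effects = (
        rngs[2].normal(0.0, config.common_effect_sd, size=config.n_common_variants)
        if config.common_effect_sd > 0
        else np.zeros(config.n_common_variants)
    )

    gene_mats, gene_carriers, gene_variant_of = [], [], []
    for spec in config.genes:
        g, cidx, vof = simulate_rare_gene(spec, n, seed=rngs[3])
        gene_mats.append(g)
        gene_carriers.append(cidx)
        gene_variant_of.append(vof)

    pc_effects = (
        rngs[2].normal(0.0, config.pc_log_hr_sd, size=config.n_pcs)
        if config.pc_log_hr_sd > 0
        else np.zeros(config.n_pcs)
    )
    design_cols = [sex.astype(float)[:, None], Z]
    effect_vec = [np.array([config.sex_log_hr]), pc_effects]
    if config.n_common_variants:
        design_cols.append(common_dos)
        effect_vec.append(common_effects)
    for spec, g in zip(config.genes, gene_mats):
        carrier = (g.sum(axis=1) > 0).astype(float)
        design_cols.append(carrier[:, None])
        effect_vec.append(np.array([spec.log_hazard_ratio]))
    full_design = np.column_stack(design_cols)
    full_effects = np.concatenate(effect_vec)

    sim = simulate_survival(full_design, full_effects, config, seed=rngs[4], sex=sex)
    scale_used = getattr(sim, "hazard_scale", config.baseline_hazard_scale)
    # the cohort's analysis covariates are the PC stand-ins only
    cohort = Cohort(sim.subject_id, sim.entry_age, sim.exit_age, sim.status, sex, Z)

    # rare-variant records with read depths
    rare_records, annot_rows, carrier_rows = [], [], []
    pos = 1_000_000
    for spec, g, cidx, vof in zip(config.genes, gene_mats, gene_carriers, gene_variant_of):
        somatic = rngs[5].random(cidx.size) < spec.somatic_fraction
        alt, depth, clonal = simulate_read_depths(
            somatic, spec, config.depth_mean, seed=rngs[5]
        )
        bg_depth = rngs[5].poisson(config.depth_mean, size=n)
        bg_depth[bg_depth == 0] = 1
        for j in range(spec.n_variants):
            vid = f"{spec.name}_v{j:03d}"
            gcol = _inject_missing(g[:, j].copy(), config.missing_rate, rngs[6])
            alt_depths = np.zeros(n, dtype=int)
            depths = bg_depth.copy()
            owners = cidx[vof == j]
            alt_depths[owners] = alt[vof == j]
            depths[owners] = depth[vof == j]
            rare_records.append(
                VariantRecord(
                    variant_id=vid,
                    chrom="2",
                    pos=pos,
                    ref="C",
                    alt="T",
                    genotypes=gcol,
                    dosages=np.clip(g[:, j].astype(float), 0, 2),
                    info_score=1.0,
                    alt_depths=alt_depths,
                    depths=depths,
                )
            )
            pos += 100
            am = rev = np.nan
            if spec.variant_class == "AM-missense":
                am = float(rngs[6].uniform(0.7, 1.0))
                rev = float(rngs[6].uniform(0.0, 0.74))
            elif spec.variant_class == "REVEL-missense":
                am = float(rngs[6].uniform(0.0, 0.69))
                rev = float(rngs[6].uniform(0.75, 1.0))
            elif spec.variant_class == "benign":
                am, rev = float(rngs[6].uniform(0, 0.3)), float(rngs[6].uniform(0, 0.3))
            annot_rows.append(
                {
                    "variant_id": vid,
                    "gene": spec.name,
                    "consequence": _CLASS_CONSEQUENCE[spec.variant_class],
                    "am_score": am,
                    "revel_score": rev,
                }
            )
        for ci, sub in enumerate(cidx):
            carrier_rows.append(
                {
                    "gene": spec.name,
                    "subject_id": cohort.subject_id[sub],
                    "variant_id": f"{spec.name}_v{vof[ci]:03d}",
                    "somatic": int(somatic[ci]),
                    "clonal_vaf": clonal[ci],
                }
            )

    annotations = pd.DataFrame(
        annot_rows, columns=["variant_id", "gene", "consequence", "am_score", "revel_score"]
    )
    carrier_truth = pd.DataFrame(
        carrier_rows, columns=["gene", "subject_id", "variant_id", "somatic", "clonal_vaf"]
    )

    phenotypes = _simulate_phenotypes(config, cohort, rngs[7])

    truth_rows = [
        {
            "kind": "gene",
            "name": spec.name,
            "variant_class": spec.variant_class,
            "true_log_hr": spec.log_hazard_ratio,
            "n_carriers": int(len(cidx)),
        }
        for spec, cidx in zip(config.genes, gene_carriers)
    ] + [
        {
            "kind": "common_variant",
            "name": rec.variant_id,
            "variant_class": "common",
            "true_log_hr": float(common_effects[j]),
            "n_carriers": int((common_dos[:, j] > 0).sum()),
        }
        for j, rec in enumerate(common_records)
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "name", "variant_class", "true_log_hr", "n_carriers"]
    )

    return SyntheticDataset(
        config=config,
        cohort=cohort,
        common_records=common_records,
        common_dosages=common_dos,
        rare_records=rare_records,
        annotations=annotations,
        phenotypes=phenotypes,
        truth=truth,
        carrier_truth=carrier_truth,
        scale_used=scale_used,
    )


def _simulate_phenotypes(config: SimulationConfig, cohort: Cohort, rng) -> pd.DataFrame:
    """Null phenotypes with mild age/sex structure, both binary and continuous."""
    n = len(cohort)
    age_z = (cohort.entry_age - cohort.entry_age.mean()) / max(cohort.entry_age.std(), 1e-9)
    cols = {"subject_id": cohort.subject_id}
    kinds = {}
    for j in range(config.n_binary_phenotypes):
        prev = rng.uniform(0.08, 0.4)
        logit = np.log(prev / (1 - prev)) + 0.2 * age_z + 0.1 * cohort.sex
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        name = f"bin{j:03d}"
        cols[name] = y
        kinds[name] = "binary"
    for j in range(config.n_continuous_phenotypes):
        name = f"cont{j:03d}"
        cols[name] = rng.standard_normal(n) + 0.15 * age_z + 0.1 * cohort.sex
        kinds[name] = "continuous"
    df = pd.DataFrame(cols)
    df.attrs["kinds"] = kinds
    return df


def generate_dataset(config: SimulationConfig, out_dir) -> dict:
    """Write the synthetic bundle to disk (VCF + TSV tables); returns paths."""
    from . import interface

    bundle = simulate_bundle(config)
    return interface.write_bundle(bundle, out_dir)
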