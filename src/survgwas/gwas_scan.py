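"""Common-variant association scan on Martingale residuals.

Each variant's dosage is regressed on the (covariate-adjusted) Martingale
residual phenotype with a per-variant simple linear regression.  The mixed
model used at biobank scale for relatedness control is deliberately replaced
here by a fixed-effect least-squares projection of the residuals on the
covariates: synthetic cohorts are unrelated by construction, and the residual
phenotype itself is what defines the scan.  This is the package's single
largest declared stand-in and is documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival_core import Cohort, MartingaleResidualSet, fit_cox_null, martingale_residuals

SCAN_COLUMNS = ["variant_id", "beta", "se", "p", "maf", "n"]


@dataclass
class EnrichmentResult:
    label: str
    subgroup_carrier_prop: float
    overall_carrier_prop: float
    chi2: float
    p: float
    min_expected: float
    low_expected_warning: bool


def adjust_residuals(residuals, covariates) -> np.ndarray:
    """Least-squares projection residuals of M on [1, covariates].

    The output is orthogonal to the intercept and every covariate column
    (max |dot| < 1e-8 * n).  A rank-deficient design raises with the indices
    of the collinear columns.
    """
    if isinstance(residuals, MartingaleResidualSet):
        residuals = residuals.residuals
    y = np.asarray(residuals, float)
    C = np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != y.size:
        C = C.T
    if C.size:
        C = C[:, C.std(axis=0) > 0]  # constant columns duplicate the intercept
    X = np.column_stack([np.ones(y.size), C]) if C.size else np.ones((y.size, 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by checking incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(j - 1)  # covariate index (intercept is column -1)
            r = rj
        raise ValueError(f"design is rank deficient; collinear covariate columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def association_scan(
    residuals: np.ndarray,
    dosages: np.ndarray,
    variant_ids=None,
    min_maf: float = 0.0,
) -> tuple[pd.DataFrame, list]:
    """Per-variant OLS of residuals on dosage (intercept included).

    Vectorized across variants: beta = Sxy/Sxx, two-sided p from the t
    statistic on n-2 df.  Variants with MAF below ``min_maf`` or zero dosage
    variance are skipped and logged.  Returns (results frame, skip log).
    """
    y = np.asarray(residuals, float)
    X = np.atleast_2d(np.asarray(dosages, float))
    if X.shape[0] != y.size:
        X = X.T
    n, m = X.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]

    yc = y - y.mean()
    xm = X.mean(axis=0)
    af = xm / 2.0
    maf = np.minimum(af, 1.0 - af)
    Sxx = ((X - xm) ** 2).sum(axis=0)
    Sxy = yc @ (X - xm)
    Syy = float(yc @ yc)

    skip_log = []
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Sxy / Sxx
        rss = Syy - beta * Sxy
        s2 = rss / max(n - 2, 1)
        se = np.sqrt(s2 / Sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df=max(n - 2, 1))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    for j in range(m):
        if Sxx[j] <= 0:
            skip_log.append((variant_ids[j], "zero_variance"))
            continue
        if maf[j] < min_maf:
            skip_log.append((variant_ids[j], "maf_below_min"))
            continue
        rows.append((variant_ids[j], beta[j], se[j], p[j], maf[j], n))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS), skip_log


def scan_cohort(
    cohort: Cohort,
    dosages: np.ndarray,
    variant_ids=None,
    min_maf: float = 0.0,
    include_sex: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Null Cox fit -> Martingale residuals -> adjustment -> scan, in one call.

    Residuals are projection-adjusted on the same covariates that entered
    the null model (betas are reported on the adjusted-residual scale).
    """
    fit = fit_cox_null(cohort, include_sex=include_sex)
    resid = martingale_residuals(cohort, fit)
    adj = adjust_residuals(resid, cohort.design(include_sex))
    return association_scan(adj, dosages, variant_ids, min_maf)


def sex_stratified_scan(
    cohort: Cohort,
    dosages: np.ndarray,
    variant_ids=None,
    min_maf: float = 0.0,
) -> dict:
    """Rerun the scan within each sex stratum with sex dropped from the null.

    Sex coding: 0 = female, 1 = male.  A stratum with no subjects or no
    events raises.  Returns {"female": frame, "male": frame}.
    """
    X = np.atleast_2d(np.asarray(dosages, float))
    if X.shape[0] != len(cohort):
        X = X.T
    out = {}
    for label, code in (("female", 0), ("male", 1)):
        mask = cohort.sex == code
        if not mask.any():
            raise ValueError(f"{label} stratum is empty")
        sub = cohort.subset(mask)
        if sub.n_events == 0:
            raise ValueError(f"{label} stratum has zero events")
        ids = variant_ids if variant_ids is not None else None
        out[label], _ = scan_cohort(sub, X[mask], ids, min_maf, include_sex=False)
    return out


def carrier_enrichment(
    carrier_flags: np.ndarray, subgroup_flags: np.ndarray, label: str = ""
) -> EnrichmentResult:
    """Pearson chi-square (1 df) for carrier enrichment within a subgroup.

    Compares carrier frequency inside the subgroup against the remainder of
    the supplied population (2x2 table, no continuity correction).  Expected
    cells below 5 set a warning flag; the result is still returned.
    """
    carrier = np.asarray(carrier_flags, bool)
    sub = np.asarray(subgroup_flags, bool)
    if not sub.any():
        raise ValueError("subgroup is empty")
    table = np.array(
        [
            [(carrier & sub).sum(), (~carrier & sub).sum()],
            [(carrier & ~sub).sum(), (~carrier & ~sub).sum()],
        ],
        dtype=float,
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(
        label=label,
        subgroup_carrier_prop=float(carrier[sub].mean()),
        overall_carrier_prop=float(carrier.mean()),
        chi2=chi2,
        p=max(min(p, 1.0), np.nextafter(0, 1)),
        min_expected=float(expected.min()),
        low_expected_warning=bool(expected.min() < 5),
    )


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Median-based genomic-control inflation factor of a p-value set."""
    chi2 = stats.chi2.isf(np.asarray(pvalues, float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
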