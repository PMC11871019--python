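"""Minimal phenome-wide scan of carrier status.

Each phenotype is regressed on the carrier indicator with age and sex as
covariates: logistic regression for binary traits (effect reported as an
odds ratio), ordinary least squares for continuous traits (effect is the
slope).  Binary phenotypes with fewer than 100 cases, and continuous ones
with fewer than 100 observations, are dropped and logged.  The phenome-wide
threshold is alpha Bonferroni-corrected by the number of phenotypes tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import ALPHA, PHEWAS_MIN_CASES
from .rare_variant import bonferroni_threshold


@dataclass
class PheWASResult:
    phenotype: str
    kind: str
    effect: float      # OR (binary) or slope (continuous)
    p: float
    n: int
    converged: bool


def run_phewas(
    carrier: np.ndarray,
    phenotypes: pd.DataFrame,
    kinds: dict,
    age: np.ndarray | None,
    sex: np.ndarray | None,
    min_cases: int = PHEWAS_MIN_CASES,
    alpha: float = ALPHA,
):
    """Scan every phenotype column against carrier status.

    Age and sex enter as covariates when given (the default analysis); pass
    None for an unadjusted scan.  Returns (results frame, threshold dict,
    filter log).  Non-convergent logistic fits (e.g. separation) are flagged
    in the result rather than dropped.  The log reconciles: tested + dropped
    = input phenotypes.
    """
    carrier = np.asarray(carrier, float)
    covs = [np.asarray(c, float) for c in (age, sex) if c is not None]
    results: list[PheWASResult] = []
    log = []
    for name in phenotypes.columns:
        kind = kinds.get(name)
        if kind not in ("binary", "continuous"):
            log.append((name, "unknown_kind"))
            continue
        y = pd.to_numeric(phenotypes[name], errors="coerce").to_numpy(float)
        obs = ~np.isnan(y)
        n_obs = int(obs.sum())
        if kind == "binary":
            n_cases = int(np.nansum(y))
            if n_cases < min_cases:
                log.append((name, f"fewer_than_{min_cases}_cases"))
                continue
        elif n_obs < min_cases:
            log.append((name, f"fewer_than_{min_cases}_observed"))
            continue
        X = sm.add_constant(
            np.column_stack([carrier[obs]] + [c[obs] for c in covs]),
            has_constant="add",
        )
        yv = y[obs]
        converged = True
        try:
            if kind == "binary":
                with np.errstate(all="ignore"):
                    fit = sm.Logit(yv, X).fit(disp=False, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", True))
                effect = float(np.exp(fit.params[1]))
            else:
                fit = sm.OLS(yv, X).fit()
                effect = float(fit.params[1])
            p = float(fit.pvalues[1])
        except Exception:
            effect, p, converged = np.nan, np.nan, False
        results.append(
            PheWASResult(name, kind, effect, min(max(p, np.nextafter(0, 1)), 1.0)
                         if np.isfinite(p) else np.nan, n_obs, converged)
        )
    if not results:
        raise ValueError("no phenotype survived the case-count filters")
    raw, display = bonferroni_threshold(alpha, len(results))
    frame = pd.DataFrame([r.__dict__ for r in results])
    return frame, {"raw": raw, "display": display, "n_tested": len(results)}, log
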