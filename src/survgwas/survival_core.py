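"""Cox proportional-hazards machinery on the age timescale.

The survival model underlying the whole pipeline is

    H(t | Z) = H0(t) * exp(Z @ beta)

with age as the analysis time, delayed entry (left truncation) at the
enrollment age, and right censoring at the last known age.  Subjects
contribute to a risk set at age t only when entry < t <= exit.  Ties among
event ages are handled with the Breslow approximation, consistently with the
Breslow baseline cumulative hazard used for the Martingale residuals

    M_i = delta_i - [H0(exit_i) - H0(entry_i)] * exp(Z_i @ beta)

which downstream modules use as a quantitative GWAS phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime

import numpy as np
from scipy import stats


class CoxFitError(ValueError):
    """Raised when a Cox model cannot be fitted (no events, rank deficiency...)."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Per-subject survival records on the age timescale.

    Parameters
    ----------
    subject_id : array of str
    entry_age, exit_age : arrays of float, years; exit must exceed entry
    status : array of int, 1 = dead, 0 = alive at exit
    sex : array of int in {0, 1}
    covariates : (n, p) float array; p may be 0
    """

    subject_id: np.ndarray
    entry_age: np.ndarray
    exit_age: np.ndarray
    status: np.ndarray
    sex: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.entry_age = np.asarray(self.entry_age, dtype=float)
        self.exit_age = np.asarray(self.exit_age, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        n = len(self.subject_id)
        if self.covariates.shape[0] != n:
            if self.covariates.size == 0:
                self.covariates = np.empty((n, 0))
            else:
                raise ValueError("covariate rows do not match cohort size")
        if np.any(self.exit_age <= self.entry_age):
            bad = int(np.argmax(self.exit_age <= self.entry_age))
            raise ValueError(
                f"exit_age must exceed entry_age (subject {self.subject_id[bad]!r})"
            )
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if np.isnan(self.covariates).any():
            raise ValueError("missing covariates are not allowed after preprocessing")

    def __len__(self) -> int:
        return len(self.subject_id)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def design(self, include_sex: bool = True) -> np.ndarray:
        """Covariate matrix for the null model, optionally with sex prepended."""
        if include_sex:
            return np.column_stack([self.sex.astype(float), self.covariates])
        return self.covariates

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(
            self.subject_id[mask],
            self.entry_age[mask],
            self.exit_age[mask],
            self.status[mask],
            self.sex[mask],
            self.covariates[mask],
        )


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, curvature, and Breslow baseline."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    baseline_ages: np.ndarray
    baseline_cumhaz: np.ndarray
    n_iter: int
    converged: bool
    include_sex: bool = True

    def cumhaz_at(self, ages: np.ndarray) -> np.ndarray:
        """Step-function evaluation of the baseline cumulative hazard."""
        idx = np.searchsorted(self.baseline_ages, np.asarray(ages, float), side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]


@dataclass
class MartingaleResidualSet:
    residuals: np.ndarray
    fit: CoxFit


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group, with delayed entry."""

    group: object
    ages: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class HazardEstimate:
    hr: float
    log_hr_se: float
    p: float
    n_carriers: int
    carrier_proportion: float
    converged: bool = True
    beta: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# Partial likelihood internals
# ---------------------------------------------------------------------------


def _partial_lik_terms(entry, exit_, status, X, beta, want_hessian=True):
    """Breslow log partial likelihood, score, and information with truncation.

    Risk-set sums use a single signed suffix sum: each subject contributes
    +w at key exit and -w at key entry (w = exp(X beta)), so
    S0(t) = sum over keys >= t of the signed contributions equals the sum of
    w over the risk set {entry < t <= exit}.  Interleaving the signs keeps
    the running sums at the scale of the true risk-set mass, which preserves
    the precision Newton-Raphson needs near the optimum.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    # guard against overflow during step-halving excursions
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)

    event_ages, d_counts = np.unique(exit_[status == 1], return_counts=True)
    d_counts = d_counts.astype(float)

    keys = np.concatenate([exit_, entry])
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    idx = np.searchsorted(sorted_keys, event_ages, side="left")

    def suffix(values):
        v = values[order]
        if v.ndim == 1:
            s = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])
        else:
            s = np.concatenate(
                [np.cumsum(v[::-1], axis=0)[::-1], np.zeros((1,) + v.shape[1:])],
                axis=0,
            )
        return s[idx]

    S0 = suffix(np.concatenate([w, -w]))
    if np.any(S0 <= 0):
        raise CoxFitError("empty risk set at an event age")

    loglik = float(eta[status == 1].sum() - d_counts @ np.log(S0))
    if p == 0:
        return loglik, np.zeros(0), np.zeros((0, 0)), event_ages, d_counts, S0

    wX = w[:, None] * X
    S1 = suffix(np.concatenate([wX, -wX], axis=0))   # (n_event_ages, p)
    Ebar = S1 / S0[:, None]
    score = X[status == 1].sum(axis=0) - d_counts @ Ebar

    info = None
    if want_hessian:
        wXX = wX[:, :, None] * X[:, None, :]          # (n, p, p)
        S2 = suffix(np.concatenate([wXX, -wXX], axis=0))
        V = S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]
        info = np.einsum("d,dij->ij", d_counts, V)
    return loglik, score, info, event_ages, d_counts, S0


def cox_partial_loglik(entry, exit_, status, X, beta) -> float:
    """Breslow log partial likelihood at ``beta`` (delayed-entry risk sets)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(entry):
        X = X.T
    ll, *_ = _partial_lik_terms(
        np.asarray(entry, float),
        np.asarray(exit_, float),
        np.asarray(status, int),
        X,
        np.asarray(beta, float),
        want_hessian=False,
    )
    return ll


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

SCORE_TOL = 1e-8
MAX_ITER = 100


def _fit_cox(entry, exit_, status, X) -> CoxFit:
    n, p = X.shape
    if status.sum() < 1:
        raise CoxFitError("cannot fit a Cox model with zero events")
    if p:
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
            raise CoxFitError("covariate matrix is rank deficient (collinear columns)")

    beta = np.zeros(p)
    loglik, score, info, *_ = _partial_lik_terms(entry, exit_, status, X, beta)
    converged = p == 0
    it = 0
    while not converged and it < MAX_ITER:
        it += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_score, new_info, *_ = _partial_lik_terms(
            entry, exit_, status, X, new_beta
        )
        # accept any step that does not decrease the likelihood beyond the
        # float-noise scale of the log partial likelihood itself
        ll_noise = 1e-11 * (1.0 + abs(loglik))
        halvings = 0
        while new_ll < loglik - ll_noise and halvings < 30:   # step halving
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info, *_ = _partial_lik_terms(
                entry, exit_, status, X, new_beta
            )
            halvings += 1
        step_size = float(np.max(np.abs(new_beta - beta), initial=0.0))
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score), initial=0.0) < SCORE_TOL:
            converged = True
        elif step_size < 1e-12 * (1.0 + float(np.max(np.abs(beta)))):
            break  # numerically stationary but score above tolerance

    cov = np.linalg.pinv(info) if p else np.zeros((0, 0))
    ages, cumhaz = _breslow_from_fit(entry, exit_, status, X, beta)
    return CoxFit(beta, cov, loglik, ages, cumhaz, it, converged)


def _breslow_from_fit(entry, exit_, status, X, beta):
    _, _, _, event_ages, d_counts, S0 = _partial_lik_terms(
        entry, exit_, status, X, beta, want_hessian=False
    )
    return event_ages, np.cumsum(d_counts / S0)


def fit_cox_null(cohort: Cohort, include_sex: bool = True) -> CoxFit:
    """Fit the genotype-free null Cox model on the cohort covariates.

    ``include_sex=False`` drops sex from the design (sex-stratified analyses
    refit the null within each stratum).  Newton-Raphson with step halving;
    convergence requires the score max-norm to fall below 1e-8.  A monotone
    likelihood (e.g. a covariate separating all events) leaves the fit
    flagged ``converged=False`` rather than failing silently.
    """
    X = cohort.design(include_sex)
    fit = _fit_cox(cohort.entry_age, cohort.exit_age, cohort.status, X)
    fit.include_sex = include_sex
    return fit


def breslow_cumhaz(cohort: Cohort, fit: CoxFit, include_sex: bool | None = None):
    """Breslow baseline cumulative hazard H0(t) as a step function.

    H0(t) = sum over event ages t_d <= t of d_d / sum_{at risk} exp(Z beta).
    Returns (event_ages, cumhaz); also refreshes ``fit``'s stored baseline.
    """
    if include_sex is None:
        include_sex = fit.include_sex
    X = cohort.design(include_sex)
    ages, ch = _breslow_from_fit(
        cohort.entry_age, cohort.exit_age, cohort.status, X, fit.beta
    )
    fit.baseline_ages, fit.baseline_cumhaz = ages, ch
    return ages, ch


def martingale_residuals(cohort: Cohort, fit: CoxFit) -> MartingaleResidualSet:
    """Martingale residuals M_i = delta_i - dH0_i * exp(Z_i beta).

    dH0_i is the baseline cumulative hazard accrued over the subject's own
    observation window (entry, exit], so residuals respect delayed entry.
    At the MLE they sum to zero (a property of the Breslow estimator).
    """
    if fit.baseline_ages is None or len(fit.baseline_ages) == 0:
        raise CoxFitError("fit has no baseline cumulative hazard")
    X = cohort.design(fit.include_sex)
    eta = X @ fit.beta if X.shape[1] else np.zeros(len(cohort))
    dH = fit.cumhaz_at(cohort.exit_age) - fit.cumhaz_at(cohort.entry_age)
    resid = cohort.status - dH * np.exp(eta)
    return MartingaleResidualSet(resid, fit)


def kaplan_meier(cohort: Cohort, group_labels: np.ndarray) -> dict:
    """Product-limit survival curves per group, with delayed entry.

    Subjects join a group's risk set at their entry age.  Returns a dict
    mapping group label -> :class:`KMCurve`.
    """
    group_labels = np.asarray(group_labels)
    if len(cohort) == 0 or group_labels.size == 0:
        raise ValueError("cannot build survival curves for an empty group")
    curves = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} has zero subjects")
        entry = cohort.entry_age[mask]
        exit_ = cohort.exit_age[mask]
        status = cohort.status[mask]
        event_ages, d = np.unique(exit_[status == 1], return_counts=True)
        # at risk at t: entry < t <= exit
        se = np.sort(entry)
        sx = np.sort(exit_)
        at_risk = np.searchsorted(se, event_ages, side="left") - np.searchsorted(
            sx, event_ages, side="left"
        )
        surv = np.cumprod(1.0 - d / at_risk)
        curves[g] = KMCurve(g, event_ages, surv, at_risk.astype(int), d.astype(int))
    return curves


def cox_carrier_hr(
    cohort: Cohort,
    carrier_indicator: np.ndarray,
    covariates: np.ndarray | None = None,
) -> HazardEstimate:
    """Hazard ratio for carrier status from a Cox fit with optional covariates.

    The carrier coefficient is the first design column; HR = exp(beta_hat)
    with a Wald two-sided p-value.  Zero carriers is an error; zero carrier
    events yields a flagged, non-converged estimate (monotone likelihood).
    """
    carrier = np.asarray(carrier_indicator, dtype=float)
    n_carriers = int((carrier > 0).sum())
    if n_carriers == 0:
        raise CoxFitError("no carriers: carrier hazard ratio is undefined")
    cols = [carrier]
    if covariates is not None and np.size(covariates):
        cols.append(np.atleast_2d(np.asarray(covariates, float)).reshape(len(cohort), -1))
    X = np.column_stack(cols)
    fit = _fit_cox(cohort.entry_age, cohort.exit_age, cohort.status, X)
    b = float(fit.beta[0])
    se = float(np.sqrt(fit.cov[0, 0]))
    z = b / se if se > 0 else np.inf
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    p = max(p, np.nextafter(0, 1))
    return HazardEstimate(
        hr=float(np.exp(b)),
        log_hr_se=se,
        p=p,
        n_carriers=n_carriers,
        carrier_proportion=n_carriers / len(cohort),
        converged=fit.converged,
        beta=b,
    )


def last_known_age(
    birth_year: int,
    birth_month: int,
    censor_date: datetime.date | tuple,
) -> float:
    """Age in years at the censoring date, at month resolution (months/12)."""
    if isinstance(censor_date, tuple):
        cy, cm = censor_date[0], censor_date[1]
    else:
        cy, cm = censor_date.year, censor_date.month
    if not 1 <= birth_month <= 12:
        raise ValueError("birth_month must be in 1..12")
    months = (cy - birth_year) * 12 + (cm - birth_month)
    if months < 0:
        raise ValueError("birth date is after the censoring date")
    return months / 12.0
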