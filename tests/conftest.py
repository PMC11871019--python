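"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from survgwas import rare_variant as rv
from survgwas import survival_core as sc
from survgwas import synthetic_cohort as syn


def naive_partial_loglik(entry, exit_, status, eta):
    """Brute-force Breslow log partial likelihood, O(n^2), delayed entry.

    Written independently of the package internals: for every event, the
    risk set is scanned subject by subject (entry < t <= exit).
    """
    ll = 0.0
    event_ages = sorted({float(exit_[i]) for i in range(len(eta)) if status[i] == 1})
    for t in event_ages:
        d = 0
        num = 0.0
        denom = 0.0
        for j in range(len(eta)):
            if entry[j] < t <= exit_[j]:
                denom += np.exp(eta[j])
            if status[j] == 1 and exit_[j] == t:
                d += 1
                num += eta[j]
        ll += num - d * np.log(denom)
    return ll


def grid_search_beta(entry, exit_, status, x, lo=-10.0, hi=10.0, step=1e-4):
    """Dense 1-D grid maximization of the explicitly coded partial likelihood.

    For a binary covariate the Breslow partial likelihood is, per event age t
    with d_t events and risk-set carrier/non-carrier counts n1_t/n0_t,
    ll(b) = b * sum(x over events) - sum_t d_t * log(n0_t + n1_t * e^b),
    which is evaluated directly on the dense grid.
    """
    x = np.asarray(x, float)
    assert set(np.unique(x)) <= {0.0, 1.0}, "grid oracle expects a binary covariate"
    grid = np.arange(lo, hi + step / 2, step)
    event_ages = np.unique(np.asarray(exit_)[np.asarray(status) == 1])
    x_event_sum = float(x[np.asarray(status) == 1].sum())
    lls = grid * x_event_sum
    eb = np.exp(grid)
    for t in event_ages:
        at_risk = (np.asarray(entry) < t) & (t <= np.asarray(exit_))
        d = int(np.sum((np.asarray(exit_) == t) & (np.asarray(status) == 1)))
        n1 = float(x[at_risk].sum())
        n0 = float(at_risk.sum() - n1)
        lls = lls - d * np.log(n0 + n1 * eb)
    return float(grid[int(np.argmax(lls))])


def random_small_cohort(rng, n):
    """A tiny cohort with one binary covariate, distinct exit ages, >=1 event."""
    while True:
        entry = np.round(rng.uniform(0, 2, n), 3)
        exit_ = np.round(entry + rng.uniform(0.5, 5, n), 3)
        if len(np.unique(exit_)) < n:
            continue
        status = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)
        # both covariate levels must appear among events and the risk sets
        if status.sum() >= 1 and 0 < x.sum() < n:
            return entry, exit_, status, x


def make_gene_set(gmat, name="g", vclass="LoF"):
    gmat = np.asarray(gmat, dtype=np.int8)
    carrier = rv.collapse_carriers(gmat)
    return rv.GeneVariantSet(
        name,
        vclass,
        [f"{name}_v{j}" for j in range(gmat.shape[1])],
        gmat,
        carrier,
        int(carrier.sum()),
        np.maximum(gmat, 0).sum(axis=0) / (2 * gmat.shape[0]),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """2,000-subject cohort with a ~9% death fraction and no genetic effects."""
    cfg = syn.SimulationConfig(n_subjects=2000, seed=101, n_common_variants=0, n_pcs=4)
    Z, sex = syn.simulate_covariates(cfg, seed=101)
    cohort = syn.simulate_survival(
        np.column_stack([sex.astype(float), Z]),
        np.concatenate([[cfg.sex_log_hr], np.zeros(cfg.n_pcs)]),
        cfg,
        seed=102,
        sex=sex,
    )
    return sc.Cohort(cohort.subject_id, cohort.entry_age, cohort.exit_age,
                     cohort.status, sex, Z)


@pytest.fixture(scope="session")
def null_phenotype(null_cohort):
    fit = sc.fit_cox_null(null_cohort)
    resid = sc.martingale_residuals(null_cohort, fit)
    return rv.prepare_phenotype(resid, null_cohort.design(True))


@pytest.fixture(scope="session")
def demo_bundle():
    """Small synthetic dataset with known gene effects and CHIP structure."""
    cfg = syn.SimulationConfig(
        n_subjects=2000,
        seed=42,
        n_common_variants=60,
        n_pcs=4,
        genes=[
            syn.GeneSpec("GENEA", 12, 0.012, np.log(2.3), "LoF",
                         somatic_fraction=0.8, somatic_vaf_mean=0.33),
            syn.GeneSpec("GENEB", 10, 0.015, np.log(1.5), "AM-missense",
                         somatic_fraction=0.7, somatic_vaf_mean=0.24),
            syn.GeneSpec("GENEC", 8, 0.012, 0.0, "REVEL-missense"),
        ],
    )
    return syn.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def demo_bundle_dir(demo_bundle, tmp_path_factory):
    from survgwas import interface

    out = tmp_path_factory.mktemp("bundle")
    return interface.write_bundle(demo_bundle, out)
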