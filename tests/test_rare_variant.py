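"""Variant classing, carrier collapse, burden/SKAT/SKAT-O, screen, CV."""

import numpy as np
import pandas as pd
import pytest

from survgwas import rare_variant as rv
from survgwas import synthetic_cohort as syn
from survgwas.variant_qc import VariantRecord

from conftest import make_gene_set


def annot(rows):
    return pd.DataFrame(rows, columns=["variant_id", "gene", "consequence",
                                       "am_score", "revel_score"])


class TestClassify:
    def test_lof_terms_and_score_thresholds(self):
        table = annot([
            ("v1", "G", "stop_gained", np.nan, np.nan),
            ("v2", "G", "missense_variant", 0.7, 0.1),
            ("v3", "G", "missense_variant", 0.69, 0.80),
            ("v4", "G", "synonymous_variant", np.nan, np.nan),
        ])
        classes, log = rv.classify_variants(table)
        assert classes.set_index("variant_id").loc["v1", "lof"]
        assert classes.set_index("variant_id").loc["v2", "am"]  # inclusive >= 0.7
        row3 = classes.set_index("variant_id").loc["v3"]
        assert row3["revel"] and not row3["am"] and not row3["lof"]
        assert not log

    def test_unknown_consequence_logged_as_non_lof(self):
        classes, log = rv.classify_variants(
            annot([("v1", "G", "mystery_term", np.nan, np.nan)])
        )
        assert not classes["lof"].any()
        assert log == [("v1", "unknown_consequence", "mystery_term")]

    def test_am_and_revel_not_mutually_exclusive(self):
        classes, _ = rv.classify_variants(
            annot([("v1", "G", "missense_variant", 0.9, 0.9)])
        )
        assert classes.loc[0, "am"] and classes.loc[0, "revel"]


def variant_records(gmat, prefix="g"):
    return [
        VariantRecord(f"{prefix}_v{j}", "1", 100 + j, "A", "T",
                      genotypes=gmat[:, j])
        for j in range(gmat.shape[1])
    ]


class TestBuildGeneSets:
    def test_under_ten_carriers_excluded(self):
        g = np.zeros((100, 2), dtype=np.int8)
        g[:9, 0] = 1
        classes, _ = rv.classify_variants(annot(
            [(f"g_v{j}", "G", "stop_gained", np.nan, np.nan) for j in range(2)]
        ))
        sets, log = rv.build_gene_sets(variant_records(g), classes)
        assert sets == []
        assert log == [("G", "LoF", "fewer_than_min_carriers", 9)]

    def test_collapse_formula(self):
        g = np.array([[0, 0], [1, 0], [0, 2]], dtype=np.int8)
        assert list(rv.collapse_carriers(g)) == [0, 1, 1]

    def test_shuffled_variant_order_gives_identical_set(self):
        rng = np.random.default_rng(0)
        g = (rng.random((200, 4)) < 0.05).astype(np.int8)
        classes, _ = rv.classify_variants(annot(
            [(f"g_v{j}", "G", "stop_gained", np.nan, np.nan) for j in range(4)]
        ))
        recs = variant_records(g)
        s1, _ = rv.build_gene_sets(recs, classes)
        s2, _ = rv.build_gene_sets(recs[::-1], classes.iloc[::-1], )
        assert s1[0].variant_ids == s2[0].variant_ids
        assert np.array_equal(s1[0].genotypes, s2[0].genotypes)

    def test_missing_genotypes_count_as_noncarrier(self):
        g = np.array([[1], [-1], [0]], dtype=np.int8)
        classes, _ = rv.classify_variants(
            annot([("g_v0", "G", "stop_gained", np.nan, np.nan)])
        )
        sets, _ = rv.build_gene_sets(variant_records(g), classes, min_carriers=1)
        assert list(sets[0].carrier) == [1, 0, 0]

    def test_collapse_idempotent(self):
        g = (np.random.default_rng(1).random((300, 3)) < 0.03).astype(np.int8)
        G = rv.collapse_carriers(g)
        assert np.array_equal(rv.collapse_carriers(G[:, None]), G)


@pytest.fixture(scope="module")
def normal_phen():
    return rv.prepare_phenotype(np.random.default_rng(21).standard_normal(2000))


class TestGeneTests:
    def test_k1_burden_skat_skato_coincide(self, normal_phen):
        spec = syn.GeneSpec("g", 1, 0.02)
        g, *_ = syn.simulate_rare_gene(spec, 2000, seed=5)
        gs = make_gene_set(g)
        _, _, pb = rv.burden_test(gs, normal_phen)
        ps = rv.skat_test(gs, normal_phen)
        po, rho = rv.skato_test(gs, normal_phen)
        assert ps == pytest.approx(pb, abs=1e-6)
        assert po == pytest.approx(pb, abs=1e-6)

    def test_constant_carrier_indicator_errors(self, normal_phen):
        gs = make_gene_set(np.ones((2000, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="constant"):
            rv.burden_test(gs, normal_phen)

    def test_all_zero_submatrix_errors(self, normal_phen):
        gs = make_gene_set(np.zeros((2000, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            rv.skat_test(gs, normal_phen)

    def test_burden_p_decreases_with_effect_size(self):
        rng = np.random.default_rng(6)
        spec = syn.GeneSpec("g", 4, 0.02)
        g, *_ = syn.simulate_rare_gene(spec, 2000, seed=7)
        gs = make_gene_set(g)
        noise = rng.standard_normal(2000)
        ps = []
        for eff in (0.0, 0.3, 0.6, 1.0):
            phen = rv.prepare_phenotype(noise + eff * gs.carrier)
            ps.append(rv.burden_test(gs, phen)[2])
        assert ps == sorted(ps, reverse=True)

    def test_opposing_effects_favor_skat_over_burden(self):
        rng = np.random.default_rng(8)
        wins = 0
        for r in range(25):
            spec = syn.GeneSpec(f"g{r}", 6, 0.02)
            g, *_ = syn.simulate_rare_gene(spec, 2000, seed=rng)
            gs = make_gene_set(g)
            eff = np.where(np.arange(6) < 3, 0.9, -0.9)
            y = rng.standard_normal(2000) + np.maximum(g, 0) @ eff
            phen = rv.prepare_phenotype(y)
            if rv.skat_test(gs, phen) < rv.burden_test(gs, phen)[2]:
                wins += 1
        assert wins >= 22

    def test_skato_rho_tracks_effect_structure(self):
        rng = np.random.default_rng(9)
        same, opp = 0, 0
        reps = 30
        for r in range(reps):
            spec = syn.GeneSpec(f"g{r}", 6, 0.03)
            g, *_ = syn.simulate_rare_gene(spec, 1500, seed=rng)
            gs = make_gene_set(g)
            y = rng.standard_normal(1500) + np.maximum(g, 0) @ np.full(6, 0.45)
            _, rho = rv.skato_test(gs, rv.prepare_phenotype(y))
            same += rho >= 0.25   # burden-leaning end
            eff = np.where(np.arange(6) < 3, 0.9, -0.9)
            y = rng.standard_normal(1500) + np.maximum(g, 0) @ eff
            _, rho = rv.skato_test(gs, rv.prepare_phenotype(y))
            opp += rho <= 0.04    # SKAT-leaning end
        assert same >= 0.8 * reps
        assert opp >= 0.8 * reps

    def test_skato_bounded_by_grid_bonferroni(self, normal_phen):
        rng = np.random.default_rng(10)
        for r in range(10):
            spec = syn.GeneSpec(f"g{r}", 5, 0.02)
            g, *_ = syn.simulate_rare_gene(spec, 2000, seed=rng)
            gs = make_gene_set(g)
            po, _ = rv.skato_test(gs, normal_phen)
            grid = rv.SKATO_RHO_GRID
            per_rho_min = min(
                rv.skato_test(gs, normal_phen, rho_grid=[r0])[0] for r0 in grid
            )
            assert po <= per_rho_min * len(grid) + 1e-12

    def test_bad_rho_grid_rejected(self, normal_phen):
        spec = syn.GeneSpec("g", 3, 0.02)
        g, *_ = syn.simulate_rare_gene(spec, 2000, seed=11)
        with pytest.raises(ValueError, match="rho"):
            rv.skato_test(make_gene_set(g), normal_phen, rho_grid=[0.0, 1.5])


class TestQuadform:
    def test_single_eigenvalue_is_chi2_tail(self):
        from scipy.stats import chi2

        assert rv.quadform_pvalue([2.0], 7.0) == pytest.approx(
            chi2.sf(3.5, 1), abs=1e-12
        )

    def test_equal_eigenvalues_reduce_to_chi2(self):
        from scipy.stats import chi2

        assert rv.quadform_pvalue([1.0, 1.0, 1.0], 6.0) == pytest.approx(
            chi2.sf(6.0, 3), abs=1e-10
        )

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(12)
        lam = np.array([2.0, 1.0, 0.5])
        draws = (lam[None, :] * rng.chisquare(1, (1_000_000, 3))).sum(axis=1)
        mc = (draws > 5.0).mean()
        se = np.sqrt(mc * (1 - mc) / 1e6)
        assert abs(rv.quadform_pvalue(lam, 5.0) - mc) < 2 * se

    def test_zero_statistic_is_one(self):
        assert rv.quadform_pvalue([1.0, 0.5], 0.0) == 1.0

    def test_nonpositive_eigenvalues_error(self):
        with pytest.raises(ValueError):
            rv.quadform_pvalue([0.0, -1.0], 1.0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, display",
        [(599, 8.3e-5), (42, 1.1e-3), (1670, 2.9e-5), (1, 0.05)],
    )
    def test_two_digit_truncated_display(self, n, display):
        raw, disp = rv.bonferroni_threshold(0.05, n)
        assert raw == pytest.approx(0.05 / n)
        assert disp == pytest.approx(display, rel=1e-9)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            rv.bonferroni_threshold(0.05, 0)


class TestPerVariantScreen:
    def test_mac_two_skipped(self, null_cohort):
        g = np.zeros((len(null_cohort), 1), dtype=np.int8)
        g[:2, 0] = 1
        frame, _ = rv.per_variant_cox_screen([make_gene_set(g)], null_cohort)
        assert frame.empty

    def test_effect_variant_becomes_lead(self):
        from survgwas import survival_core as sc

        rng = np.random.default_rng(13)
        hits = 0
        reps = 10
        for r in range(reps):
            cfg = syn.SimulationConfig(n_subjects=4000, seed=100 + r,
                                       n_common_variants=0, n_pcs=0)
            g = np.zeros((4000, 3), dtype=np.int8)
            for j in range(3):
                g[rng.choice(4000, 40, replace=False), j] = 1
            eff = np.array([1.5, 0.0, 0.0])  # variant 0 carries the effect
            coh = syn.simulate_survival(np.maximum(g, 0).astype(float), eff,
                                        cfg, seed=rng)
            coh = sc.Cohort(coh.subject_id, coh.entry_age, coh.exit_age,
                            coh.status, np.zeros(4000, int), np.empty((4000, 0)))
            _, leads = rv.per_variant_cox_screen([make_gene_set(g)], coh,
                                                 include_covariates=False)
            hits += leads.variant_id.iloc[0] == "g_v0"
        assert hits >= 0.8 * reps

    def test_null_gene_controls_family_error(self, null_cohort):
        rng = np.random.default_rng(14)
        flagged = 0
        for r in range(20):
            g = np.zeros((len(null_cohort), 4), dtype=np.int8)
            for j in range(4):
                g[rng.choice(len(null_cohort), 25, replace=False), j] = 1
            frame, _ = rv.per_variant_cox_screen([make_gene_set(g)], null_cohort,
                                                 include_covariates=False)
            flagged += int(frame.significant.any())
        assert flagged <= 2


class TestFiveFoldCV:
    def test_same_seed_same_partition_and_report(self, null_cohort, null_phenotype):
        rng = np.random.default_rng(15)
        g = np.zeros((len(null_cohort), 3), dtype=np.int8)
        for j in range(3):
            g[rng.choice(len(null_cohort), 30, replace=False), j] = 1
        sets = [make_gene_set(g)]
        a = rv.five_fold_cv(null_cohort, sets, seed=7)
        b = rv.five_fold_cv(null_cohort, sets, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_gene_never_significant(self, null_cohort):
        rng = np.random.default_rng(16)
        g = np.zeros((len(null_cohort), 3), dtype=np.int8)
        for j in range(3):
            g[rng.choice(len(null_cohort), 30, replace=False), j] = 1
        rep = rv.five_fold_cv(null_cohort, [make_gene_set(g)], seed=8)
        assert rep.significant_folds.iloc[0] == 0
        assert rep.tested_folds.iloc[0] + rep.skipped_folds.iloc[0] == 5

    def test_strong_gene_significant_in_most_folds(self):
        from survgwas import survival_core as sc

        cfg = syn.SimulationConfig(n_subjects=20_000, seed=200,
                                   n_common_variants=0, n_pcs=0,
                                   genes=[syn.GeneSpec("hit", 5, 0.015,
                                                       np.log(2.5), "LoF")])
        g, cidx, _ = syn.simulate_rare_gene(cfg.genes[0], cfg.n_subjects, seed=201)
        carrier = (g.sum(axis=1) > 0).astype(float)
        coh = syn.simulate_survival(carrier[:, None], np.array([np.log(2.5)]),
                                    cfg, seed=202)
        coh = sc.Cohort(coh.subject_id, coh.entry_age, coh.exit_age, coh.status,
                        np.zeros(cfg.n_subjects, int), np.empty((cfg.n_subjects, 0)))
        rep = rv.five_fold_cv(coh, [make_gene_set(g)], seed=9, threshold=1e-4,
                              include_sex=False)
        assert rep.significant_folds.iloc[0] >= 4
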