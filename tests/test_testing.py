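import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from twosplice.mixed_model import FittedGeneModel, fit_gene_model, fixed_effect_names, n_fixed_params
from twosplice.testing import (
    adjust_bh,
    adjust_fwer,
    lrt_screening,
    signed_fold_change,
    simple_isoform_test,
    two_step_decisions,
    two_step_procedure,
    wald_isoform_test,
)
from .conftest import make_gene


def dummy_fit(gene_id="g", form="full", J=2, L=3, loglik=0.0, converged=True, structure="unequal_variance"):
    p = n_fixed_params(form, J, L)
    return FittedGeneModel(
        gene_id=gene_id, form=form, structure=structure, beta=np.zeros(p),
        beta_names=fixed_effect_names(form, J, L), var_params=np.ones(L + 1),
        loglik=loglik, cov_beta=np.eye(p), converged=converged, n_iter=1, J=J, L=L,
        isoform_ids=[f"t{l}" for l in range(L)],
    )


class TestLrtScreening:
    @pytest.mark.parametrize("J", [2, 3])
    @pytest.mark.parametrize("L", range(2, 9))
    def test_degrees_of_freedom(self, J, L):
        full = dummy_fit(form="full", J=J, L=L, loglik=-10.0)
        s1 = lrt_screening(full, dummy_fit(form="null_type1", J=J, L=L, loglik=-12.0))
        s2 = lrt_screening(full, dummy_fit(form="null_type2", J=J, L=L, loglik=-11.0))
        assert s1.df == (J - 1) * L and s1.test_type == "type1"
        assert s2.df == (J - 1) * (L - 1) and s2.test_type == "type2"

    def test_equal_logliks_give_p_one(self):
        s = lrt_screening(dummy_fit(loglik=-5.0), dummy_fit(form="null_type1", loglik=-5.0))
        assert s.statistic == 0.0 and s.pvalue == 1.0

    def test_statistic_clipped_at_zero(self):
        s = lrt_screening(dummy_fit(loglik=-5.0), dummy_fit(form="null_type1", loglik=-4.999))
        assert s.statistic == 0.0

    def test_nonconvergent_fit_gives_missing_p(self):
        s = lrt_screening(dummy_fit(converged=False), dummy_fit(form="null_type1"))
        assert np.isnan(s.pvalue)

    def test_mismatched_structures_rejected(self):
        with pytest.raises(ValueError, match="structure"):
            lrt_screening(dummy_fit(), dummy_fit(form="null_type1", structure="compound_symmetry"))

    def test_mismatched_genes_rejected(self):
        with pytest.raises(ValueError, match="different genes"):
            lrt_screening(dummy_fit(gene_id="a"), dummy_fit(gene_id="b", form="null_type1"))

    def test_null_p_approximately_uniform(self):
        # data simulated with no condition effect: screening p-values ~ U(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        pvals = []
        for i in range(150):
            gene = make_gene(rng, L=3, K=(30, 30), shift=0.0, gene_id=f"g{i}")
            full = fit_gene_model(gene, "full", "unequal_variance")
            null = fit_gene_model(gene, "null_type1", "unequal_variance")
            pvals.append(lrt_screening(full, null).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestWaldIsoformTest:
    @pytest.fixture()
    def fitted(self, rng):
        gene = make_gene(rng, L=3, K=(25, 25), shift=0.8)
        return fit_gene_model(gene, "full", "unequal_variance")

    def test_j2_statistic_is_squared_z_ratio(self, fitted):
        J, L = 2, 3
        for l in range(L):
            res = wald_isoform_test(fitted, l)
            idx = [1] if l == 0 else [1, J + L - 1 + (l - 1)]
            est = fitted.beta[idx].sum()
            se = np.sqrt(np.ones(len(idx)) @ fitted.cov_beta[np.ix_(idx, idx)] @ np.ones(len(idx)))
            assert res.statistic == pytest.approx((est / se) ** 2, rel=1e-10)
            assert res.df == 1

    def test_zero_contrast_gives_p_one(self):
        fit = dummy_fit()
        res = wald_isoform_test(fit, 0)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_fold_change_sign_convention(self):
        assert signed_fold_change(np.log(5.5)) == pytest.approx(5.50)
        assert signed_fold_change(-np.log(14.65)) == pytest.approx(-14.65)
        assert abs(signed_fold_change(0.0)) == 1.0

    def test_requires_full_form(self):
        with pytest.raises(ValueError, match="full"):
            wald_isoform_test(dummy_fit(form="null_type1"), 0)

    def test_detects_constructed_shift(self, rng):
        gene = make_gene(rng, L=3, K=(40, 40), shift=1.5)
        fit = fit_gene_model(gene, "full", "unequal_variance")
        assert all(wald_isoform_test(fit, l).pvalue < 1e-6 for l in range(3))


class TestSimpleIsoformTest:
    def test_equal_groups_give_p_one(self, rng):
        from twosplice.data_io import GeneData

        block = np.tile([1.0, 2.0], (4, 1))
        gene = GeneData("g", ["a", "b"], ["c1", "c2"], [block, block])
        res = simple_isoform_test(gene, 0, "ttest")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_separated_groups(self, rng):
        from twosplice.data_io import GeneData

        y1 = np.zeros((4, 2)) + rng.normal(0, 1e-3, (4, 2))
        y2 = np.ones((4, 2)) + rng.normal(0, 1e-3, (4, 2))
        gene = GeneData("g", ["a", "b"], ["c1", "c2"], [y1, y2])
        assert simple_isoform_test(gene, 0, "ttest").pvalue < 1e-6

    def test_matches_welch_formula_oracle(self, rng):
        from scipy.stats import t as tdist
        from twosplice.data_io import GeneData

        y1 = rng.normal(0.0, 1.0, (7, 2))
        y2 = rng.normal(0.5, 2.0, (11, 2))
        gene = GeneData("g", ["a", "b"], ["c1", "c2"], [y1, y2])
        res = simple_isoform_test(gene, 1, "ttest")
        a, b = y2[:, 1], y1[:, 1]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * tdist.sf(abs(tstat), df)
        assert res.statistic == pytest.approx(tstat, abs=1e-10)
        assert res.pvalue == pytest.approx(p, abs=1e-10)

    def test_anova_matches_ttest_squared_for_two_groups(self, rng):
        gene = make_gene(rng, L=2, K=(6, 6), shift=0.5)
        # pooled-variance F(1, n-2) equals the square of the pooled t; Welch
        # differs, so just check both flag the same strong effect direction
        r1 = simple_isoform_test(gene, 0, "ttest")
        r2 = simple_isoform_test(gene, 0, "anova")
        assert (r1.pvalue < 0.05) == (r2.pvalue < 0.05)

    def test_insufficient_replication(self, rng):
        from twosplice.data_io import GeneData

        gene = GeneData("g", ["a", "b"], ["c1", "c2"], [np.zeros((1, 2)), np.zeros((3, 2))])
        with pytest.raises(ValueError, match=">= 2 samples"):
            simple_isoform_test(gene, 0, "ttest")


class TestAdjustBH:
    def test_step_up_example_all_rejected(self):
        q, reject = adjust_bh([0.01, 0.04, 0.03, 0.05], alpha=0.05)
        assert reject.all()  # p_(4) = 0.05 <= 4*0.05/4

    def test_all_ones(self):
        q, reject = adjust_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_array_equal(q, 1.0)

    def test_missing_values_excluded(self):
        q, reject = adjust_bh([0.001, np.nan, 0.5], alpha=0.05)
        assert np.isnan(q[1]) and not reject[1]
        assert reject[0]
        # M=2, so q for 0.001 is 0.002
        assert q[0] == pytest.approx(0.002)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5], alpha=1.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q, reject = adjust_bh(p, alpha=0.05)
        sm_reject, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, sm_q, atol=1e-12)
        np.testing.assert_array_equal(reject, sm_reject)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestAdjustFwer:
    def test_bonferroni_example(self):
        reject = adjust_fwer([0.01, 0.2], "bonferroni", 0.05)
        np.testing.assert_array_equal(reject, [True, False])

    def test_holm_hochberg_example(self):
        for method in ("holm", "hochberg"):
            reject = adjust_fwer([0.01, 0.04], method, 0.05)
            assert reject.all(), method  # 0.01 <= 0.025 then 0.04 <= 0.05

    @pytest.mark.parametrize("method", ["bonferroni", "holm", "hochberg"])
    def test_single_hypothesis_reduction(self, method):
        assert adjust_fwer([0.04], method, 0.05)[0]
        assert not adjust_fwer([0.06], method, 0.05)[0]

    def test_empty_list(self):
        assert adjust_fwer([], "holm", 0.05).size == 0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_dominance_and_statsmodels_agreement(self, pvals):
        p = np.array(pvals)
        bonf = adjust_fwer(p, "bonferroni", 0.05)
        holm = adjust_fwer(p, "holm", 0.05)
        hoch = adjust_fwer(p, "hochberg", 0.05)
        assert not (bonf & ~holm).any()
        assert not (holm & ~hoch).any()
        np.testing.assert_array_equal(holm, multipletests(p, 0.05, method="holm")[0])
        np.testing.assert_array_equal(hoch, multipletests(p, 0.05, method="simes-hochberg")[0])

    def test_thresholds_recorded(self):
        reject, thr = adjust_fwer([0.01, 0.2, 0.03], "bonferroni", 0.06, return_thresholds=True)
        np.testing.assert_allclose(thr, 0.02)


class TestTwoStepProcedure:
    def _toy(self):
        from twosplice.testing import ConfirmatoryResult, ScreeningResult

        screening = [
            ScreeningResult("g1", "type1", 20.0, 3, 0.001),
            ScreeningResult("g2", "type1", 15.0, 3, 0.004),
            ScreeningResult("g3", "type1", 2.0, 3, 0.40),
            ScreeningResult("g4", "type1", 1.0, 3, 0.90),
        ]
        confirm = {
            g: [ConfirmatoryResult(g, f"t{i}", "wald", 1.0, 1, p) for i, p in enumerate(ps)]
            for g, ps in {
                "g1": [0.001, 0.5, 0.9],
                "g2": [0.011, 0.012, 0.6],
                "g3": [0.001, 0.001, 0.001],
                "g4": [0.9, 0.9, 0.9],
            }.items()
        }
        return screening, confirm

    def test_hand_computed_oracle(self):
        # BH at 0.05 over (0.001, 0.004, 0.40, 0.90): ranked thresholds
        # 0.0125, 0.025, 0.0375, 0.05 -> reject g1, g2 => R=2, M=4,
        # confirmatory family level = 2*0.05/4 = 0.025.
        screening, confirm = self._toy()
        res = two_step_procedure(screening, confirm, alpha=0.05, method="bonferroni")
        assert res.M == 4 and res.R == 2
        assert res.confirm_level == pytest.approx(0.025)
        assert set(res.confirmatory) == {"g1", "g2"}
        # bonferroni per-isoform threshold 0.025/3
        g1 = [r.rejected for r in res.confirmatory["g1"]]
        g2 = [r.rejected for r in res.confirmatory["g2"]]
        assert g1 == [True, False, False]
        assert g2 == [False, False, False]  # both 0.011, 0.012 > 0.025/3
        assert res.confirmatory["g1"][0].threshold == pytest.approx(0.025 / 3)
        # hochberg step-up: rank-2 threshold 0.025/2 = 0.0125 >= 0.012, so
        # both small p-values of g2 are rejected
        screening2, confirm2 = self._toy()
        res2 = two_step_procedure(screening2, confirm2, alpha=0.05, method="hochberg")
        g2h = [r.rejected for r in res2.confirmatory["g2"]]
        assert g2h == [True, True, False]

    def test_family_level_formula(self):
        # M=10, R=2, alpha=0.05 -> level 0.01
        from twosplice.testing import ConfirmatoryResult, ScreeningResult

        screening = [ScreeningResult(f"g{i}", "type1", 1.0, 3, 0.001 if i < 2 else 0.99) for i in range(10)]
        confirm = {f"g{i}": [ConfirmatoryResult(f"g{i}", "t0", "wald", 1.0, 1, 0.5)] for i in range(10)}
        res = two_step_procedure(screening, confirm, alpha=0.05)
        assert res.R == 2 and res.confirm_level == pytest.approx(0.01)

    def test_no_gene_passes(self):
        from twosplice.testing import ScreeningResult

        screening = [ScreeningResult(f"g{i}", "type1", 0.1, 3, 0.8) for i in range(4)]
        res = two_step_procedure(screening, {}, alpha=0.05)
        assert res.R == 0 and res.confirmatory == {}

    def test_hierarchy_and_alpha_monotonicity(self, rng):
        screen_p = rng.uniform(size=40)
        confirm_p = rng.uniform(size=(40, 5))
        prev_pass = None
        prev_rej = None
        for alpha in (0.20, 0.10, 0.05, 0.01):
            _, passed, rejections, R, M, _ = two_step_decisions(screen_p, confirm_p, alpha, "hochberg")
            rej = np.array(rejections)
            # confirmatory rejections only within passing genes
            assert not (rej.any(axis=1) & ~passed).any()
            if prev_pass is not None:
                assert not (passed & ~prev_pass).any()  # smaller alpha never adds genes
                assert not (rej & ~prev_rej).any()
            prev_pass, prev_rej = passed, rej

    def test_missing_screening_p_excluded_from_M(self):
        from twosplice.testing import ConfirmatoryResult, ScreeningResult

        screening = [
            ScreeningResult("g1", "type1", 20.0, 3, 0.001),
            ScreeningResult("g2", "type1", np.nan, 3, np.nan),
        ]
        confirm = {"g1": [ConfirmatoryResult("g1", "t0", "wald", 1.0, 1, 0.001)]}
        res = two_step_procedure(screening, confirm, alpha=0.05)
        assert res.M == 1 and res.R == 1
        assert res.screening[1].passed is False
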