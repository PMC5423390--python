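import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import toy_design
from oracles import bh_step_up, paired_t_closed_form, welch_t_closed_form

from crosslab.datatypes import AnalysisConfig, ExpressionMatrix, Scale
from crosslab.de import bh_fdr, paired_lab_test, per_lab_de, pooled_de


def _paired_frames(diffs, labs=None):
    labs = labs or [f"lab{i}" for i in range(len(diffs))]
    control = pd.DataFrame([[8.0] * len(diffs)], index=["G1"], columns=labs)
    treated = control + np.asarray(diffs)
    return control, treated


class TestPairedLabTest:
    def test_zero_differences(self):
        control, treated = _paired_frames([0.0] * 5)
        res = paired_lab_test(control, treated)
        assert res.loc["G1", "t"] == 0.0
        assert res.loc["G1", "p"] == 1.0

    def test_matches_closed_form(self):
        diffs = [0.5, 1.0, 0.7, 0.9, 0.6]
        control, treated = _paired_frames(diffs)
        res = paired_lab_test(control, treated)
        t_exp, p_exp = paired_t_closed_form(diffs)
        assert res.loc["G1", "t"] == pytest.approx(t_exp, abs=1e-10)
        assert res.loc["G1", "p"] == pytest.approx(p_exp, abs=1e-10)
        assert res.loc["G1", "delta_log2"] == pytest.approx(np.mean(diffs))

    def test_negated_differences_flip_t_keep_p(self):
        diffs = [0.5, 1.0, 0.7, 0.9, 0.6]
        c1, t1 = _paired_frames(diffs)
        c2, t2 = _paired_frames([-d for d in diffs])
        r1 = paired_lab_test(c1, t1)
        r2 = paired_lab_test(c2, t2)
        assert r1.loc["G1", "t"] == pytest.approx(-r2.loc["G1", "t"])
        assert r1.loc["G1", "p"] == pytest.approx(r2.loc["G1", "p"])

    def test_identical_nonzero_differences_degenerate(self):
        control, treated = _paired_frames([0.7] * 5)
        res = paired_lab_test(control, treated)
        assert res.loc["G1", "p"] == 0.0
        assert bool(res.loc["G1", "degenerate"]) is True

    def test_too_few_labs_rejected(self):
        control, treated = _paired_frames([0.5, 0.6])
        with pytest.raises(ValueError, match=">= 3"):
            paired_lab_test(control, treated)

    def test_mismatched_labs_rejected(self):
        control, treated = _paired_frames([0.5, 0.6, 0.7])
        treated.columns = ["labX", "lab1", "lab2"]
        with pytest.raises(ValueError, match="same labs"):
            paired_lab_test(control, treated)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.02, 0.04, 0.045, 0.60])
        sig, q = bh_fdr(p, q=0.05)
        # p_(2) = 0.02 <= 2*0.05/5; p_(3) = 0.04 > 3*0.05/5 = 0.03
        assert sig.tolist() == [True, True, False, False, False]

    def test_all_ones_none_rejected(self):
        sig, _ = bh_fdr(np.ones(10), q=0.05)
        assert not sig.any()

    def test_all_tiny_all_rejected(self):
        sig, _ = bh_fdr(np.full(100, 1e-6), q=0.05)
        assert sig.all()

    def test_empty_input(self):
        sig, q = bh_fdr(np.array([]))
        assert sig.size == 0 and q.size == 0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), m=st.integers(1, 60))
    def test_matches_independent_step_up_and_statsmodels(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.beta(0.5, 3.0, m)
        sig, q_adj = bh_fdr(p, q=0.05)
        assert sig.tolist() == bh_step_up(p.tolist(), 0.05)
        from statsmodels.stats.multitest import multipletests
        sm_sig, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert sig.tolist() == sm_sig.tolist()
        np.testing.assert_allclose(q_adj, sm_q, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rejections_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 40)
        strict, _ = bh_fdr(p, q=0.01)
        loose, _ = bh_fdr(p, q=0.05)
        assert (loose | ~strict).all()  # strict set is a subset


def _two_group_lab(a_vals, b_vals, lab="pilo-1"):
    design = toy_design({(lab, "pilocarpine"): {
        "control": len(b_vals), "t1": len(a_vals)}})
    row = list(b_vals) + list(a_vals)
    samples = list(design.samples(lab=lab, condition="control")) + \
        list(design.samples(lab=lab, condition="t1"))
    df = pd.DataFrame([row], index=["G1"], columns=samples)[design.sample_ids]
    return ExpressionMatrix(df, Scale.LOG2), design


class TestPerLabDe:
    def test_identical_groups_empty_list(self):
        expr, design = _two_group_lab([5, 5, 5, 5], [5, 5, 5, 5])
        _res, gl = per_lab_de(expr, design, "pilo-1")
        assert len(gl) == 0

    def test_welch_matches_closed_form(self):
        a = [6.1, 6.4, 5.9, 6.6, 6.0, 6.2]
        b = [5.0, 5.3, 4.8, 5.1, 5.2, 4.9]
        expr, design = _two_group_lab(a, b)
        res, _ = per_lab_de(expr, design, "pilo-1")
        t_exp, p_exp = welch_t_closed_form(a, b)
        assert res.table.loc["G1", "t"] == pytest.approx(t_exp, abs=1e-10)
        assert res.table.loc["G1", "p"] == pytest.approx(p_exp, abs=1e-10)

    def test_label_swap_symmetry(self):
        a = [6.1, 6.4, 5.9, 6.6]
        b = [5.0, 5.3, 4.8, 5.1]
        expr1, design1 = _two_group_lab(a, b)
        expr2, design2 = _two_group_lab(b, a)
        r1, _ = per_lab_de(expr1, design1, "pilo-1")
        r2, _ = per_lab_de(expr2, design2, "pilo-1")
        assert r1.table.loc["G1", "p"] == pytest.approx(
            r2.table.loc["G1", "p"])

    def test_zero_variance_equal_means_p_one(self):
        expr, design = _two_group_lab([5.0] * 4, [5.0] * 4)
        res, _ = per_lab_de(expr, design, "pilo-1")
        assert res.table.loc["G1", "p"] == 1.0

    def test_small_groups_rejected(self):
        expr, design = _two_group_lab([5.0, 5.1], [5.0, 5.2, 5.3])
        with pytest.raises(ValueError, match="3 animals"):
            per_lab_de(expr, design, "pilo-1")

    def test_student_variant_available(self):
        a = [6.1, 6.4, 5.9, 6.6, 6.0, 6.2]
        b = [5.0, 5.3, 4.8, 5.1, 5.2, 4.9]
        expr, design = _two_group_lab(a, b)
        res_w, _ = per_lab_de(expr, design, "pilo-1", welch=True)
        res_s, _ = per_lab_de(expr, design, "pilo-1", welch=False)
        from scipy import stats
        t_s, p_s = stats.ttest_ind(a, b, equal_var=True)
        assert res_s.table.loc["G1", "t"] == pytest.approx(t_s)
        assert res_s.table.loc["G1", "p"] == pytest.approx(p_s)
        assert res_w.table.loc["G1", "t"] != res_s.table.loc["G1", "t"] or \
            res_w.table.loc["G1", "p"] != res_s.table.loc["G1", "p"]


class TestPooledDe:
    def test_small_effect_significant_but_not_two_fold(self, default_cohort):
        """Effect semantics: genes called significant with |delta| < 1 log2
        stay out of the 2-fold sublist."""
        bundle, truth = default_cohort
        from crosslab.detection import collapse_expression, filter_probes
        from crosslab.datatypes import ProbeAnnotation
        kept = filter_probes(bundle.annotation)
        annot = ProbeAnnotation(
            bundle.annotation.table.loc[kept, ["gene_symbol"]].copy())
        sym = collapse_expression(bundle.expression.subset(features=kept),
                                  annot)
        results, union, two_fold = pooled_de(sym, bundle.design)
        assert two_fold.symbols <= union.symbols
        t1 = results["t1"].table
        for symbol in two_fold.symbols:
            assert any(
                results[tp].table.loc[symbol, "significant"]
                and abs(results[tp].table.loc[symbol, "delta_log2"]) >= 1.0
                for tp in ("t1", "t2", "t3"))

    def test_recovers_planted_core_at_t1(self, default_cohort):
        bundle, truth = default_cohort
        from crosslab.pipeline import run_analysis
        _report, art = run_analysis(bundle)
        t1_sig = set(art["de_results"]["t1"].significant_symbols())
        core = truth.shared_de_core.symbols
        assert len(t1_sig & core) / len(core) >= 0.9
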