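import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_calls, toy_design
from oracles import brute_force_consensus

from crosslab.datatypes import (
    DetectionCallMatrix,
    ProbeAnnotation,
    StudyDesign,
)
from crosslab.detection import (
    SymbolCallMatrix,
    above_background_report,
    collapse_calls,
    condition_above_background,
    filter_probes,
    lab_condition_above_background,
    overall_above_background,
    qc_inclusion_filter,
)


def _annot(mapping):
    return ProbeAnnotation(pd.DataFrame(
        {"gene_symbol": list(mapping.values())},
        index=pd.Index(list(mapping.keys()), name="probe_id")))


class TestFilterProbes:
    def test_only_bare_at_suffix_survives(self):
        annot = _annot({"Abc1_at": "Abc1", "Def2_s_at": "Def2",
                        "Ghi3_x_at": "Ghi3", "AFFX-BioB-5_at": "AFFX-BioB"})
        assert list(filter_probes(annot)) == ["Abc1_at"]

    def test_all_plain_is_identity(self):
        annot = _annot({f"g{i}_at": f"G{i}" for i in range(4)})
        assert list(filter_probes(annot)) == [f"g{i}_at" for i in range(4)]

    def test_empty_result_raises(self):
        annot = _annot({"Jkl4_a_at": "Jkl4"})
        with pytest.raises(ValueError, match="no single-gene"):
            filter_probes(annot)


class TestCollapseCalls:
    @pytest.mark.parametrize("probe_calls, expected", [
        (["P", "P", "A", "A"], "P"),   # exactly 50% qualifies ("at least")
        (["A"], "A"),
        (["P", "A", "A"], "A"),        # 1/3 < 0.5
        (["P"], "P"),
        (["P", "M"], "P"),             # Marginal counts as Absent: 1/2 = 50%
        (["M", "M"], "A"),
    ])
    def test_majority_rule(self, probe_calls, expected):
        probes = [f"p{i}_at" for i in range(len(probe_calls))]
        calls = DetectionCallMatrix(pd.DataFrame(
            {"s1": probe_calls}, index=pd.Index(probes, name="probe_id")))
        annot = _annot({p: "Gene1" for p in probes})
        out = collapse_calls(calls, annot)
        assert out.calls.loc["Gene1", "s1"] == expected

    def test_symbol_without_probes_dropped_with_warning(self):
        calls = DetectionCallMatrix(pd.DataFrame(
            {"s1": ["P"]}, index=pd.Index(["p1_at"], name="probe_id")))
        annot = _annot({"p1_at": "Kept", "p2_at": "Dropped"})
        with pytest.warns(UserWarning, match="no surviving probes"):
            out = collapse_calls(calls, annot)
        assert list(out.symbols) == ["Kept"]


def _one_lab_design(n_animals, lab="pilo-1", model="pilocarpine",
                    condition="t1"):
    return toy_design({(lab, model): {condition: n_animals}})


class TestLabConditionTier:
    @pytest.mark.parametrize("n_present, n_animals, expected", [
        (3, 6, True),    # "at least 3 of the animals"
        (0, 6, False),
        (2, 4, False),   # absolute count, not a fraction
        (3, 3, True),
        (6, 6, True),
    ])
    def test_absolute_count_rule(self, n_present, n_animals, expected):
        design = _one_lab_design(n_animals)
        row = ["P"] * n_present + ["A"] * (n_animals - n_present)
        sym = SymbolCallMatrix(pd.DataFrame(
            [row], index=["G1"], columns=design.sample_ids))
        with pytest.warns(UserWarning):  # other conditions have no samples
            flags = lab_condition_above_background(sym, design)
        assert bool(flags.loc["G1", ("pilo-1", "t1")]) is expected


def _flags_frame(design, true_labs, condition, symbols=("G1",)):
    cols = {}
    for lab in design.labs:
        for cond in ("control", "t1", "t2", "t3"):
            cols[(lab, cond)] = pd.Series(
                [(lab in true_labs and cond == condition)] * len(symbols),
                index=list(symbols))
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["lab", "condition"])
    return out


class TestConditionTier:
    def test_four_of_five_se_labs_passes_t1(self, seven_lab_design):
        flags = _flags_frame(seven_lab_design,
                             ["pilo-1", "pilo-2", "kain-1", "kain-2"], "t1")
        out = condition_above_background(flags, seven_lab_design)
        assert bool(out.loc["G1", "t1"]) is True

    def test_five_of_seven_control_fails(self, seven_lab_design):
        labs = ["pilo-1", "pilo-2", "kain-1", "kain-2", "ssse-1"]
        flags = _flags_frame(seven_lab_design, labs, "control")
        out = condition_above_background(flags, seven_lab_design)
        assert bool(out.loc["G1", "control"]) is False

    def test_all_labs_true_everywhere(self, seven_lab_design):
        cols = {(lab, cond): pd.Series([True], index=["G1"])
                for lab in seven_lab_design.labs
                for cond in ("control", "t1", "t2", "t3")}
        flags = pd.DataFrame(cols)
        flags.columns = pd.MultiIndex.from_tuples(flags.columns,
                                                  names=["lab", "condition"])
        out = condition_above_background(flags, seven_lab_design)
        assert out.loc["G1"].all()


def test_overall_is_or_over_conditions():
    cond = pd.DataFrame({"control": [False, False, True],
                         "t1": [False, False, False],
                         "t2": [False, False, False],
                         "t3": [True, False, False]},
                        index=["only_t3", "never", "control_only"])
    overall = overall_above_background(cond)
    assert bool(overall["only_t3"]) is True
    assert bool(overall["never"]) is False
    assert bool(overall["control_only"]) is True


class TestQcInclusion:
    def _calls(self, design, absent_per_lab):
        cols = {}
        for lab, n_absent in absent_per_lab.items():
            samples = design.samples(lab=lab, condition="control")
            vals = ["A"] * n_absent + ["P"] * (len(samples) - n_absent)
            for s, v in zip(samples, vals):
                cols[s] = v
        return SymbolCallMatrix(pd.DataFrame(cols, index=["G1"]))

    def test_one_bad_lab_tolerated(self, seven_lab_design):
        absent = {lab: 0 for lab in seven_lab_design.labs}
        absent["pilo-1"] = 4
        sym = self._calls(seven_lab_design, absent)
        assert bool(qc_inclusion_filter(sym, seven_lab_design)["G1"]) is True

    def test_two_bad_labs_excluded(self, seven_lab_design):
        absent = {lab: 0 for lab in seven_lab_design.labs}
        absent["pilo-1"] = 4
        absent["kain-2"] = 4
        sym = self._calls(seven_lab_design, absent)
        assert bool(qc_inclusion_filter(sym, seven_lab_design)["G1"]) is False

    def test_all_present_included(self, seven_lab_design):
        absent = {lab: 0 for lab in seven_lab_design.labs}
        sym = self._calls(seven_lab_design, absent)
        assert bool(qc_inclusion_filter(sym, seven_lab_design)["G1"]) is True


def _random_symbol_calls(design, n_symbols, rng):
    codes = rng.choice(["P", "A"], size=(n_symbols, len(design.sample_ids)))
    return SymbolCallMatrix(pd.DataFrame(
        codes, index=[f"G{i}" for i in range(n_symbols)],
        columns=design.sample_ids))


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_flip_absent_to_present_is_monotone(seed):
    """Flipping any single A to P can never lose an above-background flag."""
    from conftest import toy_design
    design = toy_design({
        (lab, model): {c: 4 for c in ("control", "t1", "t2", "t3")}
        for lab, model in [("pilo-1", "pilocarpine"), ("pilo-2", "pilocarpine"),
                           ("kain-1", "kainate"), ("kain-2", "kainate"),
                           ("ssse-1", "SSSE"), ("kind-1", "kindling"),
                           ("kind-2", "kindling")]})
    rng = np.random.default_rng(seed)
    sym = _random_symbol_calls(design, 3, rng)
    before = above_background_report(sym, design)
    absents = np.argwhere((sym.calls == "A").to_numpy())
    if len(absents) == 0:
        return
    i, j = absents[rng.integers(len(absents))]
    flipped = sym.calls.copy()
    flipped.iloc[i, j] = "P"
    after = above_background_report(SymbolCallMatrix(flipped), design)
    assert (after.lab_condition.to_numpy() >= before.lab_condition.to_numpy()).all()
    assert (after.condition.to_numpy() >= before.condition.to_numpy()).all()
    assert (after.overall.to_numpy() >= before.overall.to_numpy()).all()


def test_tier_consistency_on_random_study():
    from conftest import toy_design
    design = toy_design({
        (lab, model): {c: 4 for c in ("control", "t1", "t2", "t3")}
        for lab, model in [("pilo-1", "pilocarpine"), ("pilo-2", "pilocarpine"),
                           ("kain-1", "kainate"), ("kain-2", "kainate"),
                           ("ssse-1", "SSSE"), ("kind-1", "kindling"),
                           ("kind-2", "kindling")]})
    rng = np.random.default_rng(123)
    sym = _random_symbol_calls(design, 40, rng)
    report = above_background_report(sym, design)
    for symbol in report.overall.index:
        if report.overall[symbol]:
            assert report.condition.loc[symbol].any()
        for cond in ("control", "t1", "t2", "t3"):
            if report.condition.loc[symbol, cond]:
                labs = report.labs_per_condition[cond]
                thresh = 6 if cond == "control" else 4
                n = sum(report.lab_condition.loc[symbol, (lab, cond)]
                        for lab in labs)
                assert n >= thresh


def test_consensus_matches_brute_force_recount(tiny_cohort):
    """All three tiers agree exactly with an explicit-loop recount."""
    bundle, _ = tiny_cohort
    from crosslab.detection import collapse_calls, filter_probes
    kept = filter_probes(bundle.annotation)
    annot = ProbeAnnotation(
        bundle.annotation.table.loc[kept, ["gene_symbol"]].copy())
    sym = collapse_calls(
        DetectionCallMatrix(bundle.calls.calls.loc[kept]), annot)
    report = above_background_report(sym, bundle.design)
    lab_bf, cond_bf, overall_bf = brute_force_consensus(sym, bundle.design)
    for symbol in sym.symbols:
        assert overall_bf[symbol] == bool(report.overall[symbol])
        for cond in ("control", "t1", "t2", "t3"):
            assert cond_bf[(symbol, cond)] == bool(
                report.condition.loc[symbol, cond])
            for lab in bundle.design.labs:
                assert lab_bf[(symbol, lab, cond)] == bool(
                    report.lab_condition.loc[symbol, (lab, cond)])
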