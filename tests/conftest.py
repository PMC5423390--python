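import numpy as np
import pandas as pd
import pytest

from crosslab.datatypes import (
    DetectionCallMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    StudyDesign,
)
from crosslab.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort, shared read-only across tests."""
    return generate_cohort(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small cohort (20 symbols) for brute-force oracle comparisons."""
    cfg = GeneratorConfig(n_symbols=20, n_shared_de=1, n_model_private_de=1,
                          n_lab_private_de=1, prop_stable=0.05,
                          prop_variable=0.05, animals_per_group=4)
    return generate_cohort(cfg, seed=7)


def toy_design(labs_conditions):
    """Build a StudyDesign from {(lab, model): {condition: n_animals}}."""
    rows = []
    for (lab, model), conds in labs_conditions.items():
        for cond, n in conds.items():
            for a in range(1, n + 1):
                rows.append({"sample_id": f"{lab}_{cond}_a{a}",
                             "lab_id": lab, "model": model,
                             "condition": cond, "animal_index": a})
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def seven_lab_design():
    """7-lab design (2 pilo, 2 kainate, 1 SSSE, 2 kindling), 6 animals."""
    spec = {}
    for lab, model in [("pilo-1", "pilocarpine"), ("pilo-2", "pilocarpine"),
                       ("kain-1", "kainate"), ("kain-2", "kainate"),
                       ("ssse-1", "SSSE"),
                       ("kind-1", "kindling"), ("kind-2", "kindling")]:
        spec[(lab, model)] = {c: 6 for c in ("control", "t1", "t2", "t3")}
    return toy_design(spec)


def make_calls(symbols, sample_ids, fill="P"):
    return DetectionCallMatrix(pd.DataFrame(
        fill, index=pd.Index(symbols, name="gene_symbol"),
        columns=pd.Index(sample_ids)))
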