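"""Packaged reference lists from the GSE47752 consortium dataset.

Three published summaries of the seven-laboratory dentate granule cell
study ship with the package as small text fixtures:

* ``stable_transcripts`` — 59 control-condition transcripts whose
  cross-laboratory coefficient of variation is below 3%;
* ``variable_transcripts`` — 87 "red-herring" transcripts whose CV
  exceeds the cohort mean by more than 3 standard deviations;
* ``common_de_genes`` — the 73 genes differentially expressed one day
  after status epilepticus in every SE laboratory and model.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import GeneList

__all__ = [
    "stable_transcripts",
    "variable_transcripts",
    "common_de_genes",
    "REPORTED_DE_UNION_SIZE",
    "REPORTED_MEAN_CV_PCT",
]

#: Size of the union of per-lab day-1 DE lists reported for the consortium.
REPORTED_DE_UNION_SIZE = 1638
#: Reported mean cross-laboratory CV of control expression (percent).
REPORTED_MEAN_CV_PCT = 14.0


def _data(name: str):
    return resources.files("crosslab.data").joinpath(name)


def _read_cv_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data(name)) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("gene_symbol")


def stable_transcripts() -> pd.DataFrame:
    """Control-stable transcripts: columns ``group_median`` (linear signal)
    and ``cv_pct``, indexed by gene symbol."""
    return _read_cv_table("stable_transcripts.tsv")


def variable_transcripts() -> pd.DataFrame:
    """Cross-laboratory hyper-variable ("red-herring") transcripts."""
    return _read_cv_table("variable_transcripts.tsv")


def common_de_genes() -> GeneList:
    """Genes differentially expressed in all five SE laboratories at day 1."""
    with resources.as_file(_data("common_de_genes.txt")) as path:
        from .io import read_gene_list
        return read_gene_list(path, name="common_de_genes")
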