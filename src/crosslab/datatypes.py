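"""Core domain types for the multi-laboratory dentate-granule-cell study.

The consortium design these types describe: seven laboratories, four rat
epilepsy models (pilocarpine, kainate, self-sustained status epilepticus,
amygdala kindling), four conditions per model (control plus three
post-insult time points / kindling stages), and four to six animals per
laboratory-condition group.  Expression is probe-level Affymetrix signal
on the linear scale, with MAS5-style Present/Absent/Marginal detection
calls alongside.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Model",
    "Condition",
    "ProbeClass",
    "ExpressionMatrix",
    "DetectionCallMatrix",
    "StudyDesign",
    "ProbeAnnotation",
    "QcTable",
    "GeneList",
    "AnalysisConfig",
    "StudyBundle",
    "SE_MODELS",
    "CONDITIONS",
    "AlignmentError",
]

SE_MODELS = ("pilocarpine", "kainate", "SSSE")
CONDITIONS = ("control", "t1", "t2", "t3")
CALL_CODES = frozenset("PAM")


class AlignmentError(ValueError):
    """Raised when paired study components disagree on their identifiers."""


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class Model(str, enum.Enum):
    PILOCARPINE = "pilocarpine"
    KAINATE = "kainate"
    SSSE = "SSSE"
    KINDLING = "kindling"


class Condition(str, enum.Enum):
    CONTROL = "control"
    T1 = "t1"
    T2 = "t2"
    T3 = "t3"


class ProbeClass(str, enum.Enum):
    PLAIN_AT = "plain_at"
    QUALIFIED_AT = "qualified_at"
    AFFX_CONTROL = "affx_control"


def classify_probe_id(probe_id: str) -> ProbeClass:
    """Classify a probe id by its text alone.

    ``AFFX-`` prefixed ids are hybridisation controls.  A bare ``_at``
    suffix (no ``_s_at`` / ``_x_at`` / ``_a_at`` qualifier) marks a probe
    set specific to a single gene; anything else is a qualified probe set
    that may cross-hybridise and is excluded from single-gene analyses.
    """
    if probe_id.startswith("AFFX-"):
        return ProbeClass.AFFX_CONTROL
    if not probe_id.endswith("_at"):
        return ProbeClass.QUALIFIED_AT
    stem = probe_id[: -len("_at")]
    if stem.endswith(("_s", "_x", "_a", "_f", "_g", "_i", "_b", "_r")):
        return ProbeClass.QUALIFIED_AT
    return ProbeClass.PLAIN_AT


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Features-by-samples signal matrix with a declared scale.

    ``values`` is a pandas DataFrame indexed by feature id (probe set or
    gene symbol) with sample ids as columns.  Linear-scale values must be
    non-negative; the log2 view is ``log2(linear)`` elementwise.
    """

    values: pd.DataFrame
    scale: Scale = Scale.LINEAR

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale is Scale.LINEAR and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale expression values must be >= 0")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale is Scale.LOG2:
            return self
        with np.errstate(divide="ignore"):
            return ExpressionMatrix(np.log2(self.values), Scale.LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale is Scale.LINEAR:
            return self
        return ExpressionMatrix(np.exp2(self.values), Scale.LINEAR)

    def subset(self, features: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        df = self.values
        if features is not None:
            df = df.loc[list(features)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df, self.scale)


@dataclass
class DetectionCallMatrix:
    """Features-by-samples matrix of detection calls ``P``/``A``/``M``."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "feature ids")
        _check_unique(self.calls.columns, "sample ids")
        seen = set(pd.unique(self.calls.to_numpy().ravel()))
        bad = seen - CALL_CODES
        if bad:
            raise ValueError(f"unknown detection call code(s): {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.columns

    def present_mask(self) -> pd.DataFrame:
        """Boolean Present mask; Marginal counts as Absent."""
        return self.calls == "P"


@dataclass
class StudyDesign:
    """Per-sample metadata: laboratory, model, condition, animal index.

    Each laboratory runs exactly one model; in the emulated consortium
    SSSE has a single laboratory and the other models two each.
    """

    table: pd.DataFrame  # columns: lab_id, model, condition, animal_index

    REQUIRED = ("lab_id", "model", "condition", "animal_index")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        _check_unique(self.table.index, "sample ids")
        for m in self.table["model"].unique():
            Model(m)
        for c in self.table["condition"].unique():
            Condition(c)
        if (self.table["animal_index"] <= 0).any():
            raise ValueError("animal_index must be a positive integer")
        per_lab = self.table.groupby("lab_id")["model"].nunique()
        multi = per_lab[per_lab > 1]
        if not multi.empty:
            raise ValueError(
                f"labs mapped to more than one model: {multi.index.tolist()}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def labs(self) -> list[str]:
        return sorted(self.table["lab_id"].unique())

    def model_of_lab(self, lab: str) -> str:
        models = self.table.loc[self.table["lab_id"] == lab, "model"].unique()
        if len(models) != 1:
            raise ValueError(f"unknown or ambiguous lab {lab!r}")
        return models[0]

    def se_labs(self) -> list[str]:
        """Laboratories running a status-epilepticus model (not kindling)."""
        mask = self.table["model"].isin(SE_MODELS)
        return sorted(self.table.loc[mask, "lab_id"].unique())

    def samples(self, lab: str | None = None, condition: str | None = None,
                model: str | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.table.index)
        if lab is not None:
            mask &= self.table["lab_id"] == lab
        if condition is not None:
            mask &= self.table["condition"] == condition
        if model is not None:
            mask &= self.table["model"] == model
        return self.table.index[mask]

    def group_sizes(self) -> pd.Series:
        return self.table.groupby(["lab_id", "condition"]).size()


@dataclass
class ProbeAnnotation:
    """Probe id to gene symbol mapping with derived probe class.

    Composite symbols (``Hba1///Hba2``) are opaque single tokens.
    """

    table: pd.DataFrame  # index: probe_id; columns: gene_symbol [, probe_class]

    def __post_init__(self) -> None:
        if "gene_symbol" not in self.table.columns:
            raise ValueError("annotation requires a gene_symbol column")
        _check_unique(self.table.index, "probe ids")
        derived = pd.Series(
            [classify_probe_id(p).value for p in self.table.index],
            index=self.table.index, name="probe_class")
        if "probe_class" in self.table.columns:
            clash = self.table["probe_class"] != derived
            if clash.any():
                raise ValueError(
                    "probe_class column disagrees with the class derived from "
                    f"probe id text for: {self.table.index[clash][:5].tolist()}")
        else:
            self.table = self.table.assign(probe_class=derived)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def symbol_of(self) -> pd.Series:
        return self.table["gene_symbol"]

    def probes_of_class(self, cls: ProbeClass) -> pd.Index:
        return self.table.index[self.table["probe_class"] == cls.value]


@dataclass
class QcTable:
    """Per-sample QC channel: four spike-in signals, 3'/5' ratio, spike-1 call.

    Spike slots are ordered by nominal spike concentration, lowest first.
    """

    table: pd.DataFrame  # index: sample_id; columns spike1..4, ratio_3p_5p, spike1_call

    SPIKES = ("spike1", "spike2", "spike3", "spike4")

    def __post_init__(self) -> None:
        need = list(self.SPIKES) + ["ratio_3p_5p", "spike1_call"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"QC table missing columns: {missing}")
        _check_unique(self.table.index, "sample ids")
        if (self.table["ratio_3p_5p"] <= 0).any():
            raise ValueError("3'/5' ratios must be positive")
        bad = set(self.table["spike1_call"].unique()) - {"P", "A"}
        if bad:
            raise ValueError(f"spike1_call must be P or A, got {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def spike_signals(self) -> pd.DataFrame:
        return self.table[list(self.SPIKES)]


@dataclass
class GeneList:
    """A named set of gene symbols with a free-text provenance record."""

    name: str
    symbols: frozenset[str]
    provenance: str = ""

    def __init__(self, name: str, symbols: Iterable[str], provenance: str = ""):
        self.name = name
        self.symbols = frozenset(symbols)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))


@dataclass
class AnalysisConfig:
    """Every numeric rule of the harmonisation analysis, with study defaults.

    Defaults reproduce the consortium's published procedure: a symbol keeps a
    probe-level Present call if >=50% of its probes are Present; it is above
    background in a lab-condition group with >=3 Present animals, per SE time
    point with >=4 of the 5 SE labs, and for controls with >=6 of the 7 labs.
    The variability screen calls CV < 3% stable and CV > mean + 3 SD variable;
    differential expression uses Benjamini-Hochberg FDR 0.05 and a 2-fold
    (1 log2 unit) change filter.  QC requires strictly increasing spike-in
    signals and 3'/5' ratios below 3.
    """

    min_probe_present_fraction: float = 0.5
    min_animals_present: int = 3
    min_se_labs: int = 4
    min_control_labs: int = 6
    cv_stable_threshold_pct: float = 3.0
    cv_outlier_sd_multiplier: float = 3.0
    fdr_q: float = 0.05
    fold_change_log2: float = 1.0
    qc_max_absent_calls_per_lab: int = 3
    qc_min_labs: int = 6
    degradation_ratio_max: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_probe_present_fraction <= 1.0):
            raise ValueError("min_probe_present_fraction must be in (0, 1]")
        positive = ("min_animals_present", "min_se_labs", "min_control_labs",
                    "cv_stable_threshold_pct", "cv_outlier_sd_multiplier",
                    "fdr_q", "fold_change_log2", "qc_min_labs",
                    "degradation_ratio_max")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.qc_max_absent_calls_per_lab < 0:
            raise ValueError("qc_max_absent_calls_per_lab must be >= 0")
        if not (0.0 < self.fdr_q <= 1.0):
            raise ValueError("fdr_q must be in (0, 1]")


@dataclass
class StudyBundle:
    """A cross-validated study: expression + calls + design + annotation (+ QC)."""

    expression: ExpressionMatrix
    calls: DetectionCallMatrix
    design: StudyDesign
    annotation: ProbeAnnotation
    qc: QcTable | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        expr_samples = list(self.expression.sample_ids)
        for name, ids in (
            ("detection calls", self.calls.sample_ids),
            ("design", self.design.sample_ids),
        ):
            _require_same_ids(expr_samples, ids, f"sample ids ({name})")
        if self.qc is not None:
            _require_same_ids(expr_samples, self.qc.sample_ids, "sample ids (QC)")
        _require_same_ids(self.expression.feature_ids, self.calls.feature_ids,
                          "feature ids (expression vs calls)")
        unannotated = self.expression.feature_ids.difference(
            self.annotation.probe_ids)
        if len(unannotated):
            raise AlignmentError(
                f"features missing from annotation: {unannotated[:5].tolist()}")


def _require_same_ids(ref, other, what: str) -> None:
    ref_set, other_set = set(ref), set(other)
    if ref_set != other_set:
        missing = sorted(ref_set - other_set)
        extra = sorted(other_set - ref_set)
        raise AlignmentError(
            f"{what} mismatch: missing={missing[:5]} extra={extra[:5]}")
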