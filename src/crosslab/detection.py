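"""Detection-call consensus filtering.

Implements the consortium's tiered "above background" designation:
probe-level calls are restricted to single-gene ``_at`` probe sets,
collapsed to gene symbols by a >=50%-Present rule, and then promoted
through three tiers — a symbol is Present in a laboratory-condition
group with at least 3 Present animals; Present for an SE time point
when at least 4 of the 5 SE laboratories agree (controls: 6 of 7, all
laboratories); and above background overall when Present in any
condition.  Marginal calls count as Absent throughout.  Expression
values of surviving symbols are never masked by individual Absent
calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    AnalysisConfig,
    DetectionCallMatrix,
    GeneList,
    ProbeAnnotation,
    ProbeClass,
    StudyDesign,
)

__all__ = [
    "SymbolCallMatrix",
    "AboveBackgroundReport",
    "filter_probes",
    "collapse_calls",
    "collapse_expression",
    "lab_condition_above_background",
    "condition_above_background",
    "overall_above_background",
    "qc_inclusion_filter",
    "above_background_report",
]


@dataclass
class SymbolCallMatrix:
    """Symbol-level Present/Absent calls derived from probe-level calls."""

    calls: pd.DataFrame  # symbols x samples, values in {"P", "A"}

    @property
    def symbols(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.columns

    def present_mask(self) -> pd.DataFrame:
        return self.calls == "P"


@dataclass
class AboveBackgroundReport:
    """Tiered consensus flags, one row per symbol at each tier."""

    lab_condition: pd.DataFrame   # index symbol, columns (lab, condition) -> bool
    condition: pd.DataFrame       # index symbol, columns condition -> bool
    overall: pd.Series            # index symbol -> bool
    labs_per_condition: dict[str, list[str]]  # denominator labs per condition

    def surviving_symbols(self, name: str = "above_background",
                          provenance: str = "") -> GeneList:
        return GeneList(name, self.overall.index[self.overall], provenance)


def filter_probes(annotation: ProbeAnnotation) -> pd.Index:
    """Retain only single-gene probe sets (bare ``_at`` suffix).

    AFFX hybridisation controls and qualifier-suffixed probe sets
    (``_s_at``, ``_x_at``, ``_a_at``, ...) are dropped.  Raises if no
    probe survives — nothing would be analysable.
    """
    kept = annotation.probes_of_class(ProbeClass.PLAIN_AT)
    if len(kept) == 0:
        raise ValueError("no single-gene '_at' probes remain after filtering")
    return kept


def collapse_calls(calls: DetectionCallMatrix, annotation: ProbeAnnotation,
                   min_fraction: float = 0.5) -> SymbolCallMatrix:
    """Collapse probe-level calls to symbol level.

    A symbol is Present in a sample when at least ``min_fraction`` of its
    probes are Present there ("at least" — a half/half split qualifies at
    the default 0.5).  Marginal counts as Absent.  Probes must already be
    filtered to the single-gene class; symbols left with no probes are
    dropped with a warning.
    """
    probe_ids = calls.feature_ids.intersection(annotation.probe_ids)
    symbols = annotation.symbol_of().loc[probe_ids]
    dropped = set(annotation.symbol_of().unique()) - set(symbols.unique())
    if dropped:
        warnings.warn(f"{len(dropped)} symbol(s) had no surviving probes "
                      "and were dropped")
    present = calls.present_mask().loc[probe_ids]
    frac = present.groupby(symbols).mean()
    out = pd.DataFrame(np.where(frac >= min_fraction, "P", "A"),
                       index=frac.index, columns=frac.columns)
    out.index.name = "gene_symbol"
    return SymbolCallMatrix(out.sort_index())


def collapse_expression(expression, annotation: ProbeAnnotation
                        ) -> "ExpressionMatrix":
    """Collapse probe-level expression to symbol level.

    Takes the median over a symbol's probes on the log2 scale (the scale
    of all downstream analysis) and returns a log2-scale matrix.  Probes
    should already be restricted to the single-gene class.
    """
    from .datatypes import ExpressionMatrix, Scale
    log2 = expression.to_log2().values
    probe_ids = log2.index.intersection(annotation.probe_ids)
    symbols = annotation.symbol_of().loc[probe_ids]
    collapsed = log2.loc[probe_ids].groupby(symbols).median()
    collapsed.index.name = "gene_symbol"
    return ExpressionMatrix(collapsed.sort_index(), Scale.LOG2)


def lab_condition_above_background(symbol_calls: SymbolCallMatrix,
                                   design: StudyDesign,
                                   min_animals: int = 3) -> pd.DataFrame:
    """Per (symbol, lab, condition) flag: >= ``min_animals`` Present animals.

    The threshold is an absolute animal count, not a fraction, so groups
    of 4-5 animals face the same bar as groups of 6.
    """
    present = symbol_calls.present_mask()
    cols: dict[tuple[str, str], pd.Series] = {}
    for lab in design.labs:
        for condition in CONDITIONS:
            samples = design.samples(lab=lab, condition=condition)
            if len(samples) == 0:
                warnings.warn(f"no samples for lab {lab!r} in {condition!r}; "
                              "flag set to False")
                cols[(lab, condition)] = pd.Series(False, index=present.index)
            else:
                cols[(lab, condition)] = present[samples].sum(axis=1) >= min_animals
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["lab", "condition"])
    return out


def condition_above_background(lab_flags: pd.DataFrame, design: StudyDesign,
                               min_se_labs: int = 4,
                               min_control_labs: int = 6) -> pd.DataFrame:
    """Per (symbol, condition) flag from the lab-level flags.

    SE time points (t1-t3) are judged over the laboratories running SE
    models against ``min_se_labs``; the control condition over all
    laboratories (kindling included) against ``min_control_labs``.
    """
    se_labs = design.se_labs()
    all_labs = design.labs
    out = {}
    for condition in CONDITIONS:
        if condition == "control":
            labs, threshold = all_labs, min_control_labs
        else:
            labs, threshold = se_labs, min_se_labs
        if len(labs) < threshold:
            warnings.warn(
                f"only {len(labs)} lab(s) available for {condition!r} "
                f"(threshold {threshold}); flags forced False. labs={labs}")
            out[condition] = pd.Series(False, index=lab_flags.index)
            continue
        sub = lab_flags.loc[:, [(lab, condition) for lab in labs]]
        out[condition] = sub.sum(axis=1) >= threshold
    return pd.DataFrame(out)


def overall_above_background(condition_flags: pd.DataFrame) -> pd.Series:
    """A symbol is above background overall if Present in any condition."""
    return condition_flags.any(axis=1)


def qc_inclusion_filter(symbol_calls: SymbolCallMatrix, design: StudyDesign,
                        max_absent: int = 3, min_labs: int = 6) -> pd.Series:
    """Inclusion filter for the control-condition QC analyses.

    A symbol is included when at least ``min_labs`` laboratories have no
    more than ``max_absent`` Absent calls among their control animals.
    """
    absent = ~symbol_calls.present_mask()
    compliant = []
    for lab in design.labs:
        samples = design.samples(lab=lab, condition="control")
        compliant.append(absent[samples].sum(axis=1) <= max_absent)
    n_compliant = pd.concat(compliant, axis=1).sum(axis=1)
    return n_compliant >= min_labs


def above_background_report(symbol_calls: SymbolCallMatrix, design: StudyDesign,
                            config: AnalysisConfig | None = None
                            ) -> AboveBackgroundReport:
    """Run all three consensus tiers and bundle the flags."""
    config = config or AnalysisConfig()
    lab_flags = lab_condition_above_background(
        symbol_calls, design, config.min_animals_present)
    cond_flags = condition_above_background(
        lab_flags, design, config.min_se_labs, config.min_control_labs)
    overall = overall_above_background(cond_flags)
    labs_per_condition = {
        c: (design.labs if c == "control" else design.se_labs())
        for c in CONDITIONS
    }
    return AboveBackgroundReport(lab_flags, cond_flags, overall,
                                 labs_per_condition)
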