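"""Cross-laboratory variability screen.

For each symbol, the expression level in a laboratory is collapsed to
the median over that laboratory's animals; the coefficient of variation
of these per-lab medians (computed on the LINEAR signal scale, where the
published group medians live) measures between-laboratory
reproducibility.  Symbols with CV below an absolute threshold (default
3%) are "stable"; symbols whose CV exceeds the cohort mean by more than
3 standard deviations are "variable" — red-herring transcripts that
low-powered single-lab studies can mistake for treatment effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, ExpressionMatrix, Scale, StudyDesign

__all__ = [
    "CrossLabSummary",
    "lab_median_profiles",
    "cross_lab_cv",
    "classify_variability",
    "cross_lab_summary",
]


@dataclass
class CrossLabSummary:
    """Per-symbol cross-laboratory summary.

    ``table`` columns: one linear-scale lab-median column per laboratory,
    ``group_median`` (median of lab medians, linear), ``cv_pct`` and
    ``variability_class`` in {stable, typical, variable}.
    """

    table: pd.DataFrame
    mean_cv_pct: float
    sd_cv_pct: float
    stable_cutoff_pct: float
    variable_cutoff_pct: float

    def symbols_in_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["variability_class"] == cls]


def lab_median_profiles(expression: ExpressionMatrix, design: StudyDesign,
                        condition: str = "control",
                        labs: list[str] | None = None) -> pd.DataFrame:
    """Symbols x labs matrix of per-laboratory median log2 expression.

    The median is taken across that laboratory's animals in *condition*
    (even counts use the midpoint convention).  Laboratories without
    samples in the condition are excluded with a warning.
    """
    log2 = expression.to_log2().values
    labs = labs if labs is not None else design.labs
    cols = {}
    for lab in labs:
        samples = design.samples(lab=lab, condition=condition)
        if len(samples) == 0:
            warnings.warn(f"lab {lab!r} has no samples in {condition!r}; "
                          "excluded from median profiles")
            continue
        cols[lab] = log2[samples].median(axis=1)
    return pd.DataFrame(cols)


def cross_lab_cv(lab_medians_linear: pd.DataFrame) -> pd.Series:
    """Percent CV (100 * sample sd / mean) of linear-scale lab medians.

    Labs are treated as sampled units, so the n-1 standard deviation is
    used.  Linear signals are positive; a non-positive mean indicates a
    scale mix-up and raises.
    """
    if lab_medians_linear.shape[1] < 2:
        raise ValueError("need at least 2 laboratories for a CV")
    mean = lab_medians_linear.mean(axis=1)
    if (mean <= 0).any():
        bad = mean.index[mean <= 0][:5].tolist()
        raise ValueError(f"non-positive mean linear signal for {bad}; "
                         "CV requires linear-scale input")
    sd = lab_medians_linear.std(axis=1, ddof=1)
    return 100.0 * sd / mean


def classify_variability(cv_pct: pd.Series, stable_thresh: float = 3.0,
                         sd_mult: float = 3.0,
                         cohort_mean: float | None = None,
                         cohort_sd: float | None = None
                         ) -> tuple[pd.Series, float, float, float]:
    """Classify each symbol as stable / typical / variable.

    stable: cv < ``stable_thresh`` (absolute percent);
    variable: cv > mean(cv) + ``sd_mult`` * sd(cv) (cohort-relative);
    typical otherwise.  Cohort mean/sd are estimated from ``cv_pct``
    unless supplied (e.g. when classifying a subset against statistics
    from a larger screen).  Returns ``(classes, mean, sd, cutoff)``.
    If the cohort cutoff ever drops below the stable threshold,
    stability takes precedence and a warning is issued.
    """
    if not np.isfinite(cv_pct).all():
        raise ValueError("all CVs must be finite")
    mean_cv = float(cv_pct.mean()) if cohort_mean is None else float(cohort_mean)
    sd_cv = float(cv_pct.std(ddof=1)) if cohort_sd is None else float(cohort_sd)
    cutoff = mean_cv + sd_mult * sd_cv
    if cutoff <= stable_thresh:
        warnings.warn("variable cutoff fell below the stable threshold; "
                      "stable classification takes precedence")
    cls = pd.Series("typical", index=cv_pct.index, name="variability_class")
    cls[cv_pct > cutoff] = "variable"
    cls[cv_pct < stable_thresh] = "stable"
    return cls, mean_cv, sd_cv, cutoff


def cross_lab_summary(expression: ExpressionMatrix, design: StudyDesign,
                      config: AnalysisConfig | None = None,
                      symbols: pd.Index | None = None,
                      condition: str = "control") -> CrossLabSummary:
    """Full screen: lab medians -> linear CV -> variability classes."""
    config = config or AnalysisConfig()
    if symbols is not None:
        expression = expression.subset(features=symbols)
    log2_medians = lab_median_profiles(expression, design, condition)
    linear_medians = np.exp2(log2_medians)
    cv = cross_lab_cv(linear_medians)
    cls, mean_cv, sd_cv, cutoff = classify_variability(
        cv, config.cv_stable_threshold_pct, config.cv_outlier_sd_multiplier)
    table = linear_medians.copy()
    table["group_median"] = linear_medians.median(axis=1)
    table["cv_pct"] = cv
    table["variability_class"] = cls
    return CrossLabSummary(
        table=table,
        mean_cv_pct=mean_cv,
        sd_cv_pct=sd_cv,
        stable_cutoff_pct=config.cv_stable_threshold_pct,
        variable_cutoff_pct=cutoff,
    )
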