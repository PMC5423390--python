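"""Technical-validation diagnostics.

Four checks mirror the consortium's quality audit: the four bacterial /
phage spike-in RNAs (bioB, bioC, bioD, cre) must show strictly
increasing signal within every sample; the median 3'/5' probe-intensity
ratio must stay below 3 (3'-biased arrays degrade from the 5' end);
control lab-median profiles must correlate highly across laboratories;
and the distribution of cross-laboratory median log2 expression should
be approximately normal, with no excess of low-expression noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import QcTable

__all__ = [
    "QcReport",
    "spike_monotonicity",
    "degradation_check",
    "cross_lab_correlations",
    "normality_check",
]


@dataclass
class QcReport:
    spike_monotonic: pd.Series            # per sample
    spike_pass_count: int
    degradation_pass: pd.Series           # per sample
    degradation_pass_count: int
    lowest_spike_present_fraction: float
    lab_correlations: pd.DataFrame | None = None
    min_off_diagonal_r: float | None = None
    max_off_diagonal_r: float | None = None
    ks_statistic: float | None = None
    ks_pvalue: float | None = None

    def to_dict(self) -> dict:
        out = {
            "spike_pass_count": int(self.spike_pass_count),
            "spike_total": int(len(self.spike_monotonic)),
            "degradation_pass_count": int(self.degradation_pass_count),
            "lowest_spike_present_fraction": float(
                self.lowest_spike_present_fraction),
        }
        if self.lab_correlations is not None:
            out["lab_correlations"] = {
                lab: self.lab_correlations[lab].round(6).to_dict()
                for lab in self.lab_correlations.columns}
            out["min_off_diagonal_r"] = float(self.min_off_diagonal_r)
            out["max_off_diagonal_r"] = float(self.max_off_diagonal_r)
        if self.ks_statistic is not None:
            out["ks_statistic"] = float(self.ks_statistic)
            out["ks_pvalue"] = float(self.ks_pvalue)
        return out


def spike_monotonicity(qc: QcTable) -> pd.Series:
    """True per sample iff the four spike signals increase strictly.

    A missing (NaN) spike slot makes the sample unevaluable (flag False
    — it cannot demonstrate monotone spikes).
    """
    spikes = qc.spike_signals().to_numpy(dtype=float)
    evaluable = ~np.isnan(spikes).any(axis=1)
    increasing = (np.diff(spikes, axis=1) > 0).all(axis=1)
    return pd.Series(evaluable & increasing, index=qc.sample_ids,
                     name="spike_monotonic")


def degradation_check(qc: QcTable, max_ratio: float = 3.0) -> pd.Series:
    """True per sample iff the 3'/5' ratio is strictly below ``max_ratio``."""
    return pd.Series(qc.table["ratio_3p_5p"] < max_ratio,
                     index=qc.sample_ids, name="degradation_pass")


def cross_lab_correlations(lab_medians_log2: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between laboratory median profiles.

    ``lab_medians_log2`` is symbols x labs (control-condition medians,
    usually restricted to the QC inclusion symbol set).  Standard
    centered Pearson r; a zero-variance profile has no defined r.
    """
    if lab_medians_log2.shape[1] < 2:
        raise ValueError("need at least 2 laboratories")
    if lab_medians_log2.shape[0] < 3:
        raise ValueError("need at least 3 symbols")
    sd = lab_medians_log2.std(axis=0, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(
            f"zero-variance median profile for lab(s) {flat}; "
            "Pearson correlation undefined")
    corr = lab_medians_log2.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def off_diagonal_range(corr: pd.DataFrame) -> tuple[float, float]:
    mask = ~np.eye(len(corr), dtype=bool)
    vals = corr.to_numpy()[mask]
    return float(vals.min()), float(vals.max())


def normality_check(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    Mean and sd are estimated from the data (a Lilliefors-style caveat:
    the nominal p-value is conservative toward normality).  Requires at
    least 30 values and non-degenerate spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 values for the normality check")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) input; normality undefined")
    stat, p = stats.kstest(x, "norm", args=(mu, sd))
    return float(stat), float(p)


def qc_report(qc: QcTable,
              lab_medians_log2: pd.DataFrame | None = None,
              max_ratio: float = 3.0) -> QcReport:
    """Assemble the full QC report; correlation/normality need profiles."""
    mono = spike_monotonicity(qc)
    degr = degradation_check(qc, max_ratio)
    report = QcReport(
        spike_monotonic=mono,
        spike_pass_count=int(mono.sum()),
        degradation_pass=degr,
        degradation_pass_count=int(degr.sum()),
        lowest_spike_present_fraction=float(
            (qc.table["spike1_call"] == "P").mean()),
    )
    if lab_medians_log2 is not None:
        corr = cross_lab_correlations(lab_medians_log2)
        report.lab_correlations = corr
        report.min_off_diagonal_r, report.max_off_diagonal_r = (
            off_diagonal_range(corr))
        cross_lab_median = lab_medians_log2.median(axis=1)
        report.ks_statistic, report.ks_pvalue = normality_check(
            cross_lab_median)
    return report
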