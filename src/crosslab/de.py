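"""Differential expression.

Two procedures from the consortium analysis:

* **Pooled, paired across laboratories** — each of the 5 SE
  laboratories contributes one median log2 value per symbol per
  condition; a paired t-test (df = n_labs - 1) compares each post-SE
  time point with control, Benjamini-Hochberg controls the FDR at 0.05
  across the above-background symbols, and the union over the three
  time points with an additional >=2-fold (1 log2 unit) change filter
  yields the clustering gene set.

* **Per laboratory, animal level** — unpaired t-tests (Welch by
  default) on log2 animal values, day 1 versus control within one
  laboratory, BH within that laboratory; the per-lab significant sets
  feed the between-lab/between-model concordance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneList,
    StudyDesign,
)
from .variability import lab_median_profiles

__all__ = [
    "DeResult",
    "paired_lab_test",
    "bh_fdr",
    "pooled_de",
    "per_lab_de",
]


@dataclass
class DeResult:
    """Per-symbol test results for one contrast.

    ``table`` columns: t, p, q (BH-adjusted), significant, delta_log2
    (mean per-lab difference of lab medians in pooled mode; difference
    of group means in per-lab mode), n_units.  ``m`` records the size of
    the tested universe used for the BH correction.
    """

    contrast: str
    table: pd.DataFrame
    m: int
    q_level: float

    def significant_symbols(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def paired_lab_test(control: pd.DataFrame, treated: pd.DataFrame
                    ) -> pd.DataFrame:
    """Two-sided paired t-test on per-lab median differences, per symbol.

    ``control`` and ``treated`` are symbols x labs median log2 matrices
    over the same laboratories.  df = n_labs - 1.  When every difference
    is identical the statistic degenerates: p = 1 for zero differences,
    p = 0 (flagged) for identical nonzero differences.
    """
    if list(control.columns) != list(treated.columns):
        raise ValueError("control and treated must cover the same labs "
                         f"({list(control.columns)} vs {list(treated.columns)})")
    n = control.shape[1]
    if n < 3:
        raise ValueError(f"paired test needs >= 3 labs, got {n}")
    diff = treated.to_numpy() - control.to_numpy()
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        t = np.where(degenerate,
                     np.sign(mean) * np.where(mean == 0, 0.0, np.inf), t)
        p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"t": t, "p": p, "delta_log2": mean, "n_units": n,
         "degenerate": degenerate},
        index=control.index)


def bh_fdr(pvals: pd.Series | np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: flags and adjusted p-values.

    Rejects H_(i) for all i <= max{k : p_(k) <= k*q/m}.  Returns
    ``(significant, q_adjusted)`` aligned with the input order; empty
    input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_adj = np.empty(m)
    q_adj[order] = np.minimum(q_sorted, 1.0)
    passing = np.nonzero(p[order] <= np.arange(1, m + 1) * q / m)[0]
    significant = np.zeros(m, dtype=bool)
    if passing.size:
        significant[order[: passing[-1] + 1]] = True
    return significant, q_adj


def pooled_de(expression: ExpressionMatrix, design: StudyDesign,
              config: AnalysisConfig | None = None,
              symbols: pd.Index | None = None
              ) -> tuple[dict[str, DeResult], GeneList, GeneList]:
    """Paired-across-labs DE at each SE time point, union, 2-fold sublist.

    ``symbols`` is the above-background universe (m for BH).  Returns
    ``(results_by_time_point, union_list, two_fold_list)``.  The 2-fold
    list contains union members with \\|delta_log2\\| >= the configured
    fold-change threshold at any significant time point.
    """
    config = config or AnalysisConfig()
    if symbols is not None:
        expression = expression.subset(features=symbols)
    se_labs = design.se_labs()
    control = lab_median_profiles(expression, design, "control", labs=se_labs)
    results: dict[str, DeResult] = {}
    union: set[str] = set()
    two_fold: set[str] = set()
    for tp in ("t1", "t2", "t3"):
        treated = lab_median_profiles(expression, design, tp, labs=se_labs)
        res = paired_lab_test(control, treated)
        significant, q_adj = bh_fdr(res["p"], config.fdr_q)
        res["q"] = q_adj
        res["significant"] = significant
        results[tp] = DeResult(contrast=f"{tp} vs control", table=res,
                               m=len(res), q_level=config.fdr_q)
        sig = res.index[res["significant"]]
        union.update(sig)
        big = res.loc[sig].index[
            res.loc[sig, "delta_log2"].abs() >= config.fold_change_log2]
        two_fold.update(big)
    provenance = (f"paired t over {len(se_labs)} SE labs, BH q={config.fdr_q}, "
                  f"m={len(control)}")
    union_list = GeneList("de_union", union, provenance + "; union over t1-t3")
    two_fold_list = GeneList(
        "de_two_fold", two_fold,
        provenance + f"; |delta_log2| >= {config.fold_change_log2} at any "
        "significant time point")
    return results, union_list, two_fold_list


def per_lab_de(expression: ExpressionMatrix, design: StudyDesign, lab: str,
               condition: str = "t1", config: AnalysisConfig | None = None,
               symbols: pd.Index | None = None, welch: bool = True
               ) -> tuple[DeResult, GeneList]:
    """Unpaired t-tests on animal-level log2 values within one laboratory.

    Welch's unequal-variance test by default (``welch=False`` gives the
    pooled-variance Student's t).  Both groups need >= 3 animals.  A
    symbol with zero variance in both groups and equal means gets p = 1.
    """
    config = config or AnalysisConfig()
    if symbols is not None:
        expression = expression.subset(features=symbols)
    log2 = expression.to_log2().values
    a = log2[design.samples(lab=lab, condition=condition)].to_numpy()
    b = log2[design.samples(lab=lab, condition="control")].to_numpy()
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError(
            f"lab {lab!r}: need >= 3 animals per group "
            f"(got {a.shape[1]} {condition}, {b.shape[1]} control)")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    delta = a.mean(axis=1) - b.mean(axis=1)
    flat = np.isnan(t)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    table = pd.DataFrame(
        {"t": t, "p": p, "delta_log2": delta,
         "n_units": a.shape[1] + b.shape[1]},
        index=log2.index)
    significant, q_adj = bh_fdr(table["p"], config.fdr_q)
    table["q"] = q_adj
    table["significant"] = significant
    result = DeResult(contrast=f"{lab}: {condition} vs control", table=table,
                      m=len(table), q_level=config.fdr_q)
    gene_list = GeneList(
        f"de_{lab}_{condition}", result.significant_symbols(),
        f"unpaired {'Welch ' if welch else ''}t in {lab}, {condition} vs "
        f"control, BH q={config.fdr_q}, m={len(table)}")
    return result, gene_list
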