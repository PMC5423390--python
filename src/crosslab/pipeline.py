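"""End-to-end orchestration of the harmonisation analysis.

Stage order mirrors the study: probe filtering and detection-call
consensus, QC diagnostics, the cross-laboratory variability screen,
pooled and per-laboratory differential expression, group-profile
clustering with a control-versus-day-1 separation verdict, and
between-lab/between-model concordance.  A run is fully determined by
(inputs, configuration, seed); the report records every headline count
so the filtering funnel (probes -> single-gene probes -> symbols ->
above background -> DE -> 2-fold) can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as clio
from .cluster import hierarchical_cluster, multiway_concordance, separation_check
from .datatypes import AnalysisConfig, GeneList, Scale, StudyBundle
from .de import per_lab_de, pooled_de
from .detection import (
    above_background_report,
    collapse_calls,
    collapse_expression,
    filter_probes,
    qc_inclusion_filter,
)
from .qc import qc_report
from .simulate import GeneratorConfig, generate_cohort, write_cohort
from .variability import cross_lab_summary, lab_median_profiles

logger = logging.getLogger("crosslab")

__all__ = ["RunReport", "run_analysis", "run_pipeline", "load_config"]


@dataclass
class RunReport:
    """Machine-readable record of one full pipeline run."""

    config: dict
    seed: int | None
    counts: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    variability: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1, sort_keys=True, default=_js)
        if path is not None:
            Path(path).write_text(text)
        return text


def _js(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.17g").encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def run_analysis(bundle: StudyBundle, config: AnalysisConfig | None = None
                 ) -> tuple[RunReport, dict]:
    """Run every analysis stage on a loaded study bundle.

    Returns the report plus an ``artifacts`` dict holding the in-memory
    stage outputs (gene lists, summaries, dendrogram) for callers that
    want more than the headline numbers.
    """
    config = config or AnalysisConfig()
    report = RunReport(config=dataclasses.asdict(config), seed=None)
    artifacts: dict = {}

    # -- detection consensus -------------------------------------------------
    kept_probes = filter_probes(bundle.annotation)
    annot = bundle.annotation
    kept_annot = annot.table.loc[kept_probes]
    from .datatypes import ProbeAnnotation
    annot_f = ProbeAnnotation(kept_annot[["gene_symbol"]].copy())
    calls_f = bundle.calls
    symbol_calls = collapse_calls(
        type(calls_f)(calls_f.calls.loc[kept_probes]), annot_f,
        config.min_probe_present_fraction)
    symbol_expr = collapse_expression(
        bundle.expression.subset(features=kept_probes), annot_f)
    ab = above_background_report(symbol_calls, bundle.design, config)
    universe = ab.overall.index[ab.overall]
    qc_incl = qc_inclusion_filter(symbol_calls, bundle.design,
                                  config.qc_max_absent_calls_per_lab,
                                  config.qc_min_labs)
    report.counts.update({
        "probes_total": int(len(bundle.expression.feature_ids)),
        "probes_single_gene": int(len(kept_probes)),
        "symbols": int(len(symbol_calls.symbols)),
        "symbols_above_background": int(len(universe)),
        "symbols_qc_included": int(qc_incl.sum()),
    })
    logger.info("funnel: %s", report.counts)
    artifacts.update(symbol_calls=symbol_calls, symbol_expr=symbol_expr,
                     above_background=ab, universe=universe, qc_incl=qc_incl)

    # -- QC ------------------------------------------------------------------
    if bundle.qc is not None:
        qc_symbols = qc_incl.index[qc_incl]
        medians = lab_median_profiles(symbol_expr.subset(features=qc_symbols),
                                      bundle.design, "control")
        qr = qc_report(bundle.qc, medians, config.degradation_ratio_max)
        report.qc = qr.to_dict()
        artifacts["qc_report"] = qr

    # -- cross-laboratory variability ----------------------------------------
    summary = cross_lab_summary(symbol_expr, bundle.design, config,
                                symbols=qc_incl.index[qc_incl])
    report.variability = {
        "mean_cv_pct": summary.mean_cv_pct,
        "sd_cv_pct": summary.sd_cv_pct,
        "variable_cutoff_pct": summary.variable_cutoff_pct,
        "n_stable": int(len(summary.symbols_in_class("stable"))),
        "n_typical": int(len(summary.symbols_in_class("typical"))),
        "n_variable": int(len(summary.symbols_in_class("variable"))),
    }
    artifacts["variability"] = summary

    # -- differential expression ---------------------------------------------
    de_results, union_list, two_fold = pooled_de(
        symbol_expr, bundle.design, config, symbols=universe)
    report.de = {
        "per_time_point": {tp: int(r.table["significant"].sum())
                           for tp, r in de_results.items()},
        "union": len(union_list),
        "two_fold": len(two_fold),
    }
    per_lab_lists: list[GeneList] = []
    for lab in bundle.design.se_labs():
        _res, gl = per_lab_de(symbol_expr, bundle.design, lab, "t1",
                              config, symbols=universe)
        per_lab_lists.append(gl)
    report.de["per_lab_t1"] = {gl.name: len(gl) for gl in per_lab_lists}
    artifacts.update(de_results=de_results, de_union=union_list,
                     de_two_fold=two_fold, per_lab_lists=per_lab_lists)

    # -- clustering ----------------------------------------------------------
    if len(two_fold) >= 1:
        se_labs = bundle.design.se_labs()
        cols = {}
        for lab in se_labs:
            for cond in ("control", "t1", "t2", "t3"):
                prof = lab_median_profiles(
                    symbol_expr.subset(features=sorted(two_fold.symbols)),
                    bundle.design, cond, labs=[lab])
                cols[f"{lab}:{cond}"] = prof[lab]
        profiles = pd.DataFrame(cols)
        dendro = hierarchical_cluster(profiles)
        controls = {c for c in profiles.columns if c.endswith(":control")}
        day1 = {c for c in profiles.columns if c.endswith(":t1")}
        separated = separation_check(dendro, controls, day1)
        report.clustering = {
            "n_genes": len(two_fold),
            "n_groups": profiles.shape[1],
            "control_vs_t1_separated": bool(separated),
            "newick": dendro.to_newick(),
        }
        artifacts["dendrogram"] = dendro
    else:
        report.clustering = {"n_genes": 0, "skipped": True}
        logger.warning("no 2-fold DE genes; clustering skipped")

    # -- concordance ---------------------------------------------------------
    if len(per_lab_lists) >= 2 and any(len(g) for g in per_lab_lists):
        conc = multiway_concordance(per_lab_lists)
        report.concordance = {
            "n_intersection": len(conc.intersection),
            "n_union": conc.union_size,
            "pct": conc.pct,
            "pairwise": conc.pairwise.to_dict(orient="records"),
        }
        artifacts["concordance"] = conc
    else:
        report.concordance = {"skipped": True}

    report.checksums = {
        "expression": _checksum(bundle.expression.values),
        "calls": _checksum(bundle.calls.calls),
    }
    return report, artifacts


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunReport:
    """Run the full pipeline from a YAML config file.

    The config either contains a ``simulate`` section (GeneratorConfig
    fields) or a ``study`` section with component paths; an ``analysis``
    section overrides AnalysisConfig defaults.  All stage outputs and
    the JSON report are written under *out_dir*.
    """
    cfg = load_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**(cfg.get("analysis") or {}))

    truth = None
    if "study" in cfg:
        paths = cfg["study"]
        bundle = clio.read_study(
            paths["expression"], paths["calls"], paths["design"],
            paths["annotation"], paths.get("qc"),
            scale=paths.get("scale", "linear"))
    else:
        gen = GeneratorConfig(**(cfg.get("simulate") or {}))
        n_labs = len(gen.labs)
        if analysis.min_control_labs > n_labs:
            raise ValueError(
                f"min_control_labs ({analysis.min_control_labs}) exceeds the "
                f"number of laboratories ({n_labs})")
        bundle, truth = generate_cohort(gen, seed=seed)
        write_cohort(bundle, truth, out_dir / "cohort", overwrite=True)

    report, artifacts = run_analysis(bundle, analysis)
    report.seed = seed

    for name in ("de_union", "de_two_fold"):
        if name in artifacts:
            clio.write_gene_list(artifacts[name], out_dir / f"{name}.txt")
    for gl in artifacts.get("per_lab_lists", []):
        clio.write_gene_list(gl, out_dir / f"{gl.name}.txt")
    if "variability" in artifacts:
        artifacts["variability"].table.to_csv(
            out_dir / "cross_lab_summary.tsv", sep="\t",
            float_format="%.6g")
    if "dendrogram" in artifacts:
        (out_dir / "dendrogram.nwk").write_text(
            artifacts["dendrogram"].to_newick() + "\n")
    report.to_json(out_dir / "report.json")
    return report
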