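"""Synthetic multi-laboratory cohort generator with known ground truth.

Emulates the structure of the GSE47752 consortium: 7 laboratories
running 4 rat epilepsy models (two labs each for pilocarpine, kainate
and kindling; one for SSSE), 4 conditions per model (control + three
time points / kindling stages), and 6 animals per laboratory-condition
group.

The generative model is additive on the log2 scale (classic log-normal
microarray noise).  For gene g, laboratory l, animal a in condition c:

    log2 signal = b_g + L_{g,l} + s_g * effect * decay(c) + eps_a

with per-gene baseline b_g ~ N(mu0, sigma0), a per-gene-per-lab batch
effect L_{g,l} ~ N(0, sigma_lab(g)) drawn from a three-component
mixture (stable / typical / hyper-variable genes), and i.i.d. animal
noise.  Probe-level values add a fixed per-probe offset.  Detection
calls are Bernoulli draws from a logistic model on the log2 signal,
P(Present) = 1 / (1 + exp(-(x - theta)/s)).

Planted structure (the ground truth every downstream stage is tested
against): a shared differential-expression core active in all SE
models, model-private and lab-private DE sets, and the stable /
hyper-variable gene classes.  Differential effects apply at full
strength one day after SE and decay geometrically at the later time
points, so day-1 groups separate in clustering while day-3/10 groups
intermix.  Kindling laboratories receive no planted effects.  Planted
genes are drawn from genes expressed well above the detection midpoint
— a study can only recover effects in transcripts the platform
detects.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    DetectionCallMatrix,
    ExpressionMatrix,
    GeneList,
    ProbeAnnotation,
    QcTable,
    Scale,
    StudyBundle,
    StudyDesign,
)
from . import io as clio

__all__ = ["GeneratorConfig", "SimulationTruth", "generate_cohort",
           "write_cohort", "read_truth"]

_MODEL_PREFIX = {"pilocarpine": "pilo", "kainate": "kain",
                 "SSSE": "ssse", "kindling": "kind"}


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic consortium.

    Defaults emulate the deposited study design and its published
    summary statistics: class proportions mirror the observed stable /
    hyper-variable fractions (59 and 87 of ~9.3k control transcripts,
    i.e. ~1% each), the hyper-variable lab-effect sd of 1.0 log2 units
    yields cross-laboratory CVs in the reported 35-85% band, and the
    planted DE set sizes give a day-1 union near 20% of symbols with a
    shared core near 4.5% of that union.
    """

    labs_per_model: dict[str, int] = field(default_factory=lambda: {
        "pilocarpine": 2, "kainate": 2, "SSSE": 1, "kindling": 2})
    animals_per_group: int = 6
    n_symbols: int = 2000
    max_probes_per_symbol: int = 4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    # lab-effect sd mixture: stable / typical / hyper-variable genes
    lab_sd_stable: float = 0.01
    lab_sd_typical: float = 0.20
    lab_sd_variable: float = 1.0
    prop_stable: float = 0.01
    prop_variable: float = 0.01
    animal_sd: float = 0.30
    animal_sd_stable: float = 0.05   # stable genes are quiet at both levels
    # planted differential expression
    effect_log2: float = 1.5
    effect_decay: tuple[float, float, float] = (1.0, 0.6, 0.3)
    n_shared_de: int = 20
    n_model_private_de: int = 45
    n_lab_private_de: int = 55
    min_planted_baseline_log2: float = 6.5
    # detection model
    detection_theta: float = 5.0
    detection_slope: float = 0.7
    marginal_fraction: float = 0.02  # of Absent calls rendered as Marginal
    probe_offset_sd: float = 0.15
    # nuisance probes exercising the probe filter
    frac_qualified_probes: float = 0.05
    n_affx_probes: int = 10
    frac_composite_symbols: float = 0.02
    # QC channels
    spike_log2_means: tuple[float, float, float, float] = (6.0, 8.0, 10.0, 12.0)
    spike_log2_sd: float = 0.3
    degradation_log_mean: float = math.log(1.6)
    degradation_log_sd: float = 0.15
    degradation_fail_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (np.diff(self.spike_log2_means) <= 0).any():
            raise ValueError("spike means must be strictly increasing")
        for name in ("lab_sd_stable", "lab_sd_typical", "lab_sd_variable",
                     "animal_sd", "animal_sd_stable", "spike_log2_sd",
                     "probe_offset_sd", "degradation_log_sd",
                     "detection_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.prop_stable + self.prop_variable >= 1.0:
            raise ValueError("mixture proportions must leave a typical class")
        n_se_models = sum(1 for m in self.labs_per_model if m != "kindling")
        n_se_labs = sum(v for m, v in self.labs_per_model.items()
                        if m != "kindling")
        planted = (self.n_shared_de + n_se_models * self.n_model_private_de
                   + n_se_labs * self.n_lab_private_de
                   + int(self.prop_stable * self.n_symbols)
                   + int(self.prop_variable * self.n_symbols))
        if planted > self.n_symbols:
            raise ValueError(
                f"planted set sizes ({planted}) exceed n_symbols "
                f"({self.n_symbols})")

    @property
    def labs(self) -> list[str]:
        out = []
        for model, k in self.labs_per_model.items():
            out += [f"{_MODEL_PREFIX[model]}-{i + 1}" for i in range(k)]
        return out

    def model_of(self, lab: str) -> str:
        prefix = lab.rsplit("-", 1)[0]
        for model, pre in _MODEL_PREFIX.items():
            if pre == prefix:
                return model
        raise ValueError(f"unknown lab {lab!r}")


@dataclass
class SimulationTruth:
    """Planted ground truth of one generated cohort."""

    shared_de_core: GeneList
    model_private_de: dict[str, GeneList]
    lab_private_de: dict[str, GeneList]
    planted_stable: GeneList
    planted_variable: GeneList
    effect_log2: float
    gene_params: pd.DataFrame  # baseline, lab_sd, animal_sd, de_sign per symbol

    def __post_init__(self) -> None:
        de_sets = [self.shared_de_core.symbols]
        de_sets += [g.symbols for g in self.model_private_de.values()]
        de_sets += [g.symbols for g in self.lab_private_de.values()]
        total = sum(len(s) for s in de_sets)
        if len(frozenset().union(*de_sets)) != total:
            raise ValueError("planted DE sets must be pairwise disjoint")
        if self.planted_stable.symbols & self.planted_variable.symbols:
            raise ValueError("stable and variable sets must be disjoint")

    def expected_t1_de(self, lab: str, model: str) -> frozenset[str]:
        """Symbols carrying a planted day-1 effect in the given lab."""
        out = set(self.shared_de_core.symbols)
        out |= self.model_private_de.get(model, GeneList(model, [])).symbols
        out |= self.lab_private_de.get(lab, GeneList(lab, [])).symbols
        return frozenset(out)

    def all_de_symbols(self) -> frozenset[str]:
        sets = [self.shared_de_core.symbols]
        sets += [g.symbols for g in self.model_private_de.values()]
        sets += [g.symbols for g in self.lab_private_de.values()]
        return frozenset().union(*sets)

    def to_json(self, path) -> None:
        payload = {
            "shared_de_core": sorted(self.shared_de_core.symbols),
            "model_private_de": {m: sorted(g.symbols)
                                 for m, g in self.model_private_de.items()},
            "lab_private_de": {l: sorted(g.symbols)
                               for l, g in self.lab_private_de.items()},
            "planted_stable": sorted(self.planted_stable.symbols),
            "planted_variable": sorted(self.planted_variable.symbols),
            "effect_log2": self.effect_log2,
            "gene_params": self.gene_params.reset_index().to_dict(
                orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    gp = pd.DataFrame(payload["gene_params"]).set_index("gene_symbol")
    return SimulationTruth(
        shared_de_core=GeneList("shared_de_core", payload["shared_de_core"]),
        model_private_de={m: GeneList(f"model_private_{m}", s)
                          for m, s in payload["model_private_de"].items()},
        lab_private_de={l: GeneList(f"lab_private_{l}", s)
                        for l, s in payload["lab_private_de"].items()},
        planted_stable=GeneList("planted_stable", payload["planted_stable"]),
        planted_variable=GeneList("planted_variable",
                                  payload["planted_variable"]),
        effect_log2=payload["effect_log2"],
        gene_params=gp,
    )


def _symbol_names(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    names = [f"Gene{i:04d}" for i in range(cfg.n_symbols)]
    n_comp = int(cfg.frac_composite_symbols * cfg.n_symbols)
    comp_idx = rng.choice(cfg.n_symbols, size=n_comp, replace=False)
    for i in comp_idx:
        names[i] = f"{names[i]}///LOC{900000 + i}"
    return names


def generate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[StudyBundle, SimulationTruth]:
    """Generate one synthetic consortium cohort.

    Returns a :class:`StudyBundle` (probe-level linear expression,
    detection calls, design, annotation, QC channel) plus the
    :class:`SimulationTruth`.  Identical ``(config, seed)`` give
    bit-identical output.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    symbols = _symbol_names(cfg, rng)
    n = cfg.n_symbols

    # --- per-gene parameters ------------------------------------------------
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    n_stable = int(cfg.prop_stable * n)
    n_variable = int(cfg.prop_variable * n)
    detectable = np.nonzero(baseline >= cfg.min_planted_baseline_log2)[0]
    se_models = [m for m in cfg.labs_per_model if m != "kindling"]
    se_labs = [l for l in cfg.labs if cfg.model_of(l) != "kindling"]
    n_planted_de = (cfg.n_shared_de + len(se_models) * cfg.n_model_private_de
                    + len(se_labs) * cfg.n_lab_private_de)
    need = n_planted_de + n_stable + n_variable
    if len(detectable) < need:
        raise ValueError("not enough well-expressed genes to plant all sets; "
                         "lower the planted sizes or raise n_symbols")
    chosen = rng.choice(detectable, size=need, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = chosen[cursor:cursor + k]
        cursor += k
        return out

    core_idx = take(cfg.n_shared_de)
    model_idx = {m: take(cfg.n_model_private_de) for m in se_models}
    lab_idx = {l: take(cfg.n_lab_private_de) for l in se_labs}
    stable_idx = take(n_stable)
    variable_idx = take(n_variable)

    lab_sd = np.full(n, cfg.lab_sd_typical)
    lab_sd[stable_idx] = cfg.lab_sd_stable
    lab_sd[variable_idx] = cfg.lab_sd_variable
    animal_sd = np.full(n, cfg.animal_sd)
    animal_sd[stable_idx] = cfg.animal_sd_stable

    de_idx = np.concatenate([core_idx] + list(model_idx.values())
                            + list(lab_idx.values()))
    de_sign = np.zeros(n)
    de_sign[de_idx] = rng.choice([-1.0, 1.0], size=de_idx.size)

    # --- design -------------------------------------------------------------
    rows = []
    for lab in cfg.labs:
        model = cfg.model_of(lab)
        for cond in CONDITIONS:
            for a in range(1, cfg.animals_per_group + 1):
                rows.append({"sample_id": f"{lab}_{cond}_a{a}",
                             "lab_id": lab, "model": model,
                             "condition": cond, "animal_index": a})
    design_df = pd.DataFrame(rows).set_index("sample_id")
    design = StudyDesign(design_df)
    sample_ids = design_df.index
    n_samples = len(sample_ids)

    # --- symbol-level log2 signal -------------------------------------------
    decay = dict(zip(("t1", "t2", "t3"), cfg.effect_decay))
    sym_log2 = np.empty((n, n_samples))
    col = 0
    for lab in cfg.labs:
        model = cfg.model_of(lab)
        lab_effect = rng.normal(0.0, lab_sd)
        affected = np.zeros(n, dtype=bool)
        if model != "kindling":
            affected[core_idx] = True
            affected[model_idx[model]] = True
            affected[lab_idx[lab]] = True
        for cond in CONDITIONS:
            delta = np.zeros(n)
            if cond != "control" and model != "kindling":
                delta[affected] = (de_sign[affected] * cfg.effect_log2
                                   * decay[cond])
            for _a in range(cfg.animals_per_group):
                noise = rng.normal(0.0, animal_sd)
                sym_log2[:, col] = baseline + lab_effect + delta + noise
                col += 1

    # --- probe level --------------------------------------------------------
    probes_per_symbol = rng.integers(1, cfg.max_probes_per_symbol + 1, size=n)
    probe_rows, probe_symbols = [], []
    pid = 1367000
    for i, sym in enumerate(symbols):
        for _k in range(probes_per_symbol[i]):
            probe_rows.append((f"{pid}_at", i))
            pid += 1
    n_qual = int(cfg.frac_qualified_probes * len(probe_rows))
    qual_targets = rng.choice(n, size=n_qual, replace=True)
    for j, i in enumerate(qual_targets):
        suffix = "_s_at" if j % 2 == 0 else "_x_at"
        probe_rows.append((f"{pid}{suffix}", int(i)))
        pid += 1
    probe_ids = [p for p, _ in probe_rows]
    probe_gene_idx = np.array([i for _, i in probe_rows])
    offsets = rng.normal(0.0, cfg.probe_offset_sd, len(probe_rows))
    probe_log2 = sym_log2[probe_gene_idx] + offsets[:, None]

    # AFFX hybridisation controls: bright, effect-free
    affx_names = [f"AFFX-Ctrl{i + 1}_at" for i in range(cfg.n_affx_probes)]
    affx_log2 = rng.normal(10.0, 0.3, (cfg.n_affx_probes, n_samples))

    all_probe_ids = probe_ids + affx_names
    all_log2 = np.vstack([probe_log2, affx_log2])
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(all_log2), index=all_probe_ids,
                     columns=sample_ids),
        Scale.LINEAR)

    annot = ProbeAnnotation(pd.DataFrame(
        {"gene_symbol": [symbols[i] for i in probe_gene_idx]
         + [f"AFFX-Ctrl{i + 1}" for i in range(cfg.n_affx_probes)]},
        index=pd.Index(all_probe_ids, name="probe_id")))

    # --- detection calls ----------------------------------------------------
    p_present = 1.0 / (1.0 + np.exp(
        -(all_log2 - cfg.detection_theta) / cfg.detection_slope))
    present = rng.random(all_log2.shape) < p_present
    marginal = (~present) & (rng.random(all_log2.shape)
                             < cfg.marginal_fraction)
    codes = np.where(present, "P", np.where(marginal, "M", "A"))
    calls = DetectionCallMatrix(pd.DataFrame(
        codes, index=all_probe_ids, columns=sample_ids))

    # --- QC channel ---------------------------------------------------------
    spike_log2 = rng.normal(np.array(cfg.spike_log2_means), cfg.spike_log2_sd,
                            (n_samples, 4))
    ratio = np.exp(rng.normal(cfg.degradation_log_mean, cfg.degradation_log_sd,
                              n_samples))
    n_fail = int(round(cfg.degradation_fail_fraction * n_samples))
    if n_fail:
        fail_at = rng.choice(n_samples, size=n_fail, replace=False)
        ratio[fail_at] = rng.uniform(3.2, 4.0, n_fail)
    qc = QcTable(pd.DataFrame(
        {"spike1": np.exp2(spike_log2[:, 0]),
         "spike2": np.exp2(spike_log2[:, 1]),
         "spike3": np.exp2(spike_log2[:, 2]),
         "spike4": np.exp2(spike_log2[:, 3]),
         "ratio_3p_5p": ratio,
         "spike1_call": np.where(spike_log2[:, 0] >= cfg.detection_theta,
                                 "P", "A")},
        index=sample_ids))

    gene_params = pd.DataFrame(
        {"baseline_log2": baseline, "lab_sd": lab_sd, "animal_sd": animal_sd,
         "de_sign": de_sign},
        index=pd.Index(symbols, name="gene_symbol"))
    truth = SimulationTruth(
        shared_de_core=GeneList(
            "shared_de_core", [symbols[i] for i in core_idx],
            f"planted |delta log2| = {cfg.effect_log2} at t1 in all SE labs"),
        model_private_de={
            m: GeneList(f"model_private_{m}", [symbols[i] for i in idx])
            for m, idx in model_idx.items()},
        lab_private_de={
            l: GeneList(f"lab_private_{l}", [symbols[i] for i in idx])
            for l, idx in lab_idx.items()},
        planted_stable=GeneList("planted_stable",
                                [symbols[i] for i in stable_idx]),
        planted_variable=GeneList("planted_variable",
                                  [symbols[i] for i in variable_idx]),
        effect_log2=cfg.effect_log2,
        gene_params=gene_params,
    )
    bundle = StudyBundle(expression=expr, calls=calls, design=design,
                         annotation=annot, qc=qc)
    return bundle, truth


def write_cohort(bundle: StudyBundle, truth: SimulationTruth, directory,
                 overwrite: bool = False) -> dict[str, Path]:
    """Write a generated cohort plus its truth record as JSON.

    Refuses a non-empty directory unless ``overwrite`` is set.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace")
    paths = clio.write_study(bundle, directory)
    paths["truth"] = directory / "truth.json"
    truth.to_json(paths["truth"])
    return paths
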