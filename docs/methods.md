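# Methods

## Scope and data model

`crosslab` operates on four aligned tables: a probe-level expression
matrix (linear-scale signal, with a log2 view), a Present/Absent/
Marginal detection-call matrix of the same shape, per-sample metadata
(laboratory, animal model, condition, animal index), and a probe →
gene-symbol annotation; an optional QC table carries four spike-in
signals, the median 3'/5' intensity ratio, and the lowest-spike call
per sample. All serialisation is tab-separated text with full float
precision, so a written study re-reads bit-identically.

Two conventions apply throughout. Marginal calls are treated as
Absent: the consensus rules are phrased in terms of Present versus
not-Present, and folding the rare Marginal class into Absent is the
conservative choice. Composite symbols (`Hba1///Hba2`) are opaque
single tokens, matching how multi-gene probe sets are reported.

## Detection consensus

The tiers are implemented exactly as absolute-count rules:

* probe filter — keep only bare-`_at` probe sets (no `_s_at`/`_x_at`/
  `_a_at` qualifier, no `AFFX-` prefix), the class being derived from
  the probe-id text itself;
* symbol collapse — Present when ≥ 50% of a symbol's probes are
  Present ("at least": a 2-of-4 split qualifies);
* lab tier — ≥ 3 Present animals in the lab–condition group, an
  absolute count even for 4–5-animal groups;
* condition tier — ≥ 4 of the 5 SE-model laboratories for t1–t3;
  ≥ 6 of all 7 laboratories (kindling included) for control;
* overall — Present in any condition.

Kindling laboratories participate only in the control tier by default;
their stage contrasts can be analysed with the per-lab test. Once a
symbol passes, its expression values are used for every animal
regardless of individual calls — the filter never masks data.

A separate inclusion filter guards the control-condition QC analyses:
a symbol qualifies when at least 6 of the 7 laboratories have at most
3 Absent calls among their control animals.

## Variability screen

Per-lab medians use the midpoint convention for even counts. The CV is
computed on the **linear** scale — published group medians are linear
signal units, and a CV of log2 values would be meaningless — with the
n − 1 standard deviation, laboratories being sampled units. The class
rules are `stable: CV < 3%` (absolute) and `variable: CV > mean +
3·SD` of the cohort CV distribution (cohort-relative, both cutoffs
configurable); when classifying a subset against statistics from a
larger screen, the cohort mean and SD can be supplied externally. If
the relative cutoff ever fell below the stable threshold, stability
takes precedence with a warning.

## Differential expression

The pooled test is a textbook paired t on the per-lab differences of
median log2 values (df = n_labs − 1). Degenerate cases are explicit:
all-zero differences give t = 0, p = 1; identical non-zero differences
give p = 0 with a `degenerate` flag rather than a division error.
Benjamini–Hochberg is implemented directly (step-up, reject all
hypotheses up to the largest k with p₍ₖ₎ ≤ kq/m) and cross-checked in
the tests against both a naive enumeration and
`statsmodels.multipletests`; the tested universe m is always the
above-background set for the relevant tier and is recorded in the
result. The 2-fold sub-list takes union members with |Δ median log2|
≥ 1 at any significant time point — the "any time point" reading is
recorded in the list's provenance string.

Per-lab tests default to Welch's unequal-variance t (robust at n = 6
per group; a pooled-variance switch exists). Zero-variance groups with
equal means give p = 1; groups under 3 animals are an error.

## Clustering and concordance

The uncentered Pearson similarity and its 1 − r_u distance are authored
here (it is not a mean-centered correlation, so `pandas.corr` does not
apply); the agglomeration itself is `scipy.cluster.hierarchy.linkage`
with complete linkage, whose merge heights are verified ultrametric on
every construction and checked against a brute-force all-pairs
agglomeration in the tests. Columns are lab×condition median-log2
profiles of the 2-fold DE gene set (20 for the SE track: 5 labs × 4
conditions). The separation verdict asks for two disjoint subtrees,
each containing all members of one group set and none of the other,
with bystander labels permitted anywhere.

Concordance is intersection-over-union of gene sets, pairwise and
multiway; 73 common genes over a 1,638-gene union reproduces the
published 4.5%.

## QC diagnostics

Spike monotonicity demands strictly increasing signal across the four
spikes (ties fail); the 3'/5' degradation bound is strict (`ratio < 3`,
so 3.0 fails), mirroring the stated operator. Cross-laboratory
correlations are standard centered Pearson on control lab-median log2
profiles over the QC-inclusion symbols. The normality check is a
one-sample Kolmogorov–Smirnov test against a normal with mean and sd
estimated from the data — a Lilliefors-style caveat applies (the
nominal p is conservative toward normality), noted here because no
parameters are published for this check.

## The synthetic consortium

The generator emulates the consortium design: 7 labs (pilocarpine ×2,
kainate ×2, SSSE ×1, kindling ×2), 4 conditions, 6 animals per group
(168 arrays), 2,000 symbols with 1–4 probes each plus qualifier-suffixed
and AFFX nuisance probes that exercise the probe filter.

Signal is additive on the log2 scale:

    x = b_g + L_{g,l} + s_g · effect · decay(c) + ε,
    b_g ~ N(8, 2),  L_{g,l} ~ N(0, σ_lab(g)),  ε ~ N(0, σ_a(g))

with fixed per-probe offsets ~ N(0, 0.15). Detection calls are
Bernoulli draws from P(Present) = 1/(1 + exp(−(x − θ)/s)) with θ = 5,
s = 0.7; 2% of Absent calls are rendered Marginal. The spike channel
draws four log2 signals around means (6, 8, 10, 12) with sd 0.3 — the
lowest spike sits well above the detection midpoint, so it is called
Present in essentially every sample — and the 3'/5' ratio is
LogNormal(ln 1.6, 0.15) with an optional injected-failure fraction.

**Lab-effect mixture.** σ_lab is drawn from three components: stable
(σ = 0.01, 1% of genes), typical (σ = 0.20, 98%), hyper-variable
(σ = 1.0, 1%). The proportions mirror the observed class fractions in
the reference study (59 stable and 87 variable of ~9.3k control
transcripts, i.e. ≈1% each), and σ = 1.0 for the heavy class places its
linear-scale CVs in the observed 35–85% band. These choices matter for
the mean + 3·SD screen: the cutoff is estimated from the same cohort
it classifies, so a heavy-variance class much larger than a few percent
inflates its own cutoff and the screen loses sensitivity — with
realistic ~1% fractions the planted classes are cleanly separable.
Stable genes also receive reduced animal noise (σ_a = 0.05 instead of
0.30): with seven labs of six animals, animal-level noise alone puts a
floor of ~10% on the lab-median CV, whereas genuinely stable
transcripts in real data reach 1–3% — low variance at both levels is
what "stable" means biologically (housekeeping-like expression).

**Planted differential expression.** A shared core (20 genes, DE in
all three SE models), model-private sets (45 per SE model, DE in both
of that model's labs) and lab-private sets (55 per SE lab) receive a
±1.5 log2 effect at day 1, decaying 1.0/0.6/0.3 across t1/t2/t3 so
day-1 groups separate in clustering while later time points intermix.
Kindling labs receive no planted effects, matching the near-absence of
kindling DE in the reference study. The sizes give an expected day-1
union near 20% of symbols and core/union ≈ 4.7%, emulating the
published 1,638-gene union with its 4.5% core at the generator's scale.
Planted genes are drawn from genes with baseline log2 ≥ 6.5 (well
above the detection midpoint) and from the typical-variance class: a
study can only recover effects in transcripts the platform detects,
and the published common-core list is disjoint from both the stable
and red-herring lists.

**What the generator does not model:** probe sequence effects, RMA/MAS5
normalisation artefacts, correlated gene modules, heavy-tailed or
count-based noise, missing animals (all groups are complete), and any
real biology of epileptogenesis. Passing recovery tests therefore
demonstrates that the pipeline's rules and statistics behave correctly
under the stated noise model — not that they would recover biology
from real arrays.

## Problem sizes and tolerances

Unit and property tests run on toy matrices and a 20-symbol cohort
where brute-force recounts are exact (equality to 1e-9–1e-12).
Recovery batteries use the full 2,000-symbol design over 5 seeds
(recall thresholds 90%, contamination 5%) and a 500-symbol null
configuration over 10 seeds for FDR calibration; these sizes give
stable averages while keeping the whole suite under half a minute.
`scripts/acceptance.py` repeats the same computations from scratch with
seeds derived from its `--seed` argument.

## Known limitations

* The per-symbol expression collapse (median of probe log2 values) is
  one reasonable convention; studies built on different summarisation
  (e.g. probe-set-level modelling) will differ in detail.
* The KS normality p-value ignores parameter estimation; treat it as a
  descriptive diagnostic, not a calibrated test.
* The separation check is a binary verdict on subtree purity; it does
  not quantify how close a near-separation is.
* Between-lab concordance percentages depend strongly on list sizes;
  IoU is reported because it reproduces the published arithmetic, but
  it is not comparable across studies with very different DE counts.
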