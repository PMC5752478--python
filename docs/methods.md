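# Methods

This note records the statistical models, the synthetic-data design, the
numerical conventions, and the reasoning behind the package's default
parameters. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

Each layer is tested feature-by-feature with a two-sided Welch *t* on
log2-scale values; the fold change is the difference of group means
(positive = higher in the comparison group, and the *t* statistic carries
the same sign). Welch's unequal-variance form is used because two-group
omics contrasts at n≈6 rarely justify a pooled-variance assumption and the
cost under equal variances is small. Degenerate features (zero variance in
both groups) are reported as t=0, p=1 when means agree and p=0 with a
logged warning otherwise; features with fewer than two observed values in
a group (possible in the NaN-carrying metabolite layer) get p=1 with a
warning rather than an error.

Multiple testing is `raw` by default, mirroring the per-feature p<0.05
convention of array/iTRAQ workflows; Benjamini–Hochberg (`bh`) is one
configuration flag away. The default call thresholds are p ≤ 0.05 and
|log2FC| ≥ 1 for both the miRNA and the protein layer. A p-only protein
call (lfc_min=0), which some iTRAQ studies use, is supported but not the
default: with ~10³ features it admits ≈ α·m ≈ 50 false positives per
contrast, which swamps a ~20-protein signature.

**Power at the default simulated design.** With δ=2, σ=0.5 and n=6 per
group, a planted feature has Welch noncentrality δ/(σ√(2/n)) ≈ 6.9 at
df ≈ 10. Raw p ≤ 0.05 then recovers essentially everything (per-feature
miss ~10⁻³) with an empirical false-discovery proportion of a few percent
once the fold-change filter is applied. BH at q ≤ 0.05 over m ≈ 1700
features with only ~28 true signals, however, demands p ≲ 1.3×10⁻³, i.e.
|t| ≳ 4.5 — and the sampling noise of the standard error at df ≈ 10 puts
~11% of true features below that line. Expected BH recovery is therefore
~88%, an intrinsic small-n limit, not an implementation artifact; the
acceptance script reports it honestly as `de_recovery_bh`. For designs of
this size the raw+fold-change operating point is the sensible default;
BH becomes the right choice as replication grows (n ≥ 8 pushes the same
calculation above 99% recovery).

## Chemometrics

Preprocessing follows the metabolomics convention: half-minimum imputation
for left-censored peaks (half the feature's observed minimum, applied to
the stored log2 values), optional sum normalization (performed on the linear scale: de-log, equalize
sample totals, re-log), then feature-wise Pareto scaling (divide by √sd)
and centering. Pareto is the default because it tempers, without erasing,
the intensity-dependence of LC-MS variance; UV and none are available.
Note that a half-minimum value on the log2 scale is a strong outlier, so
the *univariate* confirmation test described below deliberately bypasses
imputation.

PCA is computed by SVD with a deterministic sign convention (each
loading's largest-magnitude element is positive) so outputs are
bit-comparable across runs. PLS is single-response NIPALS; O-PLS follows
Trygg–Wold orthogonal signal correction: w ∝ Xᵀy, then per orthogonal
component p − (wᵀp)w (normalized), score extraction and deflation, and
finally one predictive PLS component on the filtered matrix. Orthogonal
scores have exactly zero training covariance with y by construction
(tᵒᵀy = ‖Xᵀy‖·(wᵒᵀw) = 0), and `n_ortho=0` reproduces one-component PLS
identically — both identities are asserted to 1e-10 in the tests. If no
orthogonal variation remains (‖wᵒ‖ < 1e-12) extraction stops early and the
model records fewer components. Class membership is coded −1/+1 and
centered; only two-group discrimination is supported.

VIP uses the classic predictive-components-only formula, which forces
Σ VIP² = J; Q² is estimated by stratified, seeded k-fold cross-validation
(1 − PRESS/SSY), with the fold count capped at the smallest class size so
every training split contains both classes (the default 7 folds becomes 6
at the default 6-per-group design).

**VIP threshold.** `RunConfig.vip_min` defaults to 8.0, the criterion
printed for dominant-peak LC-MS intensity tables, where a handful of
high-variance peaks can carry almost all of the covariance with class. On
the simulator's variance-homogeneous features that regime does not exist:
with J = 2964 features of equal residual variance, a planted metabolite's
VIP is bounded near √J·w ≈ 6 even at complete separation. The simulation
studies and the `run-all` default therefore use the field-standard VIP > 1
cutoff ("more important than the average variable"), followed by a Welch
confirmation (raw p ≤ 0.05) on the **unimputed** log2 matrix with
pairwise-complete statistics — the univariate second step that trims a VIP
list to the significantly changed metabolites.

## Pathway analysis

Over-representation is the exact hypergeometric tail P(X ≥ x) with
N = |universe| (annotated, detected compounds), K = |members ∩ universe|,
n = |hits|; no normal approximation. Topology impact is computed on the
undirected, unweighted pathway graph: node betweenness centralities are
normalized to sum to one and the impact is the sum over hit nodes —
endpoints contribute zero, articulation compounds dominate. BH is applied
across pathways; a pathway is flagged "potential" at q ≤ 0.05 or
impact ≥ 0.1. The bundled mini-library (five pathways, compound-name IDs,
hand-curated skeleton edges from public pathway maps) exists so the whole
chain runs self-contained; it is a miniature stand-in, not a substitute
for a full pathway database.

## Cross-omics integration

Every cross-layer pair of significant features receives a sample Pearson
correlation with pairwise-complete deletion (n updated per pair; constant
vectors are flagged not-computable and skipped, never propagated as NaN)
and a two-sided p from the t transform. Edges are filtered at
|r| ≥ r_min and p ≤ p_max — absolute value, because anti-correlation is as
informative as correlation; the sign stays on the edge. Hubs are
miRNA-side nodes ranked by degree, then mean |r|, then id.

Correlations span **all profiled samples** by default (18 at the default
design) rather than only the two contrast groups: treatment-induced
covariation is the object of interest, the significant-feature lists
already carry the contrast, and the wider scope improves the degrees of
freedom of the r-to-p transform (df = n−2 = 16). A `samples` argument
restricts the scope (within-group or pooled-contrast) for sensitivity
analysis. Edges are canonically ordered (lexicographic layer pair) so the
network is free of duplicates and byte-reproducible.

Note an inherent property of correlating *differential* features over
pooled groups: two features that both shift by δ between groups correlate
at about ρ = (δ²/4·v)/(δ²/4·v + σ²) from the group structure alone
(v = variance of the group indicator), ≈ 0.78 at the default design. The
r ≥ 0.9 filter sits deliberately above this floor; the analytic tail of
the null (no planted structure) case is what the calibration test checks.

## Assays

Mito-stress phase summaries follow standard reporting: baseline = mean of
its last three measurements, post-oligomycin = phase minimum, post-FCCP =
phase maximum, post-rotenone/antimycin = phase minimum. The derived
parameters obey atp_linked + proton_leak = basal_mito and
spare = maximal − basal_mito exactly by construction. Negative derived
rates are reported with a QC flag, never clipped. ECAR, when present, is
summarized descriptively (basal mean) only. 2^−ΔΔCt subtracts the
calibrator-group mean ΔCt on the ΔCt scale, so the calibrator group's
geometric-mean RQ is exactly 1.

## Synthetic data: what it emulates and what it does not

Each feature is μ_f + group effect + block term + ε with μ_f ~ N(8, 2²)
(log2 intensities), ε ~ N(0, σ²), σ = 0.5. Planted features shift by ±δ
(δ = 2) in the treated group only. Metabolite values are missing at random
with an intensity-dependent (logistic-in-μ) rate averaging 2%, emulating
LC-MS left-censoring. Defaults mirror the target study shape: 1695 / 1069
/ 2964 features, three groups (control, injury model, treated) of six —
the replicate count is this package's choice (typical for cell-model
omics) and is configurable.

**Correlation blocks.** A block couples a hub miRNA to partner features
(two proteins and one TCA metabolite by default) through one shared latent
factor per block: z_s = α·s_g + √(1−α²)·η_s, where s_g is the standardized
treatment-response pattern (low in treated) and η_s i.i.d. standard
normal; members receive sign·(3.5λ)·z_s. Three consequences drive the
defaults (λ = 0.95, α = 0.98):

- any two members share z exactly, so their population correlation is
  (3.5λ)²/((3.5λ)² + σ²) ≈ 0.978 — comfortably above the 0.9 filter even
  after sampling noise at n = 18;
- the latent factor is predominantly a treatment response, so every block
  member is itself strongly differentially expressed (the hub falls with
  treatment and its partners track it — the biological situation the block
  mimics, where the regulator and its targets co-respond);
- a within-group residual component (sd ≈ 3.5λ·√(1−α²) ≈ 0.66) keeps the
  block a genuine latent factor rather than a pure group indicator.

An independent (α = 0) latent factor large enough to clear the r ≥ 0.9
filter would make its members' within-group variance so large that their
own differential expression becomes undetectable — a hub that correlates
but never reaches the significant list. The treatment-aligned construction
resolves that tension and is the single most consequential design choice
in the generator.

The generator does **not** emulate: intensity-dependent variance
(heteroscedastic dominant peaks), batch or run-order effects, correlated
null features (co-regulation beyond the planted blocks), retention-time or
spectral structure, or annotation ambiguity. Passing the recovery tests
therefore demonstrates the pipeline's correctness and calibration on clean
signal, not robustness to those real-data pathologies.

## Determinism and numerics

One seed drives everything; per-layer substreams are spawned
deterministically from it. All writers use fixed formats (6-decimal
floats, LF line endings, sorted keys), so identical runs are
byte-identical — asserted in the test suite. Sign conventions on all
loadings/scores are deterministic. Tolerances: orthogonality and
equivalence identities at 1e-8–1e-10; VIP normalization at 1e-6 relative;
round-trip IO at 1e-9.

## Problem sizes used in the automated checks

The planted-truth study runs the full default dimensions over seeds 1–20.
The null-calibration study uses 120/100/150-feature layers (the analytic
expectation scales with the pair count, so smaller layers test the same
property), correlating 40 features per layer across 20 seeds. The
block-correlation Monte-Carlo check uses 100 scaled-down simulations.
These sizes keep the whole suite to a couple of minutes while leaving
every statistical check at full strength for its property.

## Known limitations

Two-group OPLS-DA only (no multi-class, no S-plots); no moderated-variance
DE models; no paired designs; pathway analysis ignores reaction
directionality and compound-ID ambiguity; the cross-omics stage requires
samples matched one-to-one across layers (an assumption the source study
design leaves implicit); Seahorse vendor formats and plate normalization
are out of scope. BH-adjusted discovery at n = 6 per group is underpowered
for ~28-signal layers (see the power note above) — collect more replicates
rather than loosening thresholds.
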