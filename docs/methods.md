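# Methods

This note documents the statistical model, the defaults and the design
choices behind `modnet`, and what the synthetic benchmark does and does not
establish.

## Data model and preprocessing

Inputs are three TSVs: expression (gene × sample, log scale), copy number
(gene × sample, log2 ratios) and sample → subtype labels. Samples are
aligned by id intersection — samples missing any of the three inputs are
dropped and counted — and sample/gene order is canonicalized by sorting, so
results are independent of file ordering. Rows with missing values are
dropped, not imputed: no imputation scheme is part of the method, and
module scores are sensitive to fabricated values. The expression and CNV
gene universes may differ; candidate modulators must appear in both
(their expression is the split predictor), targets only in expression.

## EMD differential analysis

Per gene, both classes are binned on the shared pooled range with
⌈√n⌉ equal-width cells (minimum 10; `histogram_bin_count` overrides).
Sharing the binning is what makes the transport distance comparable across
permutations, and on a shared grid the EMD reduces exactly to
Σ|CDF_P − CDF_Q|·width, which the permutation loop exploits; the test suite
asserts bit-level agreement (≤1e-9) with a transportation-LP solution.

The null model shuffles the class partition jointly across genes, keeping
gene–gene correlation. Each gene's null summary is the **median** of its
permuted EMDs. The FDR grid runs from T down to 0 in Δ = 0.001 steps with
T = round(max observed EMD) − 1, floored at Δ. Two consequences worth
knowing:

- Under a global null the maximum EMD is well below 1.5, T collapses to Δ,
  and every q-value is 1 — the method reports nothing rather than noise.
- When strong signal raises T, null genes in the upper tail of the observed
  distribution can receive small q-values (the median-based null is
  anti-conservative there). Downstream this is tolerable: spurious
  "targets" form noise modules whose splits never beat the penalty, and
  modulator candidacy is additionally gated by the frequency filters.

A denominator of zero (no observed EMD reaches the threshold) defines
FDR = 1, the conservative choice. Selection is strict (q < 0.1).

Because the grid collapse makes an EMD call on log2 copy-number ratios
uninformative at moderate effect sizes (a ±1 shift in 80% of a subtype
yields EMD ≈ 0.8), the pipeline's modulator pre-filter is the *converged*
gene subset: expression-differential genes present in the CNV matrix, whose
copy-number evidence is then tested directly by the nonparametric frequency
criteria below. An EMD analysis of the CNV matrix remains available
(`modnet diff --matrix cnv`).

## Aberration calls and modulator nomination

Calls are inclusive: amplified at log2 ≥ +0.3, deleted at ≤ −0.3. "Mutation"
frequency fre is the fraction of a group's samples with any aberration.
The between-group frequency difference is the larger of the amplification
and deletion differences. Both filters are strict: freq_diff > 0.20 and
fre > 0.6, the latter within the focal subtype by default
(`modulator_freq_scope="all"` evaluates it across all tumors instead).

## Normal-Gamma scoring

A leaf holding values x₁..x_N is scored by the log marginal likelihood of a
normal model with unknown mean and precision under a Normal-Gamma prior
with prior mean 0, shape α (default 2), precision scaling λ (default 0.1)
and rate β = max(1, λ(α−2)/(λ+1)) — equal to 1 at the defaults:

    −(N/2)·ln 2π + ½·ln(λ/(λ+N)) + ln Γ(α⁺) − ln Γ(α) + α·ln β − α⁺·ln β⁺
    α⁺ = α + N/2,  β⁺ = β + N·Var(x)/2 + Nλx̄²/(2(N+λ))

with population variance. An empty leaf scores 0. The expression was
verified, before the pipeline was built, against two independent oracles:
a 2-D Gauss–Legendre quadrature of ∫∫ ∏N(xᵢ|μ,τ⁻¹)·NG(μ,τ) dμ dτ (agreement
≤1e-6 over 200 random leaves) and the sequential Student-t predictive
product (≤1e-8). The anchor case N=1, x=0, α=2, λ=1 equals the Student-t
(df 4) log density at 0, −0.98083.

Because the prior mean is 0, target expression is centered per gene before
scoring (`center_expression`, default on; computed on the learning sample
set, so bootstrap runs center on their own resample).

## Threshold fitting and initial modules

Each candidate modulator's split value comes from 1-D k-means (k = 2) on
its expression, initialized at the means of the CNV-neutral vs aberrant
samples; the aberrant class is the more frequent of {amplified, deleted}
(the rarer class merges with neutral, since a gene recurrently altered in
one direction in a subtype rarely carries informative calls in the other).
The threshold is the midpoint of the two final centers. Degenerate cases —
constant expression, no aberrant or no neutral samples — raise, and during
ensemble resampling such modulators are skipped for that run.

Each target gene is then assigned to the single modulator whose
below/at-or-above-threshold partition yields the highest split gain
score(A) + score(B) − score(A∪B) − penalty; ties break to the smaller
modulator id, and a modulator is never assigned to its own module.

## EM structure learning

The M-step relearns each module's regulation tree by greedy recursion: at
every node each eligible modulator is evaluated at its fitted threshold and
at all distinct midpoints of its within-node sorted expression; a split is
accepted only if the summed member-gene gain exceeds the penalty (default:
ln of the number of candidate modulator–split pairs evaluated at that node,
a multiple-testing-style complexity charge; `split_penalty` overrides).
Children need ≥ `min_leaf_size` (5) samples; depth is capped at
`max_tree_depth` (3). Modulators that are members of a module are excluded
from that module's splits, so a gene can never explain itself.

The E-step visits genes in a seeded random order and moves each to the
module whose fixed tree scores it best (ties keep the current module,
otherwise the lowest module id; a modulator may not enter a module whose
tree currently splits on it). Moves are applied immediately; since trees
are fixed and moves are only taken on strict improvement, the total log
score is non-decreasing across every E-step — the suite asserts this
exactly, with `math.fsum` totals. Iteration stops when the reassigned
fraction drops below `em_reassign_tol` (0.10) or after `em_max_iter` (50)
iterations. A parameters-only M-step mode (`mstep_structure=False`) keeps
tree shapes and refreshes leaf statistics.

## Ensemble and driver derivation

With trees held fixed in the E-step, gene moves are independent of visit
order, and the k-means initialization is deterministic — repeated runs on
identical data are identical. Run-to-run diversity therefore comes from
bootstrap resampling of the learning samples (stability selection), the
package's deliberate design choice; `ensemble_resample=False` restores
deterministic repeats. Run r of n uses seed master_seed + r. A modulator
"appears" in a run when it is used by at least one accepted split of the
final network; fre_app ≥ 0.40 (inclusive) survives, and one final
non-resampled run restricted to the survivors defines the candidate
drivers. Specificity is the set difference against the union of all other
subtypes' candidates; novelty requires the focal aberration frequency to
exceed *every* other subtype's by strictly more than 0.2 (the stricter
reading of the frequency rule; the alternative "any" reading would flag
genes that merely differ from one subtype) and absence from the optional
known-driver list. No driver database is downloaded.

## Validation

Driver sets are validated as classification features: stratified 10-fold
CV, linear-kernel SVM with C = 1.0 (logged in the run metadata), focal
subtype positive, confusion counts pooled across folds (micro) before
computing accuracy, precision, recall and F; zero-denominator precision or
recall is 0.

## Synthetic benchmark: what it shows and what it does not

The generator plants, per subtype, modulators aberrant in an exact 80% of
that subtype's samples (alternating amplification/deletion; expression
shifted ±2.0 with σ = 0.5 noise), disjoint 30-gene target blocks shifted
+2.0 whenever their modulator is on the aberrant side of its generating
threshold, one copy-number-aberrant but expression-inert decoy per subtype,
and 300 pure-noise background genes; copy-number noise is σ = 0.1 so
spurious calls are ~0.3%. Effects are Gaussian mean shifts — exactly the
structure Normal-Gamma leaf scoring represents — so recovery there shows
the machinery is correct, not that the method conquers real tumor data:
batch effects, tumor purity, segmentation artifacts, non-Gaussian
expression and overlapping regulatory programs are all absent. The
default problem sizes (200 permutations and 20 ensemble runs in the
benchmark and acceptance script; 1000 permutations and 100 runs in the
`Config` defaults used for real analyses) were chosen so the whole
benchmark runs comfortably on a single CPU.

## Known limitations

- The median-based permutation FDR has no finite-sample control guarantee;
  its selection behavior depends on the grid top T reaching the signal
  range (see above).
- Hard EM converges to a local optimum dependent on the initial
  assignment; the ensemble mitigates but does not eliminate this.
- Modules are regulated by expression thresholds of single genes;
  combinatorial or dosage-linear regulation is only approximated by tree
  depth.
- Aberration calls at fixed ±0.3 take the input log2 ratios at face value;
  no purity or ploidy correction is attempted.
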