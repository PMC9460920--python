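# Methods

This note documents the statistical procedures implemented in `gseacmap`,
the choices made where the underlying methods leave latitude, and what the
synthetic-data generator does and does not emulate.

## Overview

The pipeline predicts the bioactivities of a complex perturbagen (the
motivating case is a multi-component plant-root extract applied to cultured
cells) from the transcriptome changes it induces, without prior knowledge of
its pharmacology. It chains four stages:

1. **Differential expression** on a treated-vs-control count matrix:
   TMM scaling → log2-CPM → empirical-Bayes moderated t → Benjamini–Hochberg,
   with genes called at fold change > 2 and FDR < 0.05.
2. **Preranked GSEA** of the full fold-change ranking against a small
   hallmark-style gene-set collection (p < 0.05, FDR q < 0.25).
3. **Connectivity-map scoring**: the up/down DEG tag sets are compared with
   every instance of a compound-signature reference using the two-tailed
   Kolmogorov–Smirnov connectivity statistic; scores are scaled to ±100 and
   hit compounds taken from the [95, 100] window (top 10).
4. **Integration**: each hit compound's signature is itself pathway-analysed;
   a mechanism-of-action (MOA) class's pathway set is what a majority of its
   hits share; the final prediction is the intersection of all class sets
   with the experiment's own enriched pathways. Agreement between the two
   independent routes (direct enrichment vs. drug-mimicry) is the source of
   confidence; direction conflicts are flagged as compensatory candidates
   rather than resolved.

## Differential expression

**TMM factors.** For sample *j* against a reference sample *r* (default:
the sample whose upper-quartile CPM is closest to the mean upper-quartile),
using genes with nonzero counts in both:
M_g = log2((c_gj/N_j)/(c_gr/N_r)), A_g = ½·log2((c_gj/N_j)(c_gr/N_r)),
weights w_g = (1/c_gj − 1/N_j + 1/c_gr − 1/N_r)⁻¹ (inverse delta-method
variance). The 30% tails of M and the 5% tails of A are trimmed by rank;
the factor is 2^(Σw·M/Σw) over the kept genes, and factors are rescaled to
geometric mean 1. Fewer than 10 usable genes triggers a factor-1 fallback
with a warning record. Trim fractions are the method's conventional
defaults. The exact-scale-invariance property holds for M and A; the
weights retain a weak depth dependence, so invariance under multiplying a
sample by a constant is near-exact rather than bitwise (the test allows
2% at counts ≥ 200).

**log-CPM.** x_gs = log2((c_gs + 0.5)/(L_s + 1)·10⁶) with effective library
size L_s = (column sum)·f_s. Default mode is *unweighted* log-CPM feeding
the EB step (limma-trend-style, with no trend term): it is fully
specifiable and adequate for the replicate counts simulated here.
Mean–variance precision weights (a lowess trend of √(residual sd) against
average log-count, span 0.5, weights = trend⁻⁴ at each observation's fitted
log-count) are available behind `use_voom_weights` but are not the default.

**Moderated t.** Per gene, the two-group fit gives logFC (treated −
control) and residual variance s²_g with d_g = n − 2 df. Hyperparameters
(d₀, s₀²) are estimated by moment-matching log s²_g to a scaled-F model:
with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), excess variance
var(e) − ψ′(d_g/2) equals ψ′(d₀/2) (solved by Newton iteration to
|Δ| < 10⁻⁸), and s₀² follows from mean(e). Non-positive excess variance
gives d₀ = ∞ (pure pooling, normal reference distribution). The posterior
variance s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g) yields
t = logFC/√(s̃²(1/n₁ + 1/n₂)) with d₀ + d_g df. The implementation is
cross-checked in the test suite against a straight-line reimplementation
(10⁻¹⁰) and against limma's `eBayes` via Rscript (10⁻⁶).

**Filter.** Strict inequalities: status "up" requires log2FC > 1 *and*
fdr < 0.05 (a gene at exactly two-fold stays "ns"); "down" symmetric.
logFC is the difference of group-mean log-CPM, not a count ratio.

## Preranked GSEA

Genes are ranked by signed log2FC, descending; ties break by smaller p,
then lexicographic id, with the tie count recorded. For a set with N_h
in-universe members (retained when 5 ≤ N_h ≤ 500), the running sum gains
|r_i|^p/Σ_hits|r_j|^p at members and loses 1/(N − N_h) elsewhere; ES is the
signed maximal deviation (positive preferred on an exact magnitude tie —
consequently list reversal negates ES except at such ties). Exponent
p = 1 by default; p = 0 recovers the classic Kolmogorov–Smirnov form. An
all-zero-score set degenerates to equal hit weights.

The null uses gene-label permutation (the two-arm design has too few
samples for phenotype permutation): 1000 shared label permutations per
run — sharing one permutation across sets preserves inter-set correlation
in the pooled null. One-sided p on the observed sign is
(1 + #exceedances)/(1 + n_perm). NES divides ES by the mean |null ES| of
matching sign; sets with fewer than 10 matching-sign draws are flagged
unstable, and an empty matching-sign null leaves NES/q undefined and the
set outside the FDR pool. FDR q is the GSEA ratio-of-tails on the pooled
sign-normalised null, clipped to [0, 1]. "Enriched" means p < 0.05 and
q < 0.25.

## Connectivity scoring

Each reference instance is converted to a dense ranking (1 = highest
z-score; ties broken by gene order so every column is a permutation). For
a tag set of t genes with sorted positions V(j) in N genes:
a = max_j(j/t − V(j)/N), b = max_j(V(j)/N − (j−1)/t), ks = a if a > b else
−b. The instance's raw score is s = ks_up − ks_down when the two statistics
disagree in sign, else 0; scaled score c = 100·s/max_i|s_i|, so the best
match attains ±100 and scores depend only on rank order (scale-invariant).
Tag sets are unordered (no t-statistic weighting). Compound-level score is
the best instance (median kept for diagnostics). Hits: compounds with
c ∈ [95, 100] (both ends inclusive), descending, at most 10. The scaling
convention reproduces the published 0–100 selection semantics without
committing to any particular public scoring service; the window is
configurable. Query genes absent from the reference universe are dropped
with a logged count.

## Integration

Each hit compound's best-instance signature becomes a ranked list over the
reference universe and is analysed with the same preranked GSEA (same
thresholds); a hypergeometric over-representation mode on the top/bottom
150 genes (BH at 0.05) is available as a flag. A class's pathway set keeps
pathways enriched in ≥ `class_fraction` (default 0.5 — a majority rule is
the weakest defensible formalisation of "commonly found", and it is
configurable) of its hit compounds, with majority direction (ties → up).
Classes with zero hits are dropped with a notice. The report contains all
2^k Venn regions over {extract} ∪ classes, so both the "all classes" and
"any two classes" readings can be inspected; `predicted` is the total
intersection. Raising `class_fraction` never enlarges a class set; raising
the GSEA q cutoff never shrinks the predicted set. Each predicted pathway
carries the extract's direction; if the majority class direction disagrees,
the pathway is flagged `compensatory-candidate` — transcriptional induction
can mask a functionally opposite effect, so flagged calls need orthogonal
validation.

## Synthetic data

The generator supplies the three inputs with a single planted truth derived
deterministically from the seed, so the generators can be called
independently and still agree.

* **Counts**: negative binomial with variance μ + φμ² and constant
  dispersion φ = 0.1 (a typical cell-line value; the simplest model
  adequate for testing). Base means are log-normal (meanlog 5, sdlog 1 —
  median ≈ 150 counts, spanning tens to thousands, realistic for a
  moderately deep bulk library over a 2000-gene universe); per-sample
  library factors are uniform in [0.5, 2]; n = 3 replicates per arm (a
  typical design; the emulated study does not state its count). 5% of
  genes get ±2 log2 units (half up, half down) in the treated arm.
* **Gene sets**: 50 sets of 15–200 genes. Four "affected" sets partition
  the planted DE genes (up-genes into up-sets, down into down-sets, so each
  affected set has a coherent direction); unaffected sets are drawn only
  from signal-free genes, so they are null by construction (overlap among
  them allowed).
* **Reference**: 15 compounds round-robin over 3 MOA classes, 2 instances
  each (30 columns). An instance's z-vector is the sum of its class's
  planted programs (members get ±3 z-units; each class has 2 exclusive
  programs plus 1 shared program that is also an extract-affected set) plus
  N(0, 1) noise. Instances of the designated *matched* class additionally
  receive the extract's planted DE direction, making connectivity
  self-recovery testable. z-scores are stored; ranks are derived downstream.

What this does **not** emulate: gene-specific dispersion or
mean–dispersion trends, GC/length biases, batch effects, correlated genes
within sets beyond the planted programs, realistic pathway overlap
structure, multiple cell lines per compound, or dose/time series in the
reference. Passing tests therefore demonstrate correctness and calibration
of the algorithms under a clean generative model, not robustness to every
artefact of real RNA-seq or of a real perturbation database.

A separate generator (`synthetic_supplement_degs`) emulates a published-style
supplementary DEG table — 601 up and 730 down among ~12k genes, including
genes that fail exactly one of the two filters — as a synthetic stand-in
used to exercise the fold-change/FDR filter; its q-values are computed by
BH over the whole table so the filter outcome is seed-independent.

## Numerical choices and degenerate inputs

* Trigamma inversion: Newton with |step| < 10⁻⁸, asymptotic branches for
  extreme arguments.
* BH: vectorised step-up with stable sort; exact ties handled by rank.
* ES tie-break: positive deviation preferred on exact |max| = |min|.
* Reference ranks: stable argsort, ties by gene order.
* Connectivity with all s = 0: all scaled scores 0 (no division by 0).
* Single-gene DE input: d₀ = ∞ with a warning; all-zero residual variances
  reject. Empty query tails, empty references, whole-universe gene sets and
  empty restricted sets reject with explicit messages.
* Determinism: every stochastic step draws from a generator seeded via
  `SeedSequence([seed, stage])`; a fixed seed gives byte-identical reports.

## Problem sizes

Tests and the acceptance script run the study conditions at their natural
size (2000 genes, 50 sets, 3×5 compounds × 2 instances) with 10–20
replicate seeds for the calibration and recovery rates; unit tests use
smaller instances (N ≤ 50 for oracle sweeps, 500–800 genes for scenario
fixtures) chosen to keep the full suite under a minute of compute per
module. One full pipeline run at the default sizes takes ~1.5 s on one CPU.

## Known limitations

* The moderated model assumes a common variance prior across genes; with a
  strong mean–variance trend the unweighted default is slightly
  conservative at low counts (the optional precision weights address this).
* NES/FDR at 1000 permutations has Monte-Carlo noise of a few percent;
  p-values are floored at 1/(n_perm + 1).
* The connectivity scaling is query-relative: scores are comparable within
  one query, not across queries.
* Gene identifiers are exact strings; no alias mapping or cross-species
  translation is attempted.
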