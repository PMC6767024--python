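# Methods

## Study design assumed

Four genotypes — two parents (parent1, parent2) and two F1 hybrids
(hybrid1, hybrid2) — each with at least two biological replicates (the
canonical design has three). Expression values are non-negative FPKM-like
quantities; volatile concentrations are ng per g of sample. Everything
below operates on this 4 × r layout.

## Volatile quantification and heterosis indices

Compound concentrations are semi-quantified against a single internal
standard: conc(ng/g) = (A_target / A_IS) × m_IS(µg) × 1000 / m_sample(g).
The default internal-standard mass is 1.5 µg (a 15 µL spike of a 100 ppm
ethyl decanoate solution) and the default sample mass 5 g; both are
parameters because spike volumes differ between laboratories.

Trait values are class totals: the sum over compounds of per-genotype mean
concentrations. Heterosis is then

- MPV (%) = (F1 − MP)/MP × 100 with MP = (P1 + P2)/2,
- OPV (%) = (F1 − HP)/HP × 100 with HP = max(P1, P2).

Since (F1 − x)/x is decreasing in x and HP ≥ MP, MPV ≥ OPV for positive
traits. Indices operate on trait means; replicate SDs are reported
alongside but not propagated into the percentages.

Significance letters use the insert-and-absorb compact-letter-display
algorithm on the pairwise two-sided Welch t-test matrix: start from one
letter covering all groups; for each significant pair split every letter
set containing both, then absorb subsets. Letters are ordered by
descending group mean so the highest group is always "a". Raw p < alpha by
default (matching how such tables are usually annotated); a Bonferroni
flag divides alpha by the number of pairs. Groups with zero variance on
both sides are called different iff their means differ.

## Expression-level dominance classification

Per gene, all six genotype pairs are compared with a two-sided Welch
t-test on log2(x + c), pseudocount c = 0.1 (configurable) to admit zeros.
"A higher than B" requires p < alpha (default 0.05) **and** a pseudocounted
mean ratio ≥ fc_min (default 2). An optional q-value mode BH-adjusts each
pair's p-vector across genes before thresholding. The test is deliberately
pluggable: `pairwise_call` accepts an externally computed p-value so a
count-based differential test can replace the Welch t without touching the
decision logic.

Degenerate cases: if both groups have zero variance in log space, p is 0
when the means differ and 1 when they agree — this makes noise-free
matrices behave like their mean orderings. Two all-zero groups are
"similar" with p = 1.

The decision tree over the six calls, in order: (1) both hybrids higher
than both parents → C9 (up-overdominance); (2) both lower → C10; (3)
parents differ, hybrids similar to the high parent and higher than the low
parent → C5/C6 (higher-parent dominance; C5 when parent1 is the high
parent); (4) the mirror at the low parent → C7/C8 (lower-parent
dominance); (5) parents differ and both hybrids strictly between → additive
C1–C4, split by which parent is high and whether the two hybrids are
statistically equal (C1: parent1 high, hybrids unequal; C2: parent1 high,
hybrids equal; C3/C4 mirrors); (6) otherwise unclassified. Modes are
defined jointly over both hybrids, so conflicting hybrids (one
overdominant, one additive) fall to unclassified by construction.

Summaries report fractions on three denominators — all genes, classified
(C1–C10) genes, and non-additive (C5–C10) genes — because each answers a
different question and published analyses mix them.

qPCR support is the standard 2^−ΔΔCt relative quantification:
ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_calibrator.

## SOM co-expression modules

Input profiles are per-gene genotype means (4 dimensions), z-scored per
gene so modules capture pattern shape, not magnitude. The map is a small
rows × cols grid (default 2 × 4 = 8 units, matching the eight-module
screening design) trained with the **batch** SOM algorithm for
determinism: each epoch assigns every gene to its best-matching unit
(BMU), then sets every unit to the Gaussian-neighborhood-weighted mean of
all genes, weights exp(−d²/2σ²) on squared grid distance.

Numerical choices: the codebook is initialised by farthest-first traversal
of the input profiles from a seed-chosen random start — on well-separated
clusters this avoids dead or merged units that plain random sampling
produces. The neighborhood radius decays linearly from σ₀ = 0.75 unit
spacings to a floor of 0.1 over the epochs (default 20). The small σ₀
performs gentle topological ordering without collapsing the spread
initialisation; for much larger maps users should raise it toward
max(rows, cols)/2. BMU ties break to the lowest flat unit index
(row-major), making assignment deterministic.

TF screening is set intersection: the TFs (an input id list — TF
annotation is upstream of this package) assigned to the same unit as an
anchor gene. Pearson correlations between gene profiles use
t = r√(n−2)/√(1−r²) with n−2 df for exact two-sided p-values at the tiny
n (= 4 genotype means) involved; |r| = 1 maps to p = 0.

## Over-representation analysis

One-sided hypergeometric upper tail P(X ≥ k) for the overlap k between the
query set and each term, over an explicit background universe; BH step-up
FDR across all tested terms. "Gene ratio" is reported as the integer
overlap count. Terms smaller than `min_term_size` (default 2) are skipped
to avoid degenerate tails; query genes outside the background are dropped
with a logged count. The test choice is the standard ORA formulation;
a two-sided variant was considered unnecessary because depletion is not of
interest in this screening context.

## Synthetic data generator

The generator emulates the study conditions: a 4-genotype × 3-replicate
matrix with genes planted into the ten modes. Group means sit on a
geometric ladder with common ratio `effect_fold` (default 4): e.g. C9 puts
both hybrids at baseline × fold with parents at baseline; C1 uses four
rungs b·f³ > b·f² > b·f > b so every adjacent pair is f apart. Baseline is
10 (FPKM-like). Replicates are mean-preserving log-normal draws at a given
coefficient of variation (default 0.05): X = m·exp(N(−σ²/2, σ²)),
σ² = ln(1+cv²) — positive, right-skewed, exact means at cv → 0. Default
class proportions put ~74% of genes in "none" (no planted effect) with
dominance outweighing additivity and overdominance rarest, mirroring the
reported mixture shape. Gene counts per class use largest-remainder
apportionment so stated proportions are met exactly. All draws flow from
one `numpy` generator seeded once.

The volatile generator produces one synthetic compound per class from
stated (p1, p2, h1, h2) class totals, so class sums at cv → 0 equal the
stated totals exactly.

What the generator does **not** emulate: count-based mean–variance
relationships (no length/library-size effects), correlated genes, batch
effects, dropout, or compound-level covariance within a volatile class.
Recovery results on synthetic data therefore demonstrate correctness of
the decision logic under the stated noise model, not performance on real
RNA-seq, where a count-based test plugged into `pairwise_call` is the
appropriate route.

## Problem sizes used in validation

Classifier recovery is checked on 2000-gene matrices over 10 seeds
(3 replicates, 4-fold effects, 5% CV); SOM module purity on 8 planted
prototypes × 30 genes; hypergeometric tails are enumerated exhaustively
for backgrounds up to 60. These sizes exercise every code path while
keeping the suite fast.

## Known limitations

- The Welch t on 3-replicate log FPKM is underpowered relative to
  count-based models; the q-value mode is conservative at small n.
- The C1–C4 sub-split (which parent is high; hybrids equal or not) is one
  reasonable enumeration of the additive sub-modes; category-level results
  are insensitive to it.
- The SOM's module count is the grid size; it is a screening device, not a
  model-selection procedure.
- Letter displays from raw pairwise p-values do not control family-wise
  error; use the Bonferroni flag when that matters.
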