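# teaheterosis

Analysis toolkit for **volatile heterosis** in two-parent / two-hybrid (F1)
plant designs, built around the tea plant (*Camellia sinensis*) use case:
two parental cultivars and two F1 hybrid cultivars, each with replicated
GC-MS volatile measurements and a replicated bulk RNA-seq expression matrix
(FPKM-like units).

It is aimed at plant breeders and transcriptomics analysts who want to ask,
for a hybrid cross: *how strong is the hybrid-vigour signal in the
phenotype, and which genes express non-additively in the hybrids?*

## What it computes

**Heterosis indices.** For a trait with hybrid value F1 and parental values
P1, P2:

    MPV (%) = (F1 − MP) / MP × 100,   MP = (P1 + P2) / 2
    OPV (%) = (F1 − HP) / HP × 100,   HP = max(P1, P2)

MPV is mid-parent heterosis, OPV over-high-parent heterosis (MPV ≥ OPV for
positive traits). Volatile traits are class totals (green leaf volatiles,
monoterpenes, sesquiterpenes) of compound concentrations semi-quantified
against an internal standard: conc = (A_target / A_IS) × m_IS / m_sample.
Group differences are annotated with a compact letter display from pairwise
Welch t-tests.

**Expression-level dominance.** Each gene's four genotype groups (parent1,
parent2, hybrid1, hybrid2) are compared pairwise — "A > B" means a
two-sided Welch t-test on log2(x + 0.1) with p < 0.05 **and** fold change
≥ 2 — and the gene is assigned to one of ten modes: C1–C4 additive (hybrids
between the parents), C5–C6 higher-parent dominance, C7–C8 lower-parent
dominance, C9/C10 up-/down-regulated overdominance, or unclassified.
Summaries report additive vs non-additive fractions.

**Co-expression screening.** F1-upregulated genes (C5, C6, C9) are
clustered on a small batch-trained self-organizing map (default 2×4 grid =
8 modules) of z-scored genotype-mean profiles; transcription factors
sharing a module with an anchor pathway gene are co-regulation candidates.
Pearson correlations over the four genotype means carry exact small-n
p-values (t transform, n − 2 df).

**Over-representation analysis.** One-sided hypergeometric tests of a gene
set against user-supplied GMT term maps, with Benjamini–Hochberg FDR.

**Synthetic data.** A generator plants genes into the ten modes at chosen
proportions with log-normal replicate noise, so every stage can be
validated against known ground truth.

## Worked example

```python
from teaheterosis import (SimulationConfig, generate_expression,
                          classify_matrix, summarize_patterns,
                          mid_parent_heterosis, over_high_parent_heterosis)

# Heterosis of the HGY hybrid's monoterpene total (ng/g):
# F1 = 1500.79, parents 766.43 (TGY) and 916.7 (HD)
print(round(mid_parent_heterosis(1500.79, 766.43, 916.7), 1))        # 78.3
print(round(over_high_parent_heterosis(1500.79, 766.43, 916.7), 1))  # 63.7

# Classify a synthetic 2000-gene matrix with known planted modes
lab = generate_expression(SimulationConfig(n_genes=2000, seed=7))
summary = summarize_patterns(classify_matrix(lab.matrix))
print(summary.to_dict()["category_counts"])
# {'additive': 80, 'higher-parent dominance': 182,
#  'lower-parent dominance': 112, 'up-overdominance': 76,
#  'down-overdominance': 62, 'unclassified': 1488}
print(round(summary.fraction_of_non_additive("higher-parent dominance"), 3))
# 0.421
```

The monoterpene MPV of 78.3% says the hybrid's monoterpene total exceeds
the parental average by 78%; the OPV of 63.7% says it exceeds even the
better parent by 64% — strong over-parent vigour. In the synthetic matrix
the classifier recovers the planted mixture: most genes are unchanged
("unclassified"), and among non-additive genes higher-parent dominance is
the largest category (42.1% here).

A CLI mirrors the library: `teaheterosis simulate|volatiles|classify|som|
enrich|qpcr|run` (see `teaheterosis --help`).

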