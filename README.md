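# tcscensus

Census and gene-neighborhood statistics for **two-component-system (TCS)
and phosphorelay (PR) signaling proteins** in annotated genomes.

TCS/PR cascades transduce signals through three internal-signal-transduction
(IST) domain families: the histidine kinase domain (**HK**, autophosphorylates
a conserved His), the response regulator domain (**RR**, receives phosphate on
a conserved Asp), and the histidine phosphotransfer domain (**HPt**). These
domains combine into single proteins in many ways — the single-domain HK and
RR types, the hybrid kinase HKRR, the tripartite HKRRHPt, and dozens of rarer
architectures — and the genes encoding them cluster into operons far more
often than chance predicts. This package is for comparative genomicists who
want to quantify both phenomena: how IST domains organize into proteins
(the census) and how the corresponding genes organize along the chromosome
(the neighborhood analysis).

## What it computes

**Architecture classification.** An ordered N→C domain list maps to a
canonical type string: `[HK, RR, HK]` → `HK1RRHK2` (instances of a type
occurring k ≥ 2 times are numbered in order; singletons are unnumbered).
Upstream of classification there are curation tools for homology-search hit
tables (keep hits with e-value < 10⁻⁶ and domain coverage ≥ 80%), a merge of
the four search sources into a non-redundant set, an iterative
annotation-curation loop, a majority-residue consensus from a multiple
alignment, and a conserved His/Asp motif check.

**Cluster (operon) detection.** A cluster is a maximal run of IST genes in
consecutive genomic positions, tolerating one intervening non-IST gene
("gap"). Cluster types are labelled by member architectures in genomic order
(`HK-RR`, `HK-RR-RR`, ...).

**Neighborhood statistics.** For a genome with P proteins, n_RR single-RR
and n_HK single-HK proteins, the expected frequency of neighboring events
under fully random gene order is, for the six canonical patterns,

    F(HK↔RR)         = n_RR/(P−1) + n_RR/(P−2)
    F(HK↔RR↔HK2)     = 6 · n_HK/(P−1) · n_RR/(P−2)
    F(HK↔RR↔HK2↔RR2) = 12 · n_RR/(P−1) · (n_HK−1)/(P−2) · (n_RR−1)/(P−3)
    F(HKRR↔HK↔RR)    = 6 · n_HK/(P−1) · n_RR/(P−2)
    F(HKRRHPt↔RR)    = n_RR/(P−1) + n_RR/(P−2)
    F(HKRRHK↔RR)     = n_RR/(P−1) + n_RR/(P−2)

and the enrichment of the observed anchor-gene neighboring fraction is the
odds ratio observed/F. A seeded permutation Monte-Carlo null reproduces F
empirically, edge effects included.

**Fusion regressions.** Ordinary least squares of the percentage of "fused"
domains (instances living in multi-domain proteins) against the total domain
count, and of the total IST-domain count against proteome size plus a
phylogeny covariate (1 = prokaryote, 2 = eukaryote), with per-coefficient
ANOVA significance, R² and adjusted R².

**Synthetic genomes.** A seeded generator plants protein types, operons
(optionally gapped) and fusion trends with known ground truth, so every
stage has a parameter-recovery test without any external data.

## Worked example

```python
from tcscensus import *

config = SimulationConfig(
    genes_per_organism=2000,
    protein_type_counts={"HK": 20, "RR": 20, "HKRR": 3},
    operons=[OperonSpec("HK-RR", 10, gap_probability=0.3)],
    seed=42,
)
genes, truth = simulate_genome(config)

c = census_organism(genes, total_proteins=2000)
print(c.type_counts, c.pct_tcs_pr)          # {'HK': 20, 'RR': 20, 'HKRR': 3} 2.15
print(round(orphan_fraction(genes), 3))      # 0.628

print(cluster_type_catalog(detect_clusters(genes)))
# {'HK-RR': 9, 'HK-HK': 1, 'RR-HK-RR': 1}

stat = neighborhood_stat(genes, "HK-RR",
                         {"n_HK": c.n_hk_single, "n_RR": c.n_rr_single}, P=2000)
print(f"{stat.observed:.3f} {stat.expected:.5f} {stat.odds_ratio:.1f}")
# 0.400 0.02002 20.0

mean, se = permutation_null(genes, "HK-RR", n_permutations=500, seed=42)
print(f"{mean:.5f} ± {se:.5f}")              # 0.01890 ± 0.00132
```

Reading the output: of the 2,000 simulated genes, 43 encode TCS/PR proteins
(2.15% of the proteome, the 1–2% range typical of prokaryotes). Ten HK–RR
operons were planted; nine are recovered as `HK-RR` clusters (one planted
pair happened to land next to a background RR gene and is called as the
three-member `RR-HK-RR`). 40% of single-HK genes sit strictly adjacent to a
single-RR gene, against a random expectation of 2% — a 20-fold enrichment,
squarely in the 10–100× range real prokaryotic genomes show. The permutation
null (0.0189 ± 0.0013) agrees with the closed-form expectation 0.0200.

A fusion-series fit recovers its planted trend:

```python
fit = fit_fusion_model(simulate_fusion_series(SimulationConfig(n_organisms=200, seed=42)))
print(f"{fit.slope:.3f} ({fit.slope_ci[0]:.3f}, {fit.slope_ci[1]:.3f}) R²={fit.r_squared:.3f}")
# 0.314 (0.298, 0.330) R²=0.887
```

The planted slope 0.31 (percentage points of fused HK per additional HK
protein) lies inside the 95% CI.

The same stages are available as shell commands
(`tcscensus simulate|classify|census|clusters|neighborhood|fusion`), each a
thin wrapper over the functions above; see `tcscensus --help`.

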