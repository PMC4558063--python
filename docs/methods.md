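# Methods

## Coordinate model

Genes are addressed by 1-based ordinal rank within a replicon — gene order,
not base pairs — because every statistic here reasons about *consecutive
positions* only. Replicons are linear: the first and last gene each have a
single neighbor, and no cluster or neighborhood spans two replicons (each
plasmid or chromosome is treated independently). Strand is ignored
throughout; no rule in the pipeline conditions on it, and cluster labels are
therefore *not* canonicalized for reverse complementarity — `HK-RR` and
`RR-HK` are distinct cluster types.

## Architecture classification

A protein's architecture is its ordered N→C list of IST domains (HK, RR,
HPt). The canonical name concatenates the domains; when a type occurs k ≥ 2
times its instances are numbered 1..k in order of occurrence, and
singletons stay unnumbered (`HKRR`, `HK1RRHK2`, `HKRRHPt1HPt2HPt3`).
`parse_architecture` enforces exact canonical form: any string that does
not round-trip through `classify_architecture` is rejected, which catches
misnumbered or reordered indices.

## Hit curation

Homology hits are kept when e-value < 10⁻⁶ (strict, so a hit exactly at the
threshold is rejected) and domain coverage ≥ 0.80 (inclusive). Coverage is
consumed as a precomputed input column; how it was derived is up to the
search tool. Four hit sources (profile-HMM, PSI-BLAST vs alignment,
PSI-BLAST vs consensus sequence, annotation text-mining) merge into a
non-redundant set keyed by (protein, domain); when sources disagree the
highest-coverage record wins and the conflict is logged.

The annotation-curation loop repeatedly discards proteins whose free-text
annotation matches an exclusion term (e.g. "serine kinase") and contains no
inclusion term ("histidine kinase", "response regulator", "hybrid
kinase", ...), until the kept set is stable. The kept-set size is
non-increasing, so the loop reaches its fixed point in at most as many
rounds as there are proteins; with a membership rule that depends only on
each annotation it converges in one round, but the loop structure is kept
so rules that inspect the surviving set can be added without changing the
contract.

Consensus sequences take the most frequent non-gap residue per column; ties
break to the alphabetically first one-letter code (a deterministic,
documented choice — the data itself gives no preference), and an all-gap
column emits `X`. The motif-conservation check locates the column with the
highest frequency of the motif residue (H for HK/HPt, D for RR; earliest
column on ties) and flags sequences lacking that residue there. Proteins
annotated as hypothetical/partial carry a boolean flag so analyses can run
with and without them.

## Census

For the closed-form neighboring expectations, `n_HK` and `n_RR` count
proteins whose architecture is *exactly* one HK (resp. RR) domain; hybrids
are counted under their own types. Reported percentages and per-organism
averages are rounded half-up to two decimals. An orphan IST gene is one
with no IST gene at position ±1 — strict adjacency, deliberately
independent of the gap-tolerant cluster rule. Phylum presence tables emit
both an "HK or RR" and an "HK and RR" variant of the presence percentage,
with the "or" variant as the headline metric, because published phylum
tables are ambiguous between the two readings.

## Clusters and neighborhoods

A cluster is a maximal run of IST genes in which consecutive members are
separated by at most one non-IST gene (`max_gap=1` by default). Isolated
IST genes are orphans; every IST gene lands in exactly one cluster or the
orphan set, and a cluster of m members spans at most 2m−1 positions. The
gap allowance can merge two adjacent independent operons into one call — a
small, known error inherited from the cluster definition itself.

Neighborhood patterns use *strict* adjacency — a gap gene never satisfies a
pattern. Each pattern has an anchor type (its first-named type) and
companion types; the anchor matches when it lies inside a contiguous window
whose other members are exactly the companions, in any order. An anchor
with matching neighbors on both sides counts once (the question is "does
this gene neighbor an RR gene", not "how many"). The expectations

* pair: `n_RR/(P−1) + n_RR/(P−2)`
* triple: `6 · n_HK/(P−1) · n_RR/(P−2)`
* quadruple: `12 · n_RR/(P−1) · (n_HK−1)/(P−2) · (n_RR−1)/(P−3)`

are first-order approximations valid for interior positions and sparse
counts (IST counts a few percent of P at most). The multiplicity factors 6
and 12 are the distinct orderings of the three- and four-gene series (the
two RR genes of the quadruple being indistinguishable);
`arrangement_multiplicity` computes them by brute-force enumeration so the
multinomial formula can be property-tested against it.
`expected_frequency` raises rather than clamps when the formula exceeds 1.
For the `HKRRHPt↔RR` and `HKRRHK↔RR` patterns an RR neighbor on either
side counts (the one-sided alternative is not distinguished).

The permutation null shuffles gene order uniformly within each replicon
(contents preserved) and recomputes the observed fraction per permutation;
since only IST positions matter to the patterns, the implementation
re-places the IST genes on a uniform random set of positions, which is
distributionally identical and much faster. The null's mean agrees with the
closed-form F within Monte-Carlo error — including the edge effects the
formulas ignore — and serves as their independent check. Enrichment is the
odds ratio observed/F, flagged undefined when F = 0 or there are no
anchors.

## Fusion and scaling regressions

A domain instance is "fused" when its protein carries ≥ 2 IST domains;
counting is at the instance level (each HK inside an HKRR is one fused HK).
An alternative protein-level x-variable can be had by passing a different
column to the fit. The fusion model is OLS of % fused vs total count with
a two-sided slope t-test; organisms with zero instances of the type are
dropped (undefined percentage). A constant response with zero residual
variance makes the t statistic 0/0; the fit reports p = 1 there (no
evidence against a zero slope). The IST-count model regresses total IST
domains on proteome size and a phylogeny covariate kept as the literal
coding 1 (prokaryote) / 2 (eukaryote) — note the intercept is therefore
not at zero covariates. Per-coefficient significance uses
single-restriction ANOVA F-tests (identical to squared t-tests). When the
phylogeny term is significant the dataset can be split and refit per
stratum (`fit_ist_model_stratified`), reporting per-stratum R². Classical
OLS inference only; no robust errors.

## Synthetic data

The generator's placement model: operon blocks (with any gap genes already
inserted) and background IST singles are shuffled uniformly among filler
genes, so requested per-type totals are met *exactly* and, with no operons,
gene order is fully random — the null of the closed-form expectations.
Per-type counts are totals; operon members draw from them. With
`gap_probability` p each planted operon independently receives one non-IST
gene at a uniformly chosen interior junction. Defaults emulate a mid-sized
prokaryotic genome: 2,000 genes, IST counts of tens (about 1–2% of the
proteome), odds-ratio enrichment in the 10–100× range when half the HK
genes are planted into operons.

Fusion series use `% fused = intercept + slope·x + N(0, sd)` truncated to
[0, 100]; truncation biases recovery when the line leaves the physical
range (real fitted intercepts can be negative), which is accepted and
tested away from the boundary. Defaults (intercept 14, slope 0.31, sd 3,
totals 5–100, n = 200) put the data well inside the range. Simulated
alignments corrupt exactly `round(rate·n_rows)` rows at the motif column
with `Y` (alphabetically after H and D, so consensus recovery holds for
rates ≤ 0.5).

One global seed feeds named, independent RNG streams (genome, fusion,
alignment; per-organism sub-streams for genomes), so identical seed and
configuration give byte-identical output and any stage can be regenerated
alone.

What passing tests on these genomes does **not** show: robustness to
annotation noise, unequal replicon structure, phylogenetic correlation
among organisms, or realistic sequence-level variation — the generator
plants clean domain labels, not sequences.

## Problem sizes

The simulation-based checks run at desk scale, chosen to keep the full
suite under a few minutes while leaving the statistics well-powered:
Monte-Carlo validation of the expectations at P = 2,000 with 200–400
permutations (pair patterns at n = 20, triple/quadruple at n = 40, the
0.02·P sparsity bound of the approximation); planted-operon recovery over
50 seeded genomes; regression CI coverage over 500 replicates; type-I error
calibration over 2,000 datasets of n = 50.
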