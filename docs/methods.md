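# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the design choices made where a published
convention does not pin one down.

## Study design and data model

The pipeline assumes the sampling design of a longitudinal two-cub /
two-parent gut-microbiome survey: 33 samples in five groups (C0: 5 cub
samples at 0–1.5 months, C1: 9 at 1.5–6 months, C2: 8 at 6–9 months,
F: 5 father samples, M: 6 mother samples). Its unit of observation is a
non-redundant gene catalog: each gene carries a four-rank lineage
(phylum, family, genus, species; `Unclassified` allowed, with the
constraint that a named species implies a named genus) and optional
annotations in five namespaces (KO, KEGG pathway, COG category, EC,
CAZy family). Abundances travel as a non-negative genes × samples
matrix flagged either `relative` (columns are proportions) or `counts`;
counts are never silently renormalized, because richness estimators
need them untouched.

## Taxonomic profiles and diversity

A taxon's abundance is the sum of its assigned genes' abundances per
sample; genes `Unclassified` at the chosen rank pool into a single
`Unclassified` row, so aggregation conserves column mass exactly. Taxa
strictly below relative abundance 1e-8 in every sample are removed; a
taxon at or above the floor anywhere is kept everywhere.

Alpha diversity: Shannon–Wiener H = −Σ pᵢ ln pᵢ in natural log, Pielou
J = H/ln S (undefined, returned as `None`, for single-taxon
communities), and bias-corrected Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1))
with F₁/F₂ the singleton/doubleton counts. The natural-log convention
keeps J = H/ln S internally consistent. Rarefaction subsamples reads
without replacement (multivariate hypergeometric), 10 resamples per
depth by default; the mean rarefied richness is checked in the tests
against the closed form Σᵢ [1 − C(N−nᵢ, d)/C(N, d)].

Beta diversity uses the Whittaker index β_w − 1 = S_union/ᾱ − 1 on
presence/absence, with presence meaning relative abundance at or above
the 1e-8 floor. Because "weighted" orderings of this index are common
but the index itself is defined on incidence, the presence/absence form
is the default and an abundance-weighted variant (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ),
i.e. Bray–Curtis on proportions) is available behind a config switch
that is recorded with the run. Ordination is classical PCoA (double
centering of −D²/2, eigendecomposition); negative eigenvalues are
reported as-is — no Lingoes/Cailliez correction — and excluded from the
proportion-explained denominator. Group structure is tested by one-way
PERMANOVA: pseudo-F from total vs within-group sums of squared
distances, p = (1 + #{permuted F ≥ observed F})/(1 + n_permutations)
with 999 permutations by default, R² = SS_between/SS_total. A fully
degenerate (all-zero) distance matrix yields R² = 0, p = 1 with a
warning rather than an exception, so edge-case simulations cannot crash
a pipeline run.

## Canopy clustering, CAGs and MGS

Genes from one genome scale together across samples, so Pearson
correlation of abundance profiles is the clustering affinity. The
canopy pass iterates genes in seeded-random order: an unassigned gene
seeds a canopy; all unassigned genes with PCC ≥ 0.90 (capture
threshold) to the canopy profile join; the profile is recomputed as the
per-sample median of members and membership re-gathered until a fixed
point, capped at 5 rounds (empirically convergent well before the cap).
Assigned genes are never re-seeded. Genes with zero variance or zero in
more than 90% of samples are excluded up front and listed in the run
report — correlation on near-constant vectors is meaningless.

Canopies whose median profiles correlate above 0.97 are merged by
single linkage (connected components of the threshold graph) into a
CAG; the published phrase "PCC distance larger than 0.97" is read as
correlation above the threshold, since a literal distance reading would
merge anti-correlated canopies and contradict co-abundance. A CAG with
strictly more than 20 genes (≥ 21) is a metagenomic species (MGS). The
taxonomy label is the modal species when it covers at least half of the
member genes, otherwise `group`; an exact 50/50 tie resolves
lexicographically with a logged warning.

Significance screening collapses each CAG to its significantly changed
genes: per-gene two-sided Wilcoxon rank-sum between the contrasted
groups, Holm-adjusted **within the CAG's genes**. The CAG being
collapsed is the natural adjustment family — a family-wise correction
across an entire metagenomic catalog (thousands to millions of genes)
has no attainable rejection at n ≈ 20–30 samples, where the smallest
exact p is on the order of 1e-5. The collapsed abundance is the
per-sample median of the retained genes; collapsed CAGs are scored by
LDA effect size and reported when the score reaches the 2.0 cutoff,
with a CAG-level q-value from Holm across the collapsed profiles.

## Differential features

Feature profiles sum gene abundances per annotated feature; a gene with
k annotations in a namespace contributes fully to each of the k
features (annotated mass is conserved with multiplicity). Group
comparisons use the two-sided Wilcoxon rank-sum test: exhaustive
enumeration of rank-sum assignments for pooled sizes up to 12 (exact
with or without ties; for tie-free data it equals the classical exact
test), scipy's exact recurrence for larger tie-free samples when
requested, and the tie- and continuity-corrected normal approximation
otherwise. Holm adjustment is applied within each namespace × contrast
family, matching per-analysis correction rather than a global one. The
default pairwise contrast set follows the developmental comparisons of
interest (nursing cubs vs transition cubs, cubs vs parents, father vs
mother) and is configuration-driven.

The LDA effect size is a re-implementation of the LEfSe convention for
a flat two-class design (the study has no subclass structure, so the
within-class Wilcoxon stage is omitted): Kruskal–Wallis pre-filter at
α = 0.05; surviving features mapped to the [1, 10⁶] per-sample relative
scale (total-sum scaling, clipped below at 1); with a single feature
the fitted discriminant axis reduces to the feature itself, so the
per-bootstrap effect magnitude is the absolute class-mean difference on
that axis; the score is log₁₀(1 + |difference|), the median over 30
class-stratified bootstrap resamples (two thirds of each class, without
replacement). Collapsed CAG profiles skip the total-sum scaling — they
are already proportions of a composition whose remaining parts are not
rows of the matrix, and renormalizing a single collapsed profile would
erase its signal.

Pathway host attribution computes, per pathway × group, each genus's
share of the pathway's summed gene abundance; the host is the argmax,
ties resolve lexicographically with a logged warning, and a pathway
with zero abundance in a group is flagged undefined.

## Keystone genera

Two independent discovery routes are intersected. Route one: genera
present in strictly more than 70% of samples are "stable"; pairwise
Spearman correlations among them are tested with
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom (|ρ| = 1 falls back to
the exact enumeration bound 2/n!), edges with p > 0.05 are removed, and
genera with over 30 remaining connections (degree ≥ 31) are hubs. Ties
in abundance ranks use average ranks. Route two: a 500-tree random
forest classifies the five group labels from genus abundances
(unweighted classes, matching the absence of any weighting statement in
the source convention); genera are ranked by mean decrease in Gini
impurity and the top 20 kept. The forest runs on the full
floor-filtered genus profile, the network on stable genera only. The
keystone set is hub ∩ top-20, reported in forest rank order. OOB error
is the out-of-bag misclassification rate; with synthetic data in which
only keystone genera carry group signal, OOB error is necessarily high
(~0.5–0.65), since only one of five groups is separable — the
informative comparison is against the chance level 1 − max group
frequency ≈ 0.73.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not read-level sequencing. Per sample, each planted species has a
latent trajectory exp(base + community term + species noise + group
fold), and each of its genes is that trajectory times an independent
per-gene, per-sample lognormal factor with coefficient of variation
`gene_noise_cv` (0.05 by default) — the co-abundance premise. Defaults,
chosen once as a desk-scale analogue of the study conditions:

- 80 species × 30 genes plus 20% background genes (~3,000 genes),
  33 samples in groups 5/9/8/5/6;
- a 60-genus community block sharing one latent factor with
  alternating-sign loadings (σ = 0.5): a factor common to *every* taxon
  would cancel under closure to relative abundances, while
  half-up/half-down loadings survive normalization and make every core
  pair significantly (anti-)correlated — the network's
  high-connectivity block;
- 5 keystone genera inside the block with a 4-fold multiplicative
  effect in C2, a slightly larger community loading (1.2) and lower
  idiosyncratic noise (0.25 vs 0.32) — keystones are *defined* as
  group-discriminative and highly connected, so both properties are
  planted explicitly;
- structural occupancy zeros for the transient (non-core) taxa, drawn
  once per taxon × sample at base rate 0.8 scaled by a per-group factor
  rising from 0.5 (C0) to 1.0 (adults). This reproduces the richness
  gradient of a maturing gut community and gives the presence/absence
  Whittaker ordination its group structure; the stable core is always
  present, which is what makes the occurrence filter meaningful.

Ground truth (cluster memberships, fold changes, keystone identities)
is emitted alongside the data for recovery scoring.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: sequencing noise and depth
variation (abundances are deterministic given the latent draws; a
multinomial read sampler is provided separately for count-based
estimators), phylogenetic correlation between taxa, compositional
artifacts beyond simple closure, strain-level mosaicism within species,
and annotation errors. Recovery rates measured here are best-case
figures for data that satisfy the model's assumptions.

## Numerical choices and degenerate inputs

- Lossless TSV round-trips: matrices are written at 17 significant
  digits; reading back reproduces values to 1e-12.
- Constant vectors: excluded (and logged) from canopy clustering and
  from the correlation network; constancy is tested as max = min rather
  than sample variance to dodge floating-point fuzz.
- A Spearman statistic within 1e-12 of ±1 is treated as exact
  monotonicity.
- Canopy/CAG determinism: the gene iteration order is the only
  randomness; a fixed `seed_order_seed` fixes the partition exactly.
- PERMANOVA p-values use the add-one convention, so the smallest
  attainable p with 999 permutations is 0.001.
- Problem sizes in the test suite (e.g. 20-cluster recovery at 20
  seeds, 400-replicate PERMANOVA calibration at 199 permutations,
  50-seed keystone recovery) were chosen to keep Monte-Carlo error
  comfortably below the asserted margins while the whole suite stays
  desk-scale.

## Known limitations

- The canopy implementation follows the published outline (random seed
  gene, correlation capture, profile refinement, 0.97 merge) without
  the original tool's additional seed-pruning heuristics; on data with
  many near-threshold correlations the partitions may differ.
- Gene-level Holm within each CAG is a deliberate deviation from a
  catalog-wide family (see above); users wanting a global family can
  apply `holm_adjust` to the pooled p-values themselves.
- The LDA effect size is a faithful small-sample re-implementation of
  the convention, not a byte-compatible port of the original tool.
- PERMANOVA is one-way only; no strata/nested designs.
- No phylogeny-aware beta diversity (no tree is available at the gene
  catalog level).
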