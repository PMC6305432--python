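# pandagut

Downstream analysis of deep shotgun-metagenomic gut-microbiome surveys,
modeled on a longitudinal study of two giant-panda cubs and their parents
(33 fecal samples in five groups: cubs at 0–1.5, 1.5–6 and 6–9 months —
C0, C1, C2 — and father F / mother M). The package takes a non-redundant
gene catalog with taxonomic lineages and functional annotations plus a
gene × sample abundance matrix, and carries them through:

- **Taxonomic profiling and diversity** — taxa are quantified as the sum
  of their assigned gene abundances; taxa below relative abundance 1e-8
  everywhere are removed; per-sample Shannon–Wiener H = −Σ pᵢ ln pᵢ,
  Pielou evenness J = H/ln S, bias-corrected Chao1 richness
  S_obs + F₁(F₁−1)/(2(F₂+1)), and read-rarefaction curves.
- **Ordination and group testing** — pairwise Whittaker dissimilarity
  β_w − 1 = S_union/ᾱ − 1 on presence/absence (abundance-weighted
  variant available), classical PCoA, and one-way PERMANOVA
  (pseudo-F with a permutation p-value).
- **Co-abundance gene groups (CAGs) and metagenomic species (MGS)** —
  canopy clustering: a randomly seeded gene gathers all genes with
  Pearson correlation ≥ 0.90 to the canopy's median profile; canopies
  whose profiles correlate > 0.97 merge (single linkage) into a CAG.
  CAGs with more than 20 genes are MGS; a CAG whose modal species covers
  under half its genes is labeled `group`. Significant CAGs are found by
  per-gene Wilcoxon tests (Holm-adjusted within the CAG), collapsed to
  the median of their significant genes, and screened by LDA effect
  size ≥ 2.0.
- **Differential features** — KO / pathway / COG / EC / CAZy profiles by
  annotation sum, two-sided Wilcoxon rank-sum (exact for small samples)
  with Holm adjustment per namespace × contrast, LEfSe-style LDA effect
  sizes on the [1, 10⁶] scale, and pathway "host" attribution to the
  genus contributing the largest abundance share.
- **Structurally important (keystone) genera** — intersection of two
  routes: hubs (> 30 significant Spearman correlations, t-test p ≤ 0.05)
  of the co-occurrence network over stable genera (occurrence > 70% of
  samples), and the top-20 genera by random-forest Gini importance
  (500 trees, out-of-bag error reported) for the five group labels.

Real sequencing data are not bundled; a first-class synthetic-data
generator (`pandagut.simulate`) produces gene catalogs and abundance
matrices with planted co-abundance clusters, a correlated community
block, age-graded taxon occupancy, group fold changes and keystone
genera, together with the ground truth needed to score recovery.

## Worked example

Run the whole pipeline on the default synthetic study design:

```bash
pandagut --outdir out --seed 1 run-all
```

which prints (and writes to `out/summary.json`):

```json
{
  "n_genes": 3000,
  "n_samples": 33,
  "n_species_detected": 81,
  "n_genera_detected": 81,
  "mean_shannon": 3.2300926811269726,
  "permanova_R2": 0.27084676222462384,
  "permanova_p": 0.001,
  "n_cags": 673,
  "n_mgs": 78,
  "n_significant_cags": 30,
  "n_excluded_genes": 0,
  "n_significant_pathways": 1,
  "n_stable_genera": 63,
  "n_hub_genera": 60,
  "rf_oob_error": 0.5151515151515151,
  "n_shared_important": 11,
  "keystone_recall": 1.0
}
```

Reading the numbers: the 3,000-gene catalog (80 planted species plus
background genes) collapses to 673 CAGs of which 78 are large enough to
call MGS; group structure in the Whittaker ordination is significant
(PERMANOVA R² = 0.27 at the permutation floor p = 0.001); 63 of 81
genera are stable, 60 of those are network hubs; and all five planted
keystone genera are recovered in the hub ∩ RF-top-20 intersection
(`keystone_recall` = 1.0). The high OOB error is expected — only the
keystone genera carry group signal, so only one of five groups is
separable. Individual stages are available as `simulate`, `profile`,
`diversity`, `ordinate`, `cag`, `differential` and `keystone`
subcommands, or directly as library functions.

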