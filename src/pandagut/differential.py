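"""Functional feature profiles and differential-abundance testing.

Gene abundances are aggregated to functional features (KO, KEGG pathway,
COG category, EC, CAZy family) by summing the genes assigned to each
feature; a gene with several annotations contributes fully to each.
Group differences use the two-sided Wilcoxon rank-sum test with Holm
adjustment within each namespace-by-contrast family, and biomarkers are
screened by a LEfSe-style LDA effect size on a log10 scale.  Pathways
are attributed to the genus contributing most of their gene abundance
within each group ("host" of the pathway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import GeneCatalogEntry, NAMESPACES, UNCLASSIFIED
from .matrix import AbundanceMatrix

__all__ = [
    "FeatureProfile",
    "TestResult",
    "LDAEffect",
    "HostAttribution",
    "aggregate_features",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "feature_tests",
    "lda_effect_size",
    "host_attribution",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureProfile:
    namespace: str
    matrix: AbundanceMatrix


@dataclass
class TestResult:
    feature_id: str
    contrast: tuple[str, str]
    raw_p: float
    adjusted_p: float
    direction: int  # sign of median(group_a) - median(group_b)


@dataclass
class LDAEffect:
    feature_id: str
    class_pair: tuple[str, str]
    lda_score: float  # log10 scale
    passes: bool
    enriched_in: str = ""


@dataclass
class HostAttribution:
    pathway_id: str
    group: str
    host_genus: str
    host_share: float
    defined: bool = True


def aggregate_features(
    gene_matrix: AbundanceMatrix, catalog: list[GeneCatalogEntry], namespace: str
) -> FeatureProfile:
    """Sum gene abundances per annotated feature.  Unannotated genes are
    ignored; a gene with k features in the namespace contributes to all k."""
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    rows: dict[str, np.ndarray] = {}
    data = gene_matrix.data
    present = set(gene_matrix.row_ids)
    n_s = len(gene_matrix.sample_ids)
    for e in catalog:
        if e.gene_id not in present:
            continue
        feats = e.annotations.get(namespace, [])
        if not feats:
            continue
        vec = data.loc[e.gene_id].to_numpy()
        for f in feats:
            rows[f] = rows.get(f, np.zeros(n_s)) + vec
    df = pd.DataFrame(
        rows, index=gene_matrix.sample_ids
    ).T.sort_index() if rows else pd.DataFrame(
        np.empty((0, n_s)), columns=gene_matrix.sample_ids
    )
    return FeatureProfile(namespace, AbundanceMatrix(df, units=gene_matrix.units))


def wilcoxon_rank_sum(a, b, exact_threshold: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    When the pooled size is at most ``exact_threshold`` the p-value is
    computed by exhaustive enumeration of all group assignments of the
    (mid)ranks — the fraction with a rank-sum deviation at least as large
    as observed — which is exact with or without ties and equals the
    classical exact two-sided p for tie-free data.  Larger samples use
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in Wilcoxon test")
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    tie_free = len(np.unique(pooled)) == len(pooled)
    if n <= min(exact_threshold, 12):
        from itertools import combinations

        ranks = stats.rankdata(pooled)
        mu = n1 * (n + 1) / 2
        dev = abs(ranks[:n1].sum() - mu)
        hits = total = 0
        for combo in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    method = "exact" if (n <= exact_threshold and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(1.0, res.pvalue))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def feature_tests(
    profile: FeatureProfile,
    groups: dict[str, str] | pd.Series,
    contrast: tuple[tuple[str, ...], tuple[str, ...]],
) -> list[TestResult]:
    """Wilcoxon rank-sum per feature between two (possibly pooled) group
    sets, Holm-adjusted across the namespace's features."""
    groups = dict(groups)
    side_a, side_b = (set(contrast[0]), set(contrast[1]))
    samples = profile.matrix.sample_ids
    mask_a = np.array([groups[s] in side_a for s in samples])
    mask_b = np.array([groups[s] in side_b for s in samples])
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("empty contrast side")
    x = profile.matrix.values
    raw = np.array([wilcoxon_rank_sum(r[mask_a], r[mask_b]) for r in x])
    adj = holm_adjust(raw)
    name = ("+".join(sorted(side_a)), "+".join(sorted(side_b)))
    out = []
    for fid, r, q, row in zip(profile.matrix.row_ids, raw, adj, x):
        direction = int(np.sign(np.median(row[mask_a]) - np.median(row[mask_b])))
        out.append(TestResult(fid, name, float(r), float(q), direction))
    return out


LEFSE_SCALE = 1e6  # LEfSe convention: per-sample values on a [1, 1e6] scale


def lda_effect_size(
    feature_matrix: AbundanceMatrix,
    classes: dict[str, str] | pd.Series,
    cutoff: float = 2.0,
    seed: int = 0,
    n_bootstrap: int = 30,
    kw_alpha: float = 0.05,
    normalize: bool = True,
) -> list[LDAEffect]:
    """LEfSe-style biomarker scoring for two classes.

    Features are pre-filtered by Kruskal-Wallis at ``kw_alpha``; survivors
    are scored on the [1, 1e6] per-sample relative scale (per-sample
    total-sum scaling; pass ``normalize=False`` when the values already
    are proportions of a composition that is not fully represented by
    the rows, e.g. collapsed CAG profiles).  With a single
    feature the linear discriminant axis reduces to the feature itself,
    so the per-bootstrap effect magnitude is the absolute class-mean
    difference on that axis; the score is log10(1 + |difference|), the
    median over ``n_bootstrap`` class-stratified resamples (two thirds of
    each class, without replacement).  ``passes`` is score >= ``cutoff``.
    """
    classes = pd.Series(dict(classes))
    labels = classes.loc[feature_matrix.sample_ids]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"LDA effect size needs exactly 2 classes, got {uniq}")
    idx_a = np.flatnonzero((labels == uniq[0]).to_numpy())
    idx_b = np.flatnonzero((labels == uniq[1]).to_numpy())
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each class needs at least 3 samples")

    x = feature_matrix.values.astype(float)
    if normalize:
        colsum = x.sum(axis=0)
        colsum[colsum == 0] = 1.0
        scaled = np.maximum(x / colsum * LEFSE_SCALE, 1.0)
    else:
        scaled = np.maximum(x * LEFSE_SCALE, 1.0)

    rng = np.random.default_rng(seed)
    out: list[LDAEffect] = []
    for fid, row, srow in zip(feature_matrix.row_ids, x, scaled):
        try:
            kw_p = stats.kruskal(row[idx_a], row[idx_b]).pvalue
        except ValueError:  # all values identical
            kw_p = 1.0
        if not np.isfinite(kw_p) or kw_p >= kw_alpha:
            continue
        diffs = []
        for _ in range(n_bootstrap):
            sub_a = rng.choice(idx_a, size=max(2, round(2 * len(idx_a) / 3)), replace=False)
            sub_b = rng.choice(idx_b, size=max(2, round(2 * len(idx_b) / 3)), replace=False)
            diffs.append(srow[sub_a].mean() - srow[sub_b].mean())
        med = float(np.median(diffs))
        score = float(np.log10(1 + abs(med)))
        out.append(
            LDAEffect(
                feature_id=fid,
                class_pair=(uniq[0], uniq[1]),
                lda_score=score,
                passes=score >= cutoff,
                enriched_in=uniq[0] if med > 0 else uniq[1],
            )
        )
    return out


def host_attribution(
    gene_matrix: AbundanceMatrix,
    catalog: list[GeneCatalogEntry],
    groups: dict[str, str] | pd.Series,
    namespace: str = "pathway",
) -> list[HostAttribution]:
    """Attribute each pathway, within each group, to the genus whose genes
    contribute the largest share of the pathway's summed abundance.

    Ties resolve lexicographically (logged); a pathway with zero
    abundance in a group is flagged undefined.
    """
    groups = dict(groups)
    samples = gene_matrix.sample_ids
    group_names = sorted({groups[s] for s in samples})
    genus_of = {e.gene_id: e.lineage["genus"] for e in catalog}
    members: dict[str, list[str]] = {}
    for e in catalog:
        for f in e.annotations.get(namespace, []):
            members.setdefault(f, []).append(e.gene_id)
    present = set(gene_matrix.row_ids)
    data = gene_matrix.data
    out: list[HostAttribution] = []
    for pathway in sorted(members):
        genes = [g for g in members[pathway] if g in present]
        if not genes:
            continue
        sub = data.loc[genes]
        genus = pd.Index([genus_of[g] for g in genes], name="genus")
        by_genus = sub.groupby(genus, sort=True).sum()
        for grp in group_names:
            cols = [s for s in samples if groups[s] == grp]
            totals = by_genus[cols].sum(axis=1)
            total = totals.sum()
            if total <= 0:
                out.append(HostAttribution(pathway, grp, "", 0.0, defined=False))
                continue
            shares = totals / total
            best = shares.max()
            winners = sorted(shares.index[shares == best])
            if len(winners) > 1:
                logger.warning(
                    "pathway %s group %s: host tie %s; taking %r",
                    pathway, grp, winners, winners[0],
                )
            out.append(HostAttribution(pathway, grp, winners[0], float(best)))
    return out
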