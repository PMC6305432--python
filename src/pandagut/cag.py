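"""Canopy clustering of catalog genes into co-abundance gene groups.

Genes originating from one genome scale together across samples, so
Pearson correlation of abundance profiles serves as the clustering
"distance".  A randomly picked unassigned seed gene gathers every
unassigned gene correlated with it above the capture threshold (default
PCC >= 0.90) into a canopy; the canopy profile (per-sample median of
member abundances) is refined and membership re-gathered to a fixed
point.  Canopies whose median profiles correlate above the merge
threshold (PCC > 0.97) are merged by single linkage into a CAG.  CAGs
with strictly more than 20 genes are called metagenomic species (MGS);
a CAG whose modal species accounts for under half of its genes is
labeled 'group'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .catalog import GeneCatalogEntry, UNCLASSIFIED
from .differential import holm_adjust, lda_effect_size, wilcoxon_rank_sum
from .matrix import AbundanceMatrix

__all__ = [
    "Canopy",
    "CAG",
    "SignificantCAG",
    "gene_pcc",
    "canopy_cluster",
    "merge_canopies",
    "call_mgs",
    "label_cag",
    "significant_cags",
]

logger = logging.getLogger(__name__)

GROUP_LABEL = "group"


@dataclass
class Canopy:
    seed_gene: str
    members: set[str]
    profile: np.ndarray  # per-sample median over members


@dataclass
class CAG:
    cag_id: str
    members: set[str]
    profile: np.ndarray
    label: str = ""
    is_mgs: bool = False


@dataclass
class SignificantCAG:
    cag_id: str
    retained_genes: set[str]
    abundance: np.ndarray  # per-sample median of retained genes
    q_value: float
    lda_score: float


def gene_pcc(x, y) -> float:
    """Pearson correlation of two abundance profiles; NaN (undefined,
    excluded from clustering) when either has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def canopy_cluster(
    gene_matrix: AbundanceMatrix,
    capture_pcc: float = 0.90,
    seed_order_seed: int = 0,
    max_iter: int = 5,
    max_zero_fraction: float = 0.90,
) -> tuple[list[Canopy], list[str]]:
    """Seeded-random canopy clustering.

    Returns the canopies and the excluded gene ids (zero variance, or
    zero in more than ``max_zero_fraction`` of samples — correlation on
    near-constant vectors is unstable).  Assigned genes are never
    re-seeded; each canopy profile is refined (member medians) and
    membership re-gathered until a fixed point or ``max_iter`` rounds.
    """
    x = gene_matrix.values
    genes = np.array(gene_matrix.row_ids)
    n_s = x.shape[1]
    variances = x.std(axis=1)
    zero_frac = (x == 0).mean(axis=1)
    usable = (variances > 0) & (zero_frac <= max_zero_fraction)
    excluded = genes[~usable].tolist()
    if excluded:
        logger.info("excluded %d genes from clustering", len(excluded))
    idx = np.flatnonzero(usable)
    if len(idx) < 2:
        raise ValueError("need at least 2 genes with positive variance")
    xs = x[idx]
    z = _standardize_rows(xs)  # row i: (x - mean)/sd, so PCC = z_i . z_j / n

    rng = np.random.default_rng(seed_order_seed)
    order = rng.permutation(len(idx))
    assigned = np.zeros(len(idx), dtype=bool)
    canopies: list[Canopy] = []
    for s in order:
        if assigned[s]:
            continue
        profile = xs[s]
        members = {s}
        for _ in range(max_iter):
            sd = profile.std()
            if sd == 0:
                break
            zp = (profile - profile.mean()) / sd
            pcc = z @ zp / n_s
            candidate = (~assigned) & (pcc >= capture_pcc)
            candidate[s] = True  # the seed always stays
            new_members = set(np.flatnonzero(candidate))
            if new_members == members:
                break
            members = new_members
            profile = np.median(xs[sorted(members)], axis=0)
        assigned[sorted(members)] = True
        member_ids = set(genes[idx[sorted(members)]])
        canopies.append(
            Canopy(
                seed_gene=str(genes[idx[s]]),
                members=member_ids,
                profile=np.median(xs[sorted(members)], axis=0),
            )
        )
    return canopies, excluded


def merge_canopies(
    canopies: list[Canopy],
    gene_matrix: AbundanceMatrix,
    merge_pcc: float = 0.97,
) -> list[CAG]:
    """Single-linkage merge of canopies whose median profiles correlate
    at PCC >= ``merge_pcc``; the CAG profile is the per-sample median
    over all member genes."""
    if not canopies:
        return []
    profiles = np.vstack([c.profile for c in canopies])
    sd = profiles.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=-1.0)  # constant profiles never merge
    np.fill_diagonal(corr, 1.0)
    adj = csr_matrix((corr >= merge_pcc) & (sd[:, None] > 0) & (sd[None, :] > 0))
    n_comp, comp = connected_components(adj, directed=False)
    data = gene_matrix.data
    cags = []
    for c in range(n_comp):
        members: set[str] = set()
        for i in np.flatnonzero(comp == c):
            members |= canopies[i].members
        profile = np.median(data.loc[sorted(members)].to_numpy(), axis=0)
        cags.append(CAG(cag_id="", members=members, profile=profile))
    cags.sort(key=lambda c: (-len(c.members), min(c.members)))
    for k, cag in enumerate(cags):
        cag.cag_id = f"CAG{k + 1:04d}"
    return cags


def call_mgs(cags: list[CAG], min_genes: int = 21) -> list[CAG]:
    """Metagenomic species: CAGs with strictly more than 20 member genes
    (>= ``min_genes``)."""
    for cag in cags:
        cag.is_mgs = len(cag.members) >= min_genes
    return cags


def label_cag(cag: CAG, catalog: list[GeneCatalogEntry]) -> CAG:
    """Taxonomy label: the modal species if it covers at least half of
    the member genes, else 'group'.  A tie at exactly one half between
    two species resolves lexicographically (logged)."""
    species_of = {e.gene_id: e.lineage["species"] for e in catalog}
    counts: dict[str, int] = {}
    for g in cag.members:
        sp = species_of.get(g, UNCLASSIFIED)
        if sp != UNCLASSIFIED:
            counts[sp] = counts.get(sp, 0) + 1
    if not counts:
        cag.label = GROUP_LABEL
        return cag
    top = max(counts.values())
    modal = sorted(s for s, c in counts.items() if c == top)
    if len(modal) > 1 and top / len(cag.members) >= 0.5:
        logger.warning(
            "%s: species tie %s at fraction %.2f; taking %r",
            cag.cag_id, modal, top / len(cag.members), modal[0],
        )
    cag.label = modal[0] if top / len(cag.members) >= 0.5 else GROUP_LABEL
    return cag


def significant_cags(
    cags: list[CAG],
    gene_matrix: AbundanceMatrix,
    groups: dict[str, str] | pd.Series,
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    seed: int = 0,
) -> list[SignificantCAG]:
    """Collapse CAGs to their significantly changed genes and screen by
    LDA effect size.

    Per member gene: two-sided Wilcoxon rank-sum between the two
    contrasted groups (exact enumeration at these pooled sizes when the
    data are tie-free), Holm-adjusted within the genes of each CAG — the
    CAG being collapsed is the natural adjustment family; a family-wise
    correction across a whole gene catalog would have no attainable
    rejection at metagenomic scale.  Only genes with adjusted p <
    ``alpha`` are retained.  The collapsed CAG abundance is the
    per-sample median of retained genes; collapsed CAGs are scored with
    the LDA effect size and reported when |score| >= ``lda_cutoff``; the
    CAG-level q-value is the Holm-adjusted Wilcoxon p on the collapsed
    profile, across the collapsed CAGs.
    """
    groups = dict(groups)
    labels = pd.Series({s: groups[s] for s in gene_matrix.sample_ids})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 contrasted groups, got {uniq}")
    mask_a = (labels == uniq[0]).to_numpy()
    mask_b = (labels == uniq[1]).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each contrasted group needs at least 3 samples")

    data = gene_matrix.data
    if not cags:
        return []
    n_pooled = int(mask_a.sum() + mask_b.sum())

    collapsed: list[tuple[CAG, set[str], np.ndarray]] = []
    for cag in cags:
        members = sorted(cag.members)
        x = data.loc[members].to_numpy()
        raw = np.array(
            [
                wilcoxon_rank_sum(r[mask_a], r[mask_b], exact_threshold=n_pooled)
                for r in x
            ]
        )
        adj = holm_adjust(raw)
        retained = {g for g, p in zip(members, adj) if p < alpha}
        if not retained:
            continue
        abundance = np.median(data.loc[sorted(retained)].to_numpy(), axis=0)
        collapsed.append((cag, retained, abundance))
    if not collapsed:
        return []

    prof = pd.DataFrame(
        np.vstack([c[2] for c in collapsed]),
        index=[c[0].cag_id for c in collapsed],
        columns=gene_matrix.sample_ids,
    )
    cag_raw = np.array(
        [wilcoxon_rank_sum(r[mask_a], r[mask_b]) for r in prof.to_numpy()]
    )
    cag_q = holm_adjust(cag_raw)
    effects = {
        e.feature_id: e
        for e in lda_effect_size(
            AbundanceMatrix(prof, units="counts"),
            labels,
            cutoff=lda_cutoff,
            seed=seed,
            normalize=False,  # collapsed medians are already on the relative scale
        )
    }
    out = []
    for (cag, retained, abundance), q in zip(collapsed, cag_q):
        eff = effects.get(cag.cag_id)
        if eff is not None and eff.passes:
            out.append(
                SignificantCAG(
                    cag_id=cag.cag_id,
                    retained_genes=retained,
                    abundance=abundance,
                    q_value=float(q),
                    lda_score=eff.lda_score,
                )
            )
    return out
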