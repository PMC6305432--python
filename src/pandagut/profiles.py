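"""Taxon profiles, alpha/beta diversity, ordination and PERMANOVA.

Gene abundances are aggregated to a taxonomic rank by summing each
taxon's assigned genes per sample; taxa below a relative-abundance floor
(default 1e-8) in every sample are removed.  Alpha diversity uses the
Shannon-Wiener index (natural log), Pielou evenness J = H/ln S, and the
bias-corrected Chao1 richness estimator; community turnover uses the
Whittaker index beta_w - 1 = S_union / mean(alpha) - 1 on presence/
absence (with a documented abundance-weighted switch), ordinated by
classical principal coordinates analysis and tested by PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .catalog import GeneCatalogEntry, RANKS
from .matrix import AbundanceMatrix

__all__ = [
    "TaxonProfile",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "aggregate_taxa",
    "filter_low_abundance",
    "shannon_index",
    "pielou_evenness",
    "chao1",
    "diversity_table",
    "rarefaction_curve",
    "expected_rarefied_richness",
    "whittaker_distance",
    "pcoa",
    "permanova",
]


@dataclass
class TaxonProfile:
    rank: str
    matrix: AbundanceMatrix

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


def aggregate_taxa(
    gene_matrix: AbundanceMatrix, catalog: list[GeneCatalogEntry], rank: str
) -> TaxonProfile:
    """Sum gene abundances per taxon at ``rank``; genes Unclassified at
    that rank pool into a single ``Unclassified`` row."""
    name_of = {e.gene_id: e.rank_name(rank) for e in catalog}
    missing = [g for g in gene_matrix.row_ids if g not in name_of]
    if missing:
        raise ValueError(f"genes absent from catalog: {missing[:5]}")
    labels = [name_of[g] for g in gene_matrix.row_ids]
    agg = gene_matrix.data.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return TaxonProfile(rank, AbundanceMatrix(agg, units=gene_matrix.units))


def filter_low_abundance(profile: TaxonProfile, floor: float = 1e-8) -> TaxonProfile:
    """Drop taxa whose relative abundance is strictly below ``floor`` in
    every sample; a taxon at/above the floor anywhere is kept everywhere."""
    if not profile.matrix.is_relative:
        raise ValueError("low-abundance filtering needs relative abundances")
    keep = (profile.matrix.data >= floor).any(axis=1)
    return TaxonProfile(
        profile.rank, AbundanceMatrix(profile.matrix.data.loc[keep], units="relative")
    )


# ---------------------------------------------------------------------------
# alpha diversity


def _positive(column) -> np.ndarray:
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    if x.sum() == 0:
        raise ValueError("all-zero column")
    return x[x > 0]


def shannon_index(column) -> float:
    """Shannon-Wiener H = -sum p_i ln p_i over positive proportions."""
    x = _positive(column)
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(column) -> float | None:
    """Pielou J = H / ln S; None (undefined) for a single-taxon community."""
    x = _positive(column)
    s = len(x)
    if s == 1:
        return None
    return shannon_index(x) / np.log(s)


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    x = np.asarray(counts)
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("Chao1 requires integer counts")
    x = x.astype(np.int64)
    if (x < 0).any():
        raise ValueError("negative counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def diversity_table(profile: TaxonProfile, floor: float = 0.0) -> pd.DataFrame:
    """Per-sample Shannon, Pielou, observed richness, and (for count
    matrices) Chao1."""
    is_counts = not profile.matrix.is_relative
    rows = []
    for s in profile.matrix.sample_ids:
        col = profile.matrix.data[s].to_numpy()
        detected = col[col > max(floor, 0)]
        rows.append(
            {
                "sample_id": s,
                "shannon_H": shannon_index(col),
                "pielou_J": pielou_evenness(col),
                "observed_richness": int((col > max(floor, 0)).sum()),
                "chao1": chao1(col) if is_counts else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(
    counts, depths: list[int], n_resamples: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Subsample reads without replacement (multivariate hypergeometric)
    and report mean/sd of observed richness and Chao1 per depth."""
    x = np.asarray(counts, dtype=np.int64)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = int(x.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        rich, ch = [], []
        for _ in range(n_resamples):
            sub = rng.multivariate_hypergeometric(x, depth)
            rich.append(int((sub > 0).sum()))
            ch.append(chao1(sub))
        rows.append(
            {
                "depth": depth,
                "mean_richness": float(np.mean(rich)),
                "sd_richness": float(np.std(rich, ddof=0)),
                "mean_chao1": float(np.mean(ch)),
                "sd_chao1": float(np.std(ch, ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form hypergeometric expectation of rarefied richness:
    sum_i 1 - C(N - n_i, d) / C(N, d)."""
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    probs = np.where(
        n - x >= depth,
        np.exp(log_comb(n - x, depth) - log_comb(n, depth)),
        0.0,
    )
    return float(np.sum(1.0 - probs))


# ---------------------------------------------------------------------------
# beta diversity


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def whittaker_distance(
    profile: TaxonProfile, floor: float = 1e-8, weighted: bool = False
) -> DistanceMatrix:
    """Pairwise Whittaker dissimilarity beta_w - 1 on presence/absence
    (presence = relative abundance >= ``floor``); the abundance-weighted
    switch uses sum|x-y| / sum(x+y) on proportions."""
    if not profile.matrix.is_relative:
        raise ValueError("Whittaker distance needs relative abundances")
    x = profile.matrix.values
    samples = profile.matrix.sample_ids
    n = len(samples)
    if weighted:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                denom = (x[:, i] + x[:, j]).sum()
                d[i, j] = d[j, i] = (
                    np.abs(x[:, i] - x[:, j]).sum() / denom if denom > 0 else 0.0
                )
        return DistanceMatrix(samples, d)
    present = x >= floor
    richness = present.sum(axis=0)
    if (richness == 0).any():
        bad = samples[int(np.argmin(richness))]
        raise ValueError(f"sample {bad!r} has no taxa above the presence floor")
    union = (present[:, :, None] | present[:, None, :]).sum(axis=0)
    mean_alpha = (richness[:, None] + richness[None, :]) / 2
    d = union / mean_alpha - 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples, d)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives recorded)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical scaling: double-center -D^2/2, eigendecompose, embed on
    axes with positive eigenvalues.  Negative eigenvalues are reported
    uncorrected and excluded from the proportion-explained denominator."""
    d = dist.values
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0])) if n else eigval > 0
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        eigenvalues=eigval,
        proportion_explained=eigval[pos] / eigval[pos].sum() if pos.any() else eigval[:0],
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    R2: float
    pseudo_F: float
    p_value: float
    n_permutations: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        idx = labels == g
        ss += d2[np.ix_(idx, idx)].sum() / (2 * idx.sum())
    return ss


def permanova(
    dist: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix (Anderson's pseudo-F).

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    A degenerate all-zero distance matrix returns R2 = 0, p = 1 with a
    warning instead of erroring.
    """
    labels = np.array([dict(groups)[s] for s in dist.sample_ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    n = len(labels)
    a = len(uniq)
    d2 = dist.values**2
    ss_total = d2.sum() / (2 * n)
    if ss_total <= 0:
        warnings.warn("degenerate distance matrix: all distances zero")
        return PermanovaResult(R2=0.0, pseudo_F=0.0, p_value=1.0, n_permutations=0)
    ss_w = _ss_within(d2, labels, uniq)
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ss_w_p = _ss_within(d2, perm, uniq)
        ss_b_p = ss_total - ss_w_p
        f_p = (ss_b_p / (a - 1)) / (ss_w_p / (n - a)) if ss_w_p > 0 else np.inf
        if f_p >= f_obs:
            hits += 1
    return PermanovaResult(
        R2=float(ss_b / ss_total),
        pseudo_F=float(f_obs),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
    )
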