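"""Structurally important genera by network hubs x random-forest importance.

Two independent routes are intersected: (a) 'stable' genera (occurrence
frequency above 70% of samples) are connected by significant Spearman
correlations (t-test on the correlation, p <= 0.05) and genera with over
30 connections are hubs; (b) a random-forest classifier of the age/parent
groups on genus abundances ranks genera by mean decrease in the Gini
index, keeping the top 20.  Genera found by both routes are the
structurally important ("keystone") set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .matrix import AbundanceMatrix
from .profiles import TaxonProfile

__all__ = [
    "GenusNetwork",
    "RFModelSummary",
    "ImportantGeneraResult",
    "occurrence_filter",
    "correlation_network",
    "hub_genera",
    "rf_importance",
    "intersect_important",
]

logger = logging.getLogger(__name__)


@dataclass
class GenusNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, rho, p, sign; i<j canonical

    def degree(self) -> pd.Series:
        counts = pd.Series(0, index=pd.Index(self.nodes, name="genus"), dtype=int)
        for col in ("source", "target"):
            vc = self.edges[col].value_counts()
            counts = counts.add(vc, fill_value=0)
        return counts.astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples(index=False):
            g.add_edge(r.source, r.target, rho=r.rho, p=r.p, sign=r.sign)
        return g

    def write_edge_list(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class RFModelSummary:
    oob_error: float
    confusion: pd.DataFrame  # true group x predicted group counts
    importances: pd.Series  # genus -> mean decrease in Gini, descending
    n_trees: int
    seed: int

    def top(self, k: int = 20) -> list[str]:
        return list(self.importances.index[:k])


@dataclass
class ImportantGeneraResult:
    stable_genera: set[str]
    hub_genera: set[str]
    rf_top: list[str]
    shared: list[str]  # hub ∩ rf_top, in rf rank order


def occurrence_filter(
    genus_profile: TaxonProfile, min_freq: float = 0.70, floor: float = 1e-8
) -> set[str]:
    """Stable genera: present (relative abundance >= ``floor``) in
    strictly more than ``min_freq`` x n_samples samples."""
    if not genus_profile.matrix.is_relative:
        raise ValueError("occurrence filtering needs relative abundances")
    present = (genus_profile.matrix.data >= floor).sum(axis=1)
    n = genus_profile.matrix.n_samples()
    return set(present.index[present > min_freq * n])


def spearman_p_from_t(rho: float, n: int) -> float:
    """Two-sided significance of a Spearman correlation via
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom; |rho| = 1 is
    handled by the exact enumeration bound 2/n!."""
    if abs(rho) >= 1.0 - 1e-12:
        return min(1.0, 2.0 / math.factorial(n))
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), n - 2))


def correlation_network(
    stable_profile: TaxonProfile, alpha: float = 0.05
) -> GenusNetwork:
    """Spearman co-occurrence network over stable genera, keeping edges
    whose correlation is significant (t-test p <= ``alpha``).  Constant
    genus vectors are excluded and logged."""
    data = stable_profile.matrix.data
    n = data.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation network")
    row_min = data.min(axis=1)
    row_max = data.max(axis=1)
    constant = data.index[row_max - row_min <= 0].tolist()
    if constant:
        logger.info("excluding %d constant genera from network", len(constant))
    data = data.drop(index=constant)
    genera = list(data.index)
    rho = stats.spearmanr(data.to_numpy(), axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rows = []
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            r = float(rho[i, j])
            p = spearman_p_from_t(r, n)
            if p <= alpha:
                rows.append(
                    {
                        "source": genera[i],
                        "target": genera[j],
                        "rho": r,
                        "p": p,
                        "sign": int(np.sign(r)),
                    }
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
    return GenusNetwork(nodes=genera, edges=edges)


def hub_genera(network: GenusNetwork, min_degree: int = 31) -> set[str]:
    """Hubs: genera with strictly over 30 significant connections
    (degree >= ``min_degree``)."""
    deg = network.degree()
    return set(deg.index[deg >= min_degree])


def rf_importance(
    genus_profile: TaxonProfile,
    groups: dict[str, str] | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> RFModelSummary:
    """Random-forest classification of group labels from genus abundances.

    Reports the out-of-bag error, the OOB confusion table, and per-genus
    mean decrease in Gini impurity, sorted descending.
    """
    groups = dict(groups)
    samples = genus_profile.matrix.sample_ids
    y = np.array([groups[s] for s in samples])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("random forest needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    x = genus_profile.matrix.values.T  # samples x genera
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    oob_pred = clf.classes_[np.argmax(clf.oob_decision_function_, axis=1)]
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(oob_pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    importances = pd.Series(
        clf.feature_importances_, index=genus_profile.matrix.row_ids, name="gini"
    ).sort_values(ascending=False, kind="stable")
    return RFModelSummary(
        oob_error=float(1.0 - clf.oob_score_),
        confusion=confusion,
        importances=importances,
        n_trees=n_trees,
        seed=seed,
    )


def intersect_important(
    stable: set[str], hubs: set[str], rf_top: list[str]
) -> ImportantGeneraResult:
    """Genera named by both discovery routes, preserving RF rank order."""
    shared = [g for g in rf_top if g in hubs]
    return ImportantGeneraResult(
        stable_genera=set(stable), hub_genera=set(hubs), rf_top=list(rf_top), shared=shared
    )
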