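"""Synthetic gene catalogs and abundance matrices with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes rather than read-level sequencing: each planted species owns a
contiguous block of catalog genes that share one latent per-sample
trajectory (so they co-vary, the premise of co-abundance clustering); a
"community block" of genera additionally shares a latent community factor
(so their genus profiles correlate, the premise of the co-occurrence
network); keystone genera sit inside the community block and carry a
strong group-dependent fold change (so both discovery routes — network
hubs and random-forest importance — can find them).  Background genes are
independent noise.  Ground truth (cluster memberships, group effects,
keystone identities) is returned for recovery testing.

Sampling design mirrors a two-cub / two-parent longitudinal study:
33 samples in five groups (C0: 5, C1: 9, C2: 8, F: 5, M: 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    GROUPS,
    NAMESPACES,
    RANKS,
    UNCLASSIFIED,
    GeneCatalogEntry,
    SampleMetadata,
    write_catalog,
    write_metadata,
)
from .matrix import AbundanceMatrix, write_abundance_matrix

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_catalog",
    "simulate_abundance",
    "sample_counts",
    "truth_report",
    "write_truth",
    "read_truth",
    "write_dataset",
]

DEFAULT_GROUP_SIZES = {"C0": 5, "C1": 9, "C2": 8, "F": 5, "M": 6}

PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria")

_KO_VOCAB = tuple(f"K{i:05d}" for i in range(1, 31))
_PATHWAY_VOCAB = tuple(f"map{i:05d}" for i in range(10, 310, 15))
_COG_VOCAB = tuple("CEFGHIJKLMNOPT")
_EC_VOCAB = tuple(f"{a}.{b}.1.{c}" for a in (1, 2, 3) for b in (1, 2, 4) for c in (1, 5, 9))
_CAZY_VOCAB = tuple(f"{fam}{i}" for fam in ("GH", "GT", "PL", "CE", "AA") for i in (1, 2, 5))
_VOCAB = {
    "KO": _KO_VOCAB,
    "pathway": _PATHWAY_VOCAB,
    "COG_category": _COG_VOCAB,
    "EC": _EC_VOCAB,
    "CAZy": _CAZY_VOCAB,
}


@dataclass
class SimulationParams:
    """Knobs of the generator, with the study-design defaults.

    ``n_core`` genera share a latent community factor (they form the
    high-connectivity block of the co-occurrence network); ``n_keystone``
    of those additionally get a ``keystone_fold`` multiplicative effect in
    group ``keystone_group``.  ``gene_noise_cv`` is the coefficient of
    variation of the per-gene, per-sample lognormal factor around the
    species trajectory.  ``occupancy`` is the per-taxon, per-sample
    Bernoulli presence probability of the transient (non-core) taxa,
    scaled per group by ``occupancy_group_factors`` (cub communities
    start sparse and approach the adult presence rate with age); core
    taxa are the stable community and are always present.  With
    ``occupancy`` = 1.0 there are no structural zeros at all.
    """

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_species: int = 80
    genes_per_species: tuple[int, int] = (30, 30)
    gene_noise_cv: float = 0.05
    occupancy: float = 0.8
    occupancy_group_factors: dict[str, float] = field(
        default_factory=lambda: {"C0": 0.5, "C1": 0.7, "C2": 0.9, "F": 1.0, "M": 1.0}
    )
    depth: float = 1e6
    background_fraction: float = 0.2
    annotation_fraction: float = 0.6
    n_core: int = 60
    n_keystone: int = 5
    keystone_fold: float = 4.0
    keystone_group: str = "C2"
    sigma_community: float = 0.5
    sigma_species: float = 0.32
    keystone_loading: float = 1.2
    keystone_sigma_species: float = 0.25
    sigma_background: float = 1.0
    base_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.depth <= 0:
            raise ValueError("counts must be positive")
        if self.gene_noise_cv < 0:
            raise ValueError("gene_noise_cv must be >= 0")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0,1]")
        unknown = set(self.n_samples_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {unknown}")
        self.n_core = min(self.n_core, self.n_species)
        self.n_keystone = min(self.n_keystone, self.n_core)

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_group.values())


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    cluster_membership: dict[str, str]  # gene_id -> cluster id
    cluster_species: dict[str, str]  # cluster id -> species name
    group_effects: dict[tuple[str, str], float]  # (taxon, group) -> fold
    keystone_genera: set[str]
    seed: int

    def __post_init__(self) -> None:
        sizes: dict[str, int] = {}
        for cid in self.cluster_membership.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        small = [c for c, n in sizes.items() if n < 2]
        if small:
            raise ValueError(f"planted clusters with < 2 genes: {small[:5]}")
        for g in self.keystone_genera:
            folds = [f for (t, _), f in self.group_effects.items() if t == g]
            if not folds or max(folds) < 4:
                raise ValueError(f"keystone genus {g!r} lacks a >= 4-fold effect")


def _species_name(i: int) -> str:
    return f"Genus{i:03d} sp{i:03d}"


def _lineage(i: int) -> dict[str, str]:
    return {
        "phylum": PHYLA[i % len(PHYLA)],
        "family": f"Family{i // 4:02d}",
        "genus": f"Genus{i:03d}",
        "species": _species_name(i),
    }


def simulate_catalog(
    params: SimulationParams, seed: int
) -> tuple[list[GeneCatalogEntry], SyntheticTruth]:
    """Generate a gene catalog with planted species blocks plus background.

    Each planted species contributes a contiguous block of genes sharing
    its full lineage; background genes are Unclassified at every rank.
    A fraction ``annotation_fraction`` of genes carries annotations per
    namespace, drawn from a small fixed vocabulary.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.genes_per_species
    entries: list[GeneCatalogEntry] = []
    membership: dict[str, str] = {}
    cluster_species: dict[str, str] = {}
    for i in range(params.n_species):
        cid = f"S{i:03d}"
        cluster_species[cid] = _species_name(i)
        n_genes = int(rng.integers(lo, hi + 1))
        for j in range(n_genes):
            gid = f"{cid}_g{j:03d}"
            membership[gid] = cid
            entries.append(
                GeneCatalogEntry(
                    gene_id=gid,
                    length_bp=int(rng.integers(300, 3000)),
                    lineage=_lineage(i),
                    annotations=_draw_annotations(rng, params.annotation_fraction),
                )
            )
    n_planted = len(entries)
    n_background = int(
        round(n_planted * params.background_fraction / max(1e-12, 1 - params.background_fraction))
    )
    for k in range(n_background):
        entries.append(
            GeneCatalogEntry(
                gene_id=f"BG_g{k:04d}",
                length_bp=int(rng.integers(300, 3000)),
                lineage={r: UNCLASSIFIED for r in RANKS},
                annotations=_draw_annotations(rng, params.annotation_fraction),
            )
        )
    group_effects: dict[tuple[str, str], float] = {}
    keystones: set[str] = set()
    for i in range(params.n_keystone):
        genus = _lineage(i)["genus"]
        keystones.add(genus)
        group_effects[(genus, params.keystone_group)] = params.keystone_fold
    truth = SyntheticTruth(
        cluster_membership=membership,
        cluster_species=cluster_species,
        group_effects=group_effects,
        keystone_genera=keystones,
        seed=seed,
    )
    return entries, truth


def _draw_annotations(rng: np.random.Generator, fraction: float) -> dict[str, list[str]]:
    ann: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        if rng.random() < fraction:
            vocab = _VOCAB[ns]
            k = 2 if rng.random() < 0.2 else 1
            ann[ns] = sorted(
                str(v) for v in rng.choice(vocab, size=min(k, len(vocab)), replace=False)
            )
    return ann


def _make_metadata(params: SimulationParams) -> list[SampleMetadata]:
    meta = []
    individual_of = {"F": ["P1"], "M": ["P2"], "C0": ["P3", "P4"], "C1": ["P3", "P4"], "C2": ["P3", "P4"]}
    for group in GROUPS:
        n = params.n_samples_per_group.get(group, 0)
        pool = individual_of[group]
        for k in range(n):
            meta.append(
                SampleMetadata(
                    sample_id=f"{group}_{k + 1:02d}",
                    individual=pool[k % len(pool)],
                    group=group,
                    collection_index=k,
                )
            )
    return meta


def simulate_abundance(
    catalog: list[GeneCatalogEntry],
    truth: SyntheticTruth,
    params: SimulationParams,
    seed: int,
) -> tuple[AbundanceMatrix, list[SampleMetadata]]:
    """Generate a relative gene x sample abundance matrix.

    A planted gene's value is (species latent trajectory per sample) x
    (per-gene lognormal factor with cv = ``gene_noise_cv``) x depth; the
    trajectory combines a per-species lognormal walk, the shared community
    factor (core genera only), the planted group fold changes, and
    structural occupancy zeros.  Background genes are independent
    lognormal noise.  Columns are normalized to proportions.
    """
    rng = np.random.default_rng(seed)
    meta = _make_metadata(params)
    samples = [m.sample_id for m in meta]
    groups = np.array([m.group for m in meta])
    n_s = len(samples)

    cluster_ids = sorted(truth.cluster_species)
    n_sp = len(cluster_ids)
    core = np.arange(n_sp) < params.n_core
    species_of_cluster = truth.cluster_species

    z_comm = rng.standard_normal(n_s)
    base = rng.normal(0.0, params.base_sigma, size=n_sp)
    sigma_sp = np.full(n_sp, params.sigma_species)
    sigma_sp[: params.n_keystone] = params.keystone_sigma_species
    eps = rng.standard_normal((n_sp, n_s)) * sigma_sp[:, None]
    log_traj = base[:, None] + eps
    # Community-block loadings alternate sign so the shared factor survives
    # the closure to relative abundances (a factor common to every taxon
    # would cancel when columns are normalized); half the block rises and
    # half falls with the factor, which still makes every core pair of
    # genera strongly (anti-)correlated.
    loading = np.where(np.arange(n_sp) % 2 == 0, 1.0, -1.0) * core
    loading[: params.n_keystone] *= params.keystone_loading
    log_traj += params.sigma_community * loading[:, None] * z_comm[None, :]

    # planted group fold changes, keyed by genus in the truth record
    genus_of_cluster = {
        cid: species_of_cluster[cid].split(" ")[0] for cid in cluster_ids
    }
    for i, cid in enumerate(cluster_ids):
        genus = genus_of_cluster[cid]
        for g in GROUPS:
            fold = truth.group_effects.get((genus, g))
            if fold is not None:
                log_traj[i, groups == g] += math.log(fold)

    traj = np.exp(log_traj)
    if params.occupancy < 1:
        # structural zeros, one draw per transient taxon x sample; the
        # presence rate rises from cub to adult groups
        factors = np.array(
            [params.occupancy_group_factors.get(g, 1.0) for g in groups]
        )
        p_present = np.minimum(1.0, params.occupancy * factors)[None, :]
        present = rng.random((n_sp, n_s)) < p_present
        present[core] = True  # the stable community is always present
        traj = traj * present

    cluster_index = {cid: i for i, cid in enumerate(cluster_ids)}
    cv = params.gene_noise_cv
    sigma_g = math.sqrt(math.log(1 + cv * cv)) if cv > 0 else 0.0

    rows = np.empty((len(catalog), n_s))
    for r, entry in enumerate(catalog):
        cid = truth.cluster_membership.get(entry.gene_id)
        if cid is None:  # background gene: independent noise
            rows[r] = np.exp(
                rng.normal(0.0, params.base_sigma)
                + rng.standard_normal(n_s) * params.sigma_background
            )
        else:
            t = traj[cluster_index[cid]]
            if sigma_g > 0:
                factor = np.exp(rng.standard_normal(n_s) * sigma_g - sigma_g**2 / 2)
            else:
                factor = 1.0
            rows[r] = t * factor
    rows *= params.depth
    df = pd.DataFrame(rows, index=[e.gene_id for e in catalog], columns=samples)
    matrix = AbundanceMatrix(df, units="counts").to_relative()
    return matrix, meta


def sample_counts(matrix: AbundanceMatrix, depth: int, seed: int) -> AbundanceMatrix:
    """Multinomial read counts at a fixed per-sample depth from a relative
    matrix (for richness estimators that need integer counts)."""
    if not matrix.is_relative:
        raise ValueError("sample_counts expects a relative matrix")
    rng = np.random.default_rng(seed)
    counts = np.column_stack(
        [rng.multinomial(depth, p / p.sum()) for p in matrix.values.T]
    )
    return AbundanceMatrix(
        pd.DataFrame(counts, index=matrix.row_ids, columns=matrix.sample_ids),
        units="counts",
    )


# ---------------------------------------------------------------------------
# truth serialization


def truth_report(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Lossless tabular dump of the planted ground truth."""
    membership = pd.DataFrame(
        sorted(truth.cluster_membership.items()), columns=["gene_id", "cluster_id"]
    )
    clusters = pd.DataFrame(
        sorted(truth.cluster_species.items()), columns=["cluster_id", "species"]
    )
    effects = pd.DataFrame(
        sorted((t, g, f) for (t, g), f in truth.group_effects.items()),
        columns=["taxon", "group", "fold_change"],
    )
    keystones = pd.DataFrame(sorted(truth.keystone_genera), columns=["genus"])
    for df in (membership, clusters, effects, keystones):
        pass  # headers exist even when empty
    return {
        "membership": membership,
        "clusters": clusters,
        "effects": effects,
        "keystones": keystones,
    }


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in truth_report(truth).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "seed.txt").write_text(str(truth.seed))


def read_truth(outdir: str | Path) -> SyntheticTruth:
    out = Path(outdir)
    membership = pd.read_csv(out / "membership.tsv", sep="\t", dtype=str)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", dtype=str)
    effects = pd.read_csv(out / "effects.tsv", sep="\t")
    keystones = pd.read_csv(out / "keystones.tsv", sep="\t", dtype=str)
    return SyntheticTruth(
        cluster_membership=dict(zip(membership.gene_id, membership.cluster_id)),
        cluster_species=dict(zip(clusters.cluster_id, clusters.species)),
        group_effects={
            (r.taxon, r.group): float(r.fold_change) for r in effects.itertuples()
        },
        keystone_genera=set(keystones.genus),
        seed=int((out / "seed.txt").read_text()),
    )


def write_dataset(
    outdir: str | Path,
    catalog: list[GeneCatalogEntry],
    matrix: AbundanceMatrix,
    meta: list[SampleMetadata],
    truth: SyntheticTruth,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(catalog, out / "catalog.tsv")
    write_abundance_matrix(matrix, out / "abundance.tsv")
    write_metadata(meta, out / "metadata.tsv")
    write_truth(truth, out / "truth")
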