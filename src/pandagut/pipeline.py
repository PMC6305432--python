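"""End-to-end orchestration: simulate -> profile -> diversity -> ordination
-> CAG/MGS -> differential -> keystone, writing every stage's tables."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cag as cagmod
from . import differential as diffmod
from . import keystone as keymod
from . import profiles as profmod
from . import simulate as simmod
from .catalog import GROUPS, group_map, validate_inputs
from .config import AnalysisConfig
from .matrix import write_abundance_matrix

logger = logging.getLogger(__name__)

DEFAULT_CONTRAST = (("C0", "C1"), ("C2",))


def _contrast_labels(meta, contrast):
    """sample -> pooled side label, restricted to the contrast's samples."""
    side_a, side_b = (set(contrast[0]), set(contrast[1]))
    name_a, name_b = "+".join(sorted(side_a)), "+".join(sorted(side_b))
    out = {}
    for m in meta:
        if m.group in side_a:
            out[m.sample_id] = name_a
        elif m.group in side_b:
            out[m.sample_id] = name_b
    return out


def run_all(
    outdir: str | Path,
    params: simmod.SimulationParams | None = None,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    contrast: tuple[tuple[str, ...], tuple[str, ...]] = DEFAULT_CONTRAST,
) -> dict:
    """Run every stage on a synthetic dataset and write all outputs.

    Returns a summary dict of the principal computed quantities.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or simmod.SimulationParams()
    config = config or AnalysisConfig()
    config.to_json(out / "config.json")

    # --- synthetic inputs
    catalog, truth = simmod.simulate_catalog(params, seed)
    matrix, meta = simmod.simulate_abundance(catalog, truth, params, seed + 1)
    simmod.write_dataset(out, catalog, matrix, meta, truth)
    report = validate_inputs(matrix, catalog, meta)
    report.to_json(out / "validation.json")
    report.raise_if_invalid()
    groups = group_map(meta)

    # --- taxonomic profiles and diversity
    species = profmod.filter_low_abundance(
        profmod.aggregate_taxa(matrix, catalog, "species"), config.abundance_floor
    )
    genus = profmod.filter_low_abundance(
        profmod.aggregate_taxa(matrix, catalog, "genus"), config.abundance_floor
    )
    write_abundance_matrix(species.matrix, out / "species_profile.tsv")
    write_abundance_matrix(genus.matrix, out / "genus_profile.tsv")
    counts = simmod.sample_counts(matrix, depth=100_000, seed=seed + 2)
    count_species = profmod.aggregate_taxa(counts, catalog, "species")
    diversity = profmod.diversity_table(count_species, floor=0.0)
    diversity.to_csv(out / "diversity.tsv", sep="\t")

    # --- ordination + PERMANOVA on the Whittaker matrix
    dist = profmod.whittaker_distance(
        species, floor=config.abundance_floor, weighted=config.weighted_beta
    )
    dist.to_frame().to_csv(out / "whittaker.tsv", sep="\t")
    ordination = profmod.pcoa(dist)
    ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    perm = profmod.permanova(
        dist, groups, n_permutations=config.n_permutations, seed=seed + 3
    )
    (out / "permanova.json").write_text(json.dumps(asdict(perm), indent=2))

    # --- CAG / MGS
    canopies, excluded = cagmod.canopy_cluster(
        matrix,
        capture_pcc=config.canopy_capture_pcc,
        seed_order_seed=seed + 4,
        max_zero_fraction=config.max_zero_fraction,
    )
    cags = cagmod.merge_canopies(canopies, matrix, merge_pcc=config.canopy_merge_pcc)
    cags = cagmod.call_mgs(cags, min_genes=config.mgs_min_genes)
    for c in cags:
        cagmod.label_cag(c, catalog)
    pd.DataFrame(
        [
            {
                "cag_id": c.cag_id,
                "n_genes": len(c.members),
                "is_mgs": c.is_mgs,
                "label": c.label,
                "members": ";".join(sorted(c.members)),
            }
            for c in cags
        ]
    ).to_csv(out / "cags.tsv", sep="\t", index=False)
    contrast_groups = _contrast_labels(meta, contrast)
    sig = cagmod.significant_cags(
        cags,
        matrix.subset_samples(sorted(contrast_groups)),
        contrast_groups,
        alpha=config.alpha,
        lda_cutoff=config.lda_cutoff_species,
        seed=seed + 5,
    )
    pd.DataFrame(
        [
            {
                "cag_id": s.cag_id,
                "n_retained": len(s.retained_genes),
                "q_value": s.q_value,
                "lda_score": s.lda_score,
            }
            for s in sig
        ],
        columns=["cag_id", "n_retained", "q_value", "lda_score"],
    ).to_csv(out / "significant_cags.tsv", sep="\t", index=False)

    # --- differential features (pathway namespace) + host attribution
    pathways = diffmod.aggregate_features(matrix, catalog, "pathway")
    tests = diffmod.feature_tests(pathways, groups, contrast)
    pd.DataFrame(
        [
            {
                "feature_id": t.feature_id,
                "contrast": f"{t.contrast[0]} vs {t.contrast[1]}",
                "raw_p": t.raw_p,
                "adjusted_p": t.adjusted_p,
                "direction": t.direction,
            }
            for t in tests
        ]
    ).to_csv(out / "pathway_tests.tsv", sep="\t", index=False)
    lda = diffmod.lda_effect_size(
        pathways.matrix.subset_samples(sorted(contrast_groups)),
        contrast_groups,
        cutoff=config.lda_cutoff_species,
        seed=seed + 6,
    )
    pd.DataFrame(
        [
            {
                "feature_id": e.feature_id,
                "lda_score": e.lda_score,
                "passes": e.passes,
                "enriched_in": e.enriched_in,
            }
            for e in lda
        ],
        columns=["feature_id", "lda_score", "passes", "enriched_in"],
    ).to_csv(out / "pathway_lda.tsv", sep="\t", index=False)
    hosts = diffmod.host_attribution(matrix, catalog, groups)
    pd.DataFrame(
        [
            {
                "pathway_id": h.pathway_id,
                "group": h.group,
                "host_genus": h.host_genus,
                "host_share": h.host_share,
                "defined": h.defined,
            }
            for h in hosts
        ]
    ).to_csv(out / "pathway_hosts.tsv", sep="\t", index=False)

    # --- keystone genera
    stable = keymod.occurrence_filter(
        genus, min_freq=config.occurrence_min_freq, floor=config.abundance_floor
    )
    stable_profile = profmod.TaxonProfile(
        "genus",
        type(genus.matrix)(genus.matrix.data.loc[sorted(stable)], units="relative"),
    )
    network = keymod.correlation_network(stable_profile, alpha=config.alpha)
    network.write_edge_list(out / "network_edges.tsv")
    hubs = keymod.hub_genera(network, min_degree=config.hub_min_degree)
    rf = keymod.rf_importance(genus, groups, n_trees=config.rf_n_trees, seed=seed + 7)
    rf.importances.to_csv(out / "rf_importances.tsv", sep="\t")
    important = keymod.intersect_important(stable, hubs, rf.top(20))
    pd.DataFrame({"genus": important.shared}).to_csv(
        out / "important_genera.tsv", sep="\t", index=False
    )
    (out / "rf_summary.json").write_text(
        json.dumps(
            {
                "oob_error": rf.oob_error,
                "n_trees": rf.n_trees,
                "confusion": rf.confusion.to_dict(),
            },
            indent=2,
        )
    )

    planted = truth.keystone_genera
    recall = (
        len(planted & set(important.shared)) / len(planted) if planted else float("nan")
    )
    summary = {
        "n_genes": len(catalog),
        "n_samples": len(meta),
        "n_species_detected": species.matrix.data.shape[0],
        "n_genera_detected": genus.matrix.data.shape[0],
        "mean_shannon": float(diversity["shannon_H"].mean()),
        "permanova_R2": perm.R2,
        "permanova_p": perm.p_value,
        "n_cags": len(cags),
        "n_mgs": sum(c.is_mgs for c in cags),
        "n_significant_cags": len(sig),
        "n_excluded_genes": len(excluded),
        "n_significant_pathways": sum(t.adjusted_p < config.alpha for t in tests),
        "n_stable_genera": len(stable),
        "n_hub_genera": len(hubs),
        "rf_oob_error": rf.oob_error,
        "n_shared_important": len(important.shared),
        "keystone_recall": recall,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
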