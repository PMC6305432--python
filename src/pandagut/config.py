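"""Analysis configuration: every printed constant of the method in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the downstream pipeline.

    Attributes
    ----------
    abundance_floor:
        Relative abundance below which a taxon is treated as absent
        (taxa below it in every sample are removed).
    canopy_capture_pcc:
        Pearson correlation for a gene to join a canopy around a seed.
    canopy_merge_pcc:
        Correlation between canopy median profiles above which canopies
        merge into one co-abundance gene group (CAG).
    mgs_min_genes:
        Minimum gene count (strictly more than 20, i.e. >= 21) for a CAG
        to be called a metagenomic species (MGS).
    group_label_majority:
        Modal-species fraction below which a CAG is labeled 'group'.
    lda_cutoff_species / lda_cutoff_family:
        LDA effect-size cutoffs for species/CAG-level and family-level
        biomarker screening.
    occurrence_min_freq:
        Occurrence frequency above which a genus counts as 'stable'.
    hub_min_degree:
        Network degree (strictly over 30, i.e. >= 31) for a hub genus.
    rf_n_trees:
        Trees in the random-forest group classifier.
    max_zero_fraction:
        Genes zero in more than this fraction of samples are excluded
        from canopy clustering (correlation on near-constant vectors is
        unstable).
    """

    abundance_floor: float = 1e-8
    canopy_capture_pcc: float = 0.90
    canopy_merge_pcc: float = 0.97
    mgs_min_genes: int = 21
    group_label_majority: float = 0.50
    lda_cutoff_species: float = 2.0
    lda_cutoff_family: float = 4.0
    occurrence_min_freq: float = 0.70
    hub_min_degree: int = 31
    rf_n_trees: int = 500
    rf_seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 999
    max_zero_fraction: float = 0.90
    weighted_beta: bool = False  # abundance-weighted variant of the Whittaker index
    rarefaction_resamples: int = 10

    def __post_init__(self) -> None:
        for name in ("canopy_capture_pcc", "canopy_merge_pcc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.occurrence_min_freq <= 1:
            raise ValueError("occurrence_min_freq must be in (0,1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))
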