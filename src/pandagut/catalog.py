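"""Gene catalog, sample metadata, and input cross-validation.

The gene catalog is the non-redundant gene set the whole pipeline hangs
off: every gene carries a four-rank lineage (phylum, family, genus,
species; any rank may be ``"Unclassified"``) plus functional annotations
in up to five namespaces (KO, pathway, COG_category, EC, CAZy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matrix import AbundanceMatrix

__all__ = [
    "RANKS",
    "GROUPS",
    "NAMESPACES",
    "GeneCatalogEntry",
    "SampleMetadata",
    "ValidationReport",
    "read_catalog",
    "write_catalog",
    "read_metadata",
    "write_metadata",
    "validate_inputs",
]

RANKS = ("phylum", "family", "genus", "species")
#: age/parent groups: C0 (0-1.5 mo cubs), C1 (1.5-6 mo), C2 (6-9 mo),
#: F (father), M (mother)
GROUPS = ("C0", "C1", "C2", "F", "M")
NAMESPACES = ("KO", "pathway", "COG_category", "EC", "CAZy")

UNCLASSIFIED = "Unclassified"


@dataclass
class GeneCatalogEntry:
    gene_id: str
    length_bp: int
    lineage: dict[str, str]  # rank -> name, "Unclassified" allowed
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1")
        for rank in RANKS:
            self.lineage.setdefault(rank, UNCLASSIFIED)
        # lineage must be prefix-consistent: a named species needs a genus
        if (
            self.lineage["species"] != UNCLASSIFIED
            and self.lineage["genus"] == UNCLASSIFIED
        ):
            raise ValueError(
                f"{self.gene_id}: species named but genus Unclassified"
            )
        for ns in self.annotations:
            if ns not in NAMESPACES:
                raise ValueError(f"{self.gene_id}: unknown namespace {ns!r}")
        # canonical form: namespaces without features are absent
        self.annotations = {ns: v for ns, v in self.annotations.items() if v}

    def rank_name(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineage.get(rank, UNCLASSIFIED)


@dataclass
class SampleMetadata:
    sample_id: str
    individual: str
    group: str
    collection_index: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"{self.sample_id}: group {self.group!r} not in {GROUPS}"
            )


# ---------------------------------------------------------------------------
# TSV readers / writers


def read_catalog(path: str | Path) -> list[GeneCatalogEntry]:
    """Read a catalog TSV (gene_id, length_bp, four ranks, one column per
    namespace with ';'-separated feature ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    mandatory = ["gene_id", "length_bp", *RANKS]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in catalog {path}")
    entries = []
    for row in df.itertuples(index=False):
        ann = {}
        for ns in NAMESPACES:
            if ns in df.columns:
                raw = getattr(row, ns)
                ann[ns] = [a for a in str(raw).split(";") if a]
        entries.append(
            GeneCatalogEntry(
                gene_id=row.gene_id,
                length_bp=int(row.length_bp),
                lineage={r: getattr(row, r) or UNCLASSIFIED for r in RANKS},
                annotations=ann,
            )
        )
    return entries


def write_catalog(entries: list[GeneCatalogEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        row = {"gene_id": e.gene_id, "length_bp": e.length_bp}
        row.update({r: e.lineage[r] for r in RANKS})
        for ns in NAMESPACES:
            row[ns] = ";".join(e.annotations.get(ns, []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = ["sample_id", "individual", "group", "collection_index"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing columns: {missing}")
    return [
        SampleMetadata(
            sample_id=r.sample_id,
            individual=r.individual,
            group=r.group,
            collection_index=int(r.collection_index),
        )
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: list[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "individual": m.individual,
                "group": m.group,
                "collection_index": m.collection_index,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def group_map(meta: list[SampleMetadata]) -> dict[str, str]:
    """sample_id -> group label."""
    return {m.sample_id: m.group for m in meta}


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    missing_genes: list[str] = field(default_factory=list)
    missing_samples: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_genes or self.missing_samples)

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise ValueError(
                f"inputs inconsistent: {len(self.missing_genes)} matrix genes "
                f"absent from catalog, {len(self.missing_samples)} samples "
                f"absent from metadata"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ok": self.ok,
                    "missing_genes": self.missing_genes,
                    "missing_samples": self.missing_samples,
                },
                indent=2,
            )
        )


def validate_inputs(
    matrix: AbundanceMatrix,
    catalog: list[GeneCatalogEntry],
    meta: list[SampleMetadata],
) -> ValidationReport:
    """Cross-check matrix rows against the catalog and matrix samples
    against the metadata; the pipeline refuses to run on a non-empty report."""
    known_genes = {e.gene_id for e in catalog}
    known_samples = {m.sample_id for m in meta}
    return ValidationReport(
        missing_genes=[g for g in matrix.row_ids if g not in known_genes],
        missing_samples=[s for s in matrix.sample_ids if s not in known_samples],
    )
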