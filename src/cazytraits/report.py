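"""Study-level orchestration and table-style reports.

``annotate_study`` runs the full annotation path — parse per-genome hit
tables, apply retention filters, resolve overlaps, assemble architectures,
build genome profiles — and returns one object the statistics and report
functions consume.  Reports are pure formatting over upstream tables: every
number in them is traceable to a TSV the pipeline wrote.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .architecture import ProteinArchitecture, architecture_inventory, assemble_study
from .filtering import (
    COVERAGE_MIN_DEFAULT,
    EVALUE_MAX_DEFAULT,
    MAX_OVERLAP_FRAC_DEFAULT,
    filter_hits,
)
from .hmmio import TaxonRecord, read_domtblout, read_genome_metadata, read_taxonomy
from .profiles import GenomeProfile, build_profiles, family_summary, profiles_frame
from .registry import DomainRegistry, load_registry

__all__ = ["StudyResult", "annotate_study", "family_inventory_report", "genome_inventory_report"]


@dataclass
class StudyResult:
    """Everything the downstream statistics need, in memory."""

    registry: DomainRegistry
    gene_counts: dict[str, int]
    taxonomy: list[TaxonRecord]
    architectures: list[ProteinArchitecture]
    profiles: list[GenomeProfile]

    @property
    def profiles_frame(self) -> pd.DataFrame:
        return profiles_frame(self.profiles)

    def family_summary(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return family_summary(self.architectures, self.registry)


def annotate_study(
    study_dir: str | Path | None = None,
    domtblout_paths: dict[str, Path] | None = None,
    metadata_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    registry: DomainRegistry | str | Path = "default",
    evalue_max: float = EVALUE_MAX_DEFAULT,
    coverage_min: float = COVERAGE_MIN_DEFAULT,
    max_overlap_frac: float = MAX_OVERLAP_FRAC_DEFAULT,
) -> StudyResult:
    """Run annotation end to end over a study directory.

    A study directory has ``genomes/<genome_id>.domtblout`` (genome id taken
    from the file stem), ``metadata.tsv`` and optionally ``taxonomy.tsv``;
    each piece can also be given explicitly.
    """
    if not isinstance(registry, DomainRegistry):
        registry = load_registry(registry)
    if study_dir is not None:
        study_dir = Path(study_dir)
        if domtblout_paths is None:
            domtblout_paths = {
                p.stem: p for p in sorted((study_dir / "genomes").glob("*.domtblout"))
            }
        metadata_path = metadata_path or study_dir / "metadata.tsv"
        default_tax = study_dir / "taxonomy.tsv"
        if taxonomy_path is None and default_tax.exists():
            taxonomy_path = default_tax
    if not domtblout_paths:
        raise FileNotFoundError("no domtblout inputs found")
    if metadata_path is None:
        raise FileNotFoundError("genome metadata (gene counts) is required")
    gene_counts = read_genome_metadata(metadata_path)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else []

    retained = []
    for gid, path in domtblout_paths.items():
        hits = read_domtblout(path, genome_id=gid)
        retained.extend(filter_hits(hits, evalue_max=evalue_max, coverage_min=coverage_min))
    architectures = assemble_study(retained, registry, max_overlap_frac=max_overlap_frac)
    profiles = build_profiles(architectures, gene_counts, registry)
    return StudyResult(
        registry=registry,
        gene_counts=gene_counts,
        taxonomy=taxonomy,
        architectures=architectures,
        profiles=profiles,
    )


def family_inventory_report(
    fam_df: pd.DataFrame, inv_df: pd.DataFrame, target_only: bool = True
) -> pd.DataFrame:
    """Family inventory in the print style: one row per family with
    ``domains/proteins``, percent single-domain (nearest integer), and the
    multi-activity architectures carrying the family."""
    rows = []
    for _, fam in fam_df.iterrows():
        if target_only and fam["category"] != "target-catalytic":
            continue
        sub = inv_df[inv_df["family"] == fam["family"]]
        archs = "; ".join(
            f"{r.arch_string} ({r.n_proteins}; e.g. {r.example_protein_id})"
            for r in sub.itertuples()
        )
        label = fam["family"]
        if isinstance(fam["accession"], str):
            label = f"{fam['family']} ({fam['accession']})"
        rows.append(
            {
                "family": label,
                "domains/proteins": f"{fam['n_domains']}/{fam['n_proteins']}",
                "pct_single_domain": int(round(fam["pct_single_domain"])),
                "multi_activity_architectures": archs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "domains/proteins", "pct_single_domain",
            "multi_activity_architectures",
        ],
    )


def genome_inventory_report(profiles: Sequence[GenomeProfile], top: int = 10) -> pd.DataFrame:
    """Genomes ranked by protein inventory with percent multi-domain."""
    df = pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in profiles],
            "n_proteins": [p.n_proteins for p in profiles],
            "pct_multidomain": [int(round(p.pct_multidomain)) for p in profiles],
        }
    ).sort_values(["n_proteins", "genome_id"], ascending=[False, True])
    return df.head(top).reset_index(drop=True)


def study_architecture_inventory(result: StudyResult) -> pd.DataFrame:
    """Study-wide architecture types (all proteins), TSV-ready."""
    inv = architecture_inventory(result.architectures)
    return pd.DataFrame(
        [
            {
                "arch_string": a.arch_string,
                "n_proteins": a.n_proteins,
                "example_protein_id": a.example_protein_id,
            }
            for a in inv
        ],
        columns=["arch_string", "n_proteins", "example_protein_id"],
    )
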