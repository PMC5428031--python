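"""Per-genome trait profiles and study-wide family/architecture summaries.

All counts are DOMAIN counts: a ``2(GH5)`` protein contributes 2 to GH5 and
2 to the cellulase trait.  Trait frequencies are domains per 1,000 predicted
genes, the study's genome-size-normalised unit; protein-based trait counts
are carried alongside for inventory-style reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .architecture import ProteinArchitecture, architecture_inventory
from .hmmio import ValidationError
from .registry import TRAITS, DomainRegistry

__all__ = [
    "GenomeProfile",
    "build_genome_profile",
    "build_profiles",
    "profiles_frame",
    "family_summary",
    "trait_aggregate",
]


@dataclass(frozen=True)
class GenomeProfile:
    """Counts and normalised frequencies of one genome's enzyme repertoire."""

    genome_id: str
    gene_count: int
    family_counts: dict[str, int]
    trait_counts: dict[str, int]
    trait_freqs: dict[str, float]
    trait_protein_counts: dict[str, int]
    n_proteins: int
    n_multidomain: int

    @property
    def pct_multidomain(self) -> float:
        if self.n_proteins == 0:
            return 0.0
        return 100.0 * self.n_multidomain / self.n_proteins


def build_genome_profile(
    architectures: Sequence[ProteinArchitecture],
    genome_id: str,
    gene_count: int,
    registry: DomainRegistry,
) -> GenomeProfile:
    """Aggregate one genome's assembled proteins into a profile."""
    if gene_count <= 0:
        raise ValidationError(f"{genome_id}: gene_count must be positive, got {gene_count}")
    family_counts: Counter[str] = Counter()
    trait_counts: Counter[str] = Counter({t: 0 for t in TRAITS})
    trait_proteins: Counter[str] = Counter({t: 0 for t in TRAITS})
    n_multi = 0
    for arch in architectures:
        if arch.genome_id != genome_id:
            raise ValueError(
                f"architecture {arch.protein_id} belongs to {arch.genome_id}, not {genome_id}"
            )
        if arch.is_multidomain:
            n_multi += 1
        for name in arch.family_names:
            family_counts[name] += 1
            trait = registry.trait_of(name)
            if trait is not None:
                trait_counts[trait] += 1
        for trait in arch.traits:
            trait_proteins[trait] += 1
    freqs = {t: 1000.0 * trait_counts[t] / gene_count for t in TRAITS}
    return GenomeProfile(
        genome_id=genome_id,
        gene_count=gene_count,
        family_counts=dict(family_counts),
        trait_counts=dict(trait_counts),
        trait_freqs=freqs,
        trait_protein_counts=dict(trait_proteins),
        n_proteins=len(architectures),
        n_multidomain=n_multi,
    )


def build_profiles(
    architectures: Iterable[ProteinArchitecture],
    gene_counts: Mapping[str, int],
    registry: DomainRegistry,
) -> list[GenomeProfile]:
    """One profile per genome in ``gene_counts``; genomes with no assembled
    proteins get an all-zero profile (they are still part of the study)."""
    by_genome: dict[str, list[ProteinArchitecture]] = {g: [] for g in gene_counts}
    for arch in architectures:
        if arch.genome_id not in by_genome:
            raise ValidationError(
                f"genome {arch.genome_id!r} has hits but no metadata entry"
            )
        by_genome[arch.genome_id].append(arch)
    return [
        build_genome_profile(by_genome[g], g, gene_counts[g], registry)
        for g in gene_counts
    ]


def profiles_frame(profiles: Sequence[GenomeProfile]) -> pd.DataFrame:
    """Flatten profiles into a genome-per-row DataFrame (TSV-ready)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "genome_id": p.genome_id,
            "gene_count": p.gene_count,
            "n_proteins": p.n_proteins,
            "n_multidomain": p.n_multidomain,
            "pct_multidomain": p.pct_multidomain,
        }
        for t in TRAITS:
            row[f"{t}_domains"] = p.trait_counts.get(t, 0)
            row[f"{t}_per_1000_genes"] = p.trait_freqs.get(t, 0.0)
            row[f"{t}_proteins"] = p.trait_protein_counts.get(t, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id") if rows else pd.DataFrame(
        columns=["genome_id"]
    ).set_index("genome_id")


def family_summary(
    architectures: Sequence[ProteinArchitecture],
    registry: DomainRegistry,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-wide per-family table plus the multi-activity inventory.

    For each family: total domain count, number of distinct proteins carrying
    the family, and the percentage of those proteins that are single-domain
    (a protein with GH10 and GH11 counts once under each family).  The second
    frame lists, per family, the multi-activity architectures containing it
    with protein counts and one example id.
    """
    n_domains: Counter[str] = Counter()
    protein_families: dict[str, set[str]] = {}
    single_dom: Counter[str] = Counter()
    n_proteins: Counter[str] = Counter()
    multiactivity_archs: dict[str, list[ProteinArchitecture]] = {}
    for arch in architectures:
        fams = set(arch.family_names)
        for name in arch.family_names:
            n_domains[name] += 1
        for name in fams:
            n_proteins[name] += 1
            if arch.n_total == 1:
                single_dom[name] += 1
            if arch.is_multiactivity:
                multiactivity_archs.setdefault(name, []).append(arch)

    def fam_order(name: str) -> tuple[int, str]:
        # registry families first, in registry order; unknowns after
        for i, e in enumerate(registry.entries):
            if e.name == name:
                return (i, name)
        return (len(registry.entries), name)

    fam_rows = []
    for name in sorted(n_domains, key=fam_order):
        npr = n_proteins[name]
        fam_rows.append(
            {
                "family": name,
                "accession": (registry.get(name).accession if name in registry else None),
                "category": registry.category_of(name),
                "trait": registry.trait_of(name),
                "n_domains": n_domains[name],
                "n_proteins": npr,
                "pct_single_domain": 100.0 * single_dom[name] / npr if npr else 0.0,
            }
        )
    fam_df = pd.DataFrame(
        fam_rows,
        columns=[
            "family", "accession", "category", "trait",
            "n_domains", "n_proteins", "pct_single_domain",
        ],
    )

    inv_rows = []
    for name in sorted(multiactivity_archs, key=fam_order):
        for at in architecture_inventory(multiactivity_archs[name]):
            inv_rows.append(
                {
                    "family": name,
                    "arch_string": at.arch_string,
                    "n_proteins": at.n_proteins,
                    "example_protein_id": at.example_protein_id,
                }
            )
    inv_df = pd.DataFrame(
        inv_rows, columns=["family", "arch_string", "n_proteins", "example_protein_id"]
    )
    return fam_df, inv_df


def trait_aggregate(
    family_counts: Mapping[str, int], registry: DomainRegistry
) -> dict[str, int]:
    """Sum per-family domain counts into per-trait totals via the registry.

    Families without a registry trait (CBMs, other catalytic, unknowns) are
    skipped with a warning.  Linear in its input by construction.
    """
    import logging

    totals = {t: 0 for t in TRAITS}
    unmapped = []
    for name, n in family_counts.items():
        trait = registry.trait_of(name)
        if trait is None:
            unmapped.append(name)
            continue
        totals[trait] += int(n)
    if unmapped:
        logging.getLogger(__name__).warning(
            "trait_aggregate: %d families without a trait ignored: %s",
            len(unmapped), ", ".join(sorted(unmapped)[:10]),
        )
    return totals
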